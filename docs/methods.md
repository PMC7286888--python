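# Methods

This note records the statistical model, the defaults that matter, the
design choices made where the method descriptions in the literature leave
room, and what the synthetic-data tests do and do not demonstrate.

## Data model

Cq values are stored long-format, one row per (donor, cell type, activation
state, timepoint, gene, technical replicate). The four subgroups are the
cross of cell type (NV, EM) and activation state; non-activated samples
carry the timepoint of their paired activated sample so that a timepoint
subset keeps its pairs. Per-gene amplification factors E (fold amplification
per cycle) accompany the Cq table; a missing value defaults to E = 2 with a
logged warning — a deliberately conservative and visible default, since real
assays run slightly below perfect doubling (≈ 1.90–1.98).

Technical replicates are averaged arithmetically on the Cq scale. Replicate
groups whose spread exceeds `max_spread` (default 0.5 Cq, the same scale as
the screening effect-size threshold) are flagged in a discordance report but
still averaged: the QC rule surfaces problems, it never silently drops data.
The literature this workflow follows does not state a duplicate-handling
rule; average-and-flag is our choice.

## Standard curves

Cq is regressed on log₁₀ relative input by OLS (`scipy.stats.linregress`);
the raw slope is negative and is stored as a positive magnitude because
that is how assay tables print it. Efficiency% = 100·(10^(1/|slope|) − 1).
R² is orientation-independent for simple linear regression, so the choice
of regressing Cq on input (rather than the reverse) cannot affect it. A
series whose Cq does not decrease with input is rejected as non-amplifying;
fewer than three distinct dilution points is an error. Efficiencies are
displayed at one decimal; all stored values keep full precision.

## Screening model

Per gene and timepoint, on replicate-averaged Cq:

* Fixed effects: `cell_type * activation` (2×2 with interaction).
* Random effects: donor intercept plus a donor-level activation effect
  ("this donor responds strongly"), fitted by REML via statsmodels MixedLM.
  If the donor-activation variance component is singular the model is
  refitted with the intercept only (logged). If the residual variance is
  itself degenerate (noiseless data), the fixed effects fall back to OLS,
  which is exact on the balanced design.

All six pairwise contrasts of the four subgroup means are formed from the
fixed-effect covariance. Family-wise adjustment uses the studentized-range
distribution with k = 4 means — the classic Tukey construction for all
pairwise comparisons of estimated marginal means. Degrees of freedom are
fixed at n_donors − 1, the paired-design containment value; this is
deliberately conservative (the null simulations below measure a family-wise
error near 2–3% at nominal 5%). A Satterthwaite/Kenward–Roger approximation
would sharpen the per-contrast df but adds no power where the screening
effects of interest are several standard errors wide.

The exclusion rule is dual and strict: adjusted p < α (default 0.05) AND
|contrast| > `min_effect` (default 0.5 Cq). Both inequalities are strict.
Normality per (gene, subgroup) is reported with the Lilliefors-corrected KS
test and never gated on; zero-variance cells report a flag instead of a
p-value.

Each activation timepoint is screened as a separate dataset.

## Stability algorithms

Inputs follow each method's original description: geNorm and NormFinder
take efficiency-corrected linear relative quantities
Q = E^(Cq_min − Cq) (log-transformed internally); BestKeeper, ΔCq and ΔCq·M
take raw replicate-averaged Cq. Sample SDs use the n−1 denominator
throughout. The minimum-Cq reference sample for Q is global across the
samples entering an analysis, not per subgroup.

* **geNorm.** M_j = mean over partners k of SD(log₂(Q_j/Q_k)). The ranking
  table reports full-panel M values; stepwise exclusion of the argmax-M gene
  (recomputed each round) determines the final pair — which by construction
  shares one identical last M — and the gene order used for normalization
  factors. V(n, n+1) = SD over samples of log₂(NF_n/NF_{n+1}), NF_n being
  the geometric mean of the n most stable genes' quantities; the optimal
  panel size is the smallest n with V < 0.15 (G if never reached). M < 0.5
  indicates high stability, M ≤ 1 is acceptable in heterogeneous panels.
* **NormFinder.** On log₂ quantities centered per sample by the
  candidate-set average, per group g and gene i the naive variances s²_ig
  are corrected for the centering coupling,
  σ²_ig = (s²_ig − s̄²_g/(k−1))·k/(k−2), clamped at 0 (hence k ≥ 3 genes).
  Inter-group differences d_ig = z̄_ig − mean_g z̄_ig are shrunken by
  γ²/(γ² + σ²_ig/n_g), with γ² the method-of-moments variance of the d's in
  excess of sampling noise. Stability = mean over groups of
  |d̃_ig| + √(posterior variance); the best two-gene combination averages
  the shrunken biases (so opposite-sign biases cancel) and quarter-sums the
  variances. Default grouping is the four subgroups; any sample grouping can
  be passed instead (e.g. two groups by activation) since the partition the
  original workflow used is not documented.
* **BestKeeper.** Per-gene Cq SD and CV for every gene; index = per-sample
  geometric mean of the included genes' Cq; Pearson r of each non-excluded
  gene against an index built without the exclusion set. Exclusion from the
  correlation step is user-supplied (heterogeneous variance invalidates
  Pearson r when expression levels differ grossly); an advisory flag fires
  automatically when a gene's mean Cq deviates from the panel mean by more
  than 5 cycles, but nothing is excluded silently. SD > 1 Cq flags a gene
  unstable. Raw Cq is used rather than efficiency-corrected values — the
  tool's classical input.
* **ΔCq.** Gene score = mean over partners of SD(within-sample Cq
  difference). Shift-invariant per gene by construction.
* **ΔCq·M.** Per group pair: |mean Cq(a) − mean Cq(b)| · M_gene, ranked
  ascending within each comparison; the comprehensive order is the
  geometric mean of per-comparison ranks. Default comparisons are all six
  subgroup pairs; a restricted "biologically relevant" subset can be passed,
  since which pairs the original workflow aggregated is not documented.

**Consensus.** Geometric mean of the five per-method ranks (ties within a
method share the average rank); ties on the geometric mean are broken by
arithmetic mean rank, then lexicographically, and are always reported.

**Degradation.** With fewer than three surviving candidates the multi-gene
algorithms are undefined; the analysis then reports BestKeeper SD only
(the one score that is independent of the other genes), with an explicit
notice rather than an error.

## Fold-change validation

Per donor with both paired states, ratio = E_t^(ΔCq_t) / R_ref with
ΔCq = Cq_rest − Cq_act and R_ref the geometric mean of the per-reference
efficiency-corrected ratios (for a single reference this is the textbook
efficiency-corrected 2^−ΔΔCq). log₂ fold changes are computed per donor and
then summarized by mean and SD across donors — not averaged on the linear
scale. Donors missing either paired sample are skipped and listed. A
reference whose Cq drops by δ under activation biases every donor's log₂FC
by exactly −δ·log₂(E_ref); a noiseless test asserts this identity. The
optional significance annotation refits the screening mixed model on the
per-sample normalized log₂ values and reports the Tukey-adjusted activation
contrast for the requested cell type.

## Synthetic data generator

Cq(g,d,c,a,t,r) = baseline(g) + ct_shift(g)·1[EM] + act_shift(g,t,c)·1[act]
+ b_d + u_d·1[act] + ε + ε_rep, all Gaussian on the Cq scale. b_d and u_d
are donor-level and shared across genes (the simplest structure that
produces donor-dependent activation); per-gene donor slopes are out of
scope. ε is drawn per (gene, donor, cell type, state, timepoint) with a
per-gene SD, ε_rep per technical replicate. Per-gene RNG streams are derived
from the root seed by hashing the gene symbol (CRC32), so adding a gene
never perturbs the other genes' draws.

`tcell_panel_config()` encodes the default study conditions: 13 genes
(12 candidate references + an IFNG-like induced target), 11 paired donors,
duplicates, timepoints 2/10/20 h, donor SD 0.35, donor-activation SD 0.15,
replicate SD 0.1 Cq. Baselines span 6.9 (18S rRNA) to 28.5 (HMBS) Cq.
Ground-truth stability is expressed two ways, both mirroring what published
panels report: the stable genes (18S rRNA, SDHA) have zero planted shifts
*and* the lowest biological residual SDs (0.25/0.30 Cq, giving
within-subgroup SDs ≈ 0.4), while the other genes carry residual SDs of
0.5–0.8 Cq (subgroup SDs ≈ 0.6–0.9, e.g. a CASC3-like gene at 0.9). Planted
activation shifts are −1.2 to −3 Cq (negative = induction) for genes meant
to be detected, chosen to sit clearly above the 0.5-Cq exclusion threshold
at these sample sizes; the second-tier genes (B2M, CASC3, IPO8, RPLP0,
UBE2D2) are flat at 2 h and induced at 10/20 h, so late timepoints leave
only two stable candidates and exercise the degradation path. Where only
qualitative patterns were available, magnitudes are our interpolation — the
generator emulates the *structure* of such experiments, not any particular
dataset.

What the generator does **not** emulate: non-Gaussian/heavy-tailed Cq noise,
plate and position effects, PCR inhibition, per-gene donor-response slopes,
co-regulation between candidate genes, and missingness patterns other than
dropped samples. Passing the planted-truth tests therefore shows the
algorithms and their wiring are correct under the assumed noise model; it
does not certify performance on data violating those assumptions.

## Problem sizes and numerical choices

The planted-truth acceptance test runs 100 simulation seeds of the 2 h
panel (each: 13 mixed-model fits + the five-method ranking) and the null
calibration runs 1000 single-gene seeds; `scripts/acceptance.py` uses 60
and 400 seeds respectively — sizes at which the binomial uncertainty of the
reported rates is a few percent, adequate for the thresholds being checked.
Oracle-equivalence checks use 50 random 5-gene × 20-sample matrices at
tolerance 1e-10. Ties in any ranking are broken deterministically
(mean rank, then gene symbol). Singular mixed-model fits downgrade as
described above; zero-variance cells and constant indices report flags, not
numbers. All randomness flows from a single root seed.

## Known limitations

* Contrast p-values depend on the df convention; exact agreement with other
  software's Satterthwaite/KR p-values is not expected (estimates and SEs
  agree on balanced designs).
* NormFinder is implemented from its published model; spreadsheet/script
  implementations differ in minor correction factors, so stability *values*
  may differ in the third decimal while orderings agree.
* BestKeeper's Pearson correlations are descriptive; no significance-based
  selection is performed on them.
* The geometric-mean consensus weights all five methods equally, inheriting
  their shared sensitivity to variance (four of five methods are
  variance-driven, so the consensus is not five independent votes).
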