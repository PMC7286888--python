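# refstab

Reference-gene stability evaluation for RT-qPCR experiments.

Quantitative RT-PCR measures a target transcript *relative to* one or more
reference ("housekeeping") genes, on the assumption that the reference does
not respond to the experimental conditions. That assumption routinely fails:
classic references such as *GAPDH* or *ACTB* are themselves regulated by
cell-type differences and activation stimuli, and normalizing to a regulated
reference silently biases every fold change by the reference's own shift.
`refstab` implements the complete validation workflow a careful qPCR study
runs before trusting a normalizer, aimed at experiments with a paired
design — e.g. matched donors contributing naive (NV) and effector-memory
(EM) CD8⁺ T-cell samples, each measured non-activated and activated at one
or more timepoints.

## What it computes

**Standard curves.** For each primer pair, ordinary least squares of Cq on
log₁₀ relative input over a dilution series gives the slope (reported as a
positive magnitude), R², and the per-cycle amplification efficiency

```
efficiency% = 100 · (10^(1/|slope|) − 1),      E = 1 + efficiency/100
```

so |slope| = 1/log₁₀2 ≈ 3.3219 means perfect doubling (E = 2).

**Subgroup screening.** Per gene and activation timepoint, a linear
mixed-effects model (REML)

```
Cq ~ cell_type * activation  +  (donor intercept)  +  (donor × activation)
```

yields all six pairwise contrasts of the four subgroup means
(NV/EM × rest/activated) with Tukey family-wise adjusted p-values. A gene is
excluded from reference candidacy iff some contrast has adjusted p < 0.05
**and** |estimate| > 0.5 Cq (both strict). Normality per (gene, subgroup) is
reported via the Lilliefors-corrected Kolmogorov–Smirnov test.

**Five stability algorithms** on the screened candidates, each per its
original description: geNorm (average pairwise log-ratio SD *M*, stepwise
exclusion, pairwise variation V(n, n+1) with the 0.15 cutoff), NormFinder
(model-based intra/inter-group variance decomposition on log quantities),
BestKeeper (Cq SD/CV and Pearson correlation with the geometric-mean index),
ΔCq (mean SD of within-sample pairwise Cq differences) and ΔCq·M
(|group-mean Cq difference| × M). The consensus is the geometric mean of the
per-method ranks.

**Validation.** Efficiency-corrected fold changes (2^−ΔΔCq generalized to
per-gene bases E) of a target between paired activated/non-activated
samples, per donor, under any choice of reference panel — making the cost of
a bad normalizer directly visible.

**Synthetic data.** A generator with donor random effects, a donor-level
activation effect, per-gene biological noise and technical replicates
produces datasets with planted ground truth (which genes are stable, which
are induced and by how much), so the whole pipeline is testable end to end
without access to any lab's raw data.

## Worked example

```python
from refstab import *
from refstab.data import subset_timepoint

cfg = tcell_panel_config(seed=1)            # 13-gene T-cell panel, 11 donors
ds, truth = simulate_cq_dataset(cfg, seed=1)
ds.efficiencies.update(tcell_panel_efficiencies())
coll = collapse_replicates(ds)             # average technical duplicates

sub = subset_timepoint(coll, 2.0)          # 2 h activation dataset
report = screen_genes(sub, genes=[g for g in ds.genes if g != "IFNG"])
print(report.stable_genes)
# ['B2M', 'CASC3', 'IPO8', 'RPLP0', 'SDHA', 'UBE2D2', '18S rRNA']

stab = StabilityAnalysis(sub, genes=report.stable_genes).fit()
print(stab.summary().round(3))
#           genorm_m  normfinder_value  delta_cq_mean_sd  bestkeeper_sd  consensus_position
# 18S rRNA     0.546             0.057             0.575          0.398                   1
# SDHA         0.549             0.055             0.578          0.402                   2
# RPLP0        0.686             0.149             0.718          0.520                   3
# ...
# CASC3        0.901             0.236             0.952          0.899                   7
```

Five classic housekeeping genes (ACTB, GAPDH, HMBS, HPRT1, PPIB) are
screened out already at 2 h; among the survivors the consensus puts the two
genes simulated as truly stable (18S rRNA, SDHA) on top. At 10 h and 20 h
only those two pass screening, so the multi-gene algorithms are skipped and
only BestKeeper's per-gene SD is reported — exactly the degradation a real
late-activation dataset forces.

The price of a regulated reference, on the same simulation:

```python
good = ddcq_fold_change(coll, "IFNG", ["18S rRNA"], "NV", 20.0)
bad  = ddcq_fold_change(coll, "IFNG", ["GAPDH"],    "NV", 20.0)
print(good.summary())   # IFNG vs 18S rRNA [NV, 20 h]: mean log2FC = 6.47 (SD 0.87, n = 11)
print(bad.summary())    # IFNG vs GAPDH    [NV, 20 h]: mean log2FC = 4.35 (SD 0.85, n = 11)
fold_ratio_between_normalizations(good.mean_log2fc, bad.mean_log2fc)  # 4.3
```

The IFNG-like target is induced ~6.5 log₂ units, but normalized to the
activation-induced GAPDH-like gene the induction is under-reported more than
4-fold — the bias equals the reference's own planted Cq shift times log₂(E).

A command-line interface mirrors the library
(`refstab simulate | curves | screen | stability | validate | run-all`);
`refstab run-all --seed 1 --outdir out/` writes all TSV/JSON reports plus a
reproducibility manifest.

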