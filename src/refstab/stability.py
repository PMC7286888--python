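"""Five reference-gene stability algorithms and their consensus ranking.

Inputs follow each method's original description: geNorm and NormFinder work
on efficiency-corrected linear relative quantities (log-transformed where
the method requires); BestKeeper, the deltaCq method and deltaCq*M work on
raw Cq values. Sample standard deviations (ddof = 1) are used throughout.

* geNorm: stability M = mean SD of a gene's pairwise log2 expression ratios
  with every other candidate; stepwise exclusion of the worst gene; pairwise
  variation V(n, n+1) between normalization factors decides how many
  reference genes are enough (V < 0.15 by convention).
* NormFinder: a model-based decomposition, on the log scale after centering
  each sample by the candidate-set average, into per-(gene, group)
  intra-group variance and inter-group bias of gene-specific group means;
  the stability value combines the variance-shrunken absolute bias with the
  intra-group variation. Lower is more stable.
* BestKeeper: per-gene Cq SD and coefficient of variation; the BestKeeper
  index is the per-sample geometric mean of the included genes' Cq values,
  and each gene's Pearson correlation with the index is reported. SD > 1 Cq
  flags a gene as unstable.
* deltaCq: for every gene pair, the SD across samples of within-sample Cq
  differences; a gene's score is the mean of its pair SDs.
* deltaCq*M: |group-mean Cq difference| x geNorm M per gene and group pair,
  ranked within each comparison and aggregated by the geometric mean of
  ranks.

The consensus ranking is the geometric mean of the per-method ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .data import CqDataset, collapse_replicates
from .standard_curve import cq_to_relative_quantity

__all__ = [
    "QuantityMatrix",
    "StabilityThresholds",
    "quantity_matrix",
    "cq_matrix",
    "genorm",
    "normfinder",
    "bestkeeper",
    "delta_cq_stability",
    "delta_cq_m",
    "consensus_rank",
    "StabilityAnalysis",
    "StabilityReport",
]


@dataclass(frozen=True)
class StabilityThresholds:
    v_cutoff: float = 0.15  # pairwise variation: adding one more gene unnecessary
    m_high_stability: float = 0.5  # geNorm M below this = highly stable
    m_acceptable: float = 1.0  # accepted in heterogeneous panels
    sd_unstable: float = 1.0  # BestKeeper: SD > 1 Cq = unstable


@dataclass
class QuantityMatrix:
    """Genes x samples matrix of efficiency-corrected linear quantities.

    Every entry lies in (0, 1]; per gene the maximum is exactly 1 (the
    lowest-Cq sample is the reference).
    """

    values: pd.DataFrame  # index: genes, columns: sample ids
    sample_info: pd.DataFrame  # index: sample ids; donor_id, cell_type, activated, subgroup
    efficiencies: dict[str, float]

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        if not np.all(v > 0):
            raise ValueError("relative quantities must be strictly positive")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subgroups(self) -> pd.Series:
        return self.sample_info["subgroup"]


def _sample_table(ds: CqDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot a (collapsed) dataset to genes x samples, plus sample annotations."""
    work = ds
    if ds.data.duplicated(["gene", "donor_id", "cell_type", "activated", "timepoint_h"]).any():
        work = collapse_replicates(ds)
    d = work.data.copy()
    d["sample_id"] = [
        f"{r.donor_id}|{r.cell_type}|{'act' if r.activated else 'rest'}|{r.timepoint_h:g}h"
        for r in d.itertuples()
    ]
    wide = d.pivot(index="gene", columns="sample_id", values="cq")
    if wide.isna().any().any():
        wide = wide.dropna(axis=1)  # keep only samples measured for every gene
    info = (
        d.drop_duplicates("sample_id")
        .set_index("sample_id")[["donor_id", "cell_type", "activated", "timepoint_h", "subgroup"]]
        .loc[wide.columns]
    )
    return wide.loc[ds.genes if set(ds.genes) <= set(wide.index) else wide.index], info


def cq_matrix(ds: CqDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-averaged raw Cq matrix (genes x samples) with annotations."""
    return _sample_table(ds)


def quantity_matrix(ds: CqDataset, genes: Sequence[str] | None = None) -> QuantityMatrix:
    """Efficiency-corrected linear relative quantities from a dataset."""
    wide, info = _sample_table(ds)
    if genes is not None:
        wide = wide.loc[list(genes)]
    q = pd.DataFrame(
        {g: cq_to_relative_quantity(wide.loc[g].to_numpy(), ds.efficiencies[g]) for g in wide.index},
        index=wide.columns,
    ).T
    return QuantityMatrix(values=q, sample_info=info, efficiencies=dict(ds.efficiencies))


# --------------------------------------------------------------------------
# geNorm
# --------------------------------------------------------------------------


@dataclass
class GeNormResult:
    m_values: dict[str, float]  # full-panel M per gene (what rankings report)
    exclusion_order: list[str]  # least to most stable
    final_pair: tuple[str, str]
    final_pair_m: float
    v_series: dict[int, float]  # n -> V(n, n+1)
    optimal_n: int
    stepwise_m: list[dict[str, float]] = field(default_factory=list)

    def ranks(self) -> dict[str, float]:
        genes = list(self.m_values)
        r = rankdata([self.m_values[g] for g in genes])
        return dict(zip(genes, r.tolist()))


def _pairwise_log_sd(logq: np.ndarray) -> np.ndarray:
    """Matrix of SD(log-ratio) for all gene pairs; diagonal zero."""
    g = logq.shape[0]
    V = np.zeros((g, g))
    for j, k in combinations(range(g), 2):
        V[j, k] = V[k, j] = np.std(logq[j] - logq[k], ddof=1)
    return V


def genorm(
    q: QuantityMatrix, thresholds: StabilityThresholds = StabilityThresholds()
) -> GeNormResult:
    genes = q.genes
    if len(genes) < 3:
        raise ValueError("geNorm stepwise exclusion needs >= 3 genes")
    if q.n_samples < 2:
        raise ValueError("geNorm needs >= 2 samples")
    logq = np.log2(q.values.to_numpy(float))

    # full-panel M values (these are what stability tables report)
    V = _pairwise_log_sd(logq)
    m_full = V.sum(axis=1) / (len(genes) - 1)
    m_values = dict(zip(genes, m_full.tolist()))

    # stepwise exclusion of the least stable gene
    remaining = list(range(len(genes)))
    exclusion: list[str] = []
    stepwise: list[dict[str, float]] = []
    while len(remaining) > 2:
        sub = np.ix_(remaining, remaining)
        m = V[sub].sum(axis=1) / (len(remaining) - 1)
        stepwise.append({genes[i]: float(mi) for i, mi in zip(remaining, m)})
        worst_local = int(np.argmax(m))
        # deterministic tie-break: first max by current order
        exclusion.append(genes[remaining[worst_local]])
        remaining.pop(worst_local)
    pair = (genes[remaining[0]], genes[remaining[1]])
    final_m = float(V[remaining[0], remaining[1]])  # both share SD of their log-ratio
    stepwise.append({pair[0]: final_m, pair[1]: final_m})

    # stability order, most stable first: final pair (by full-panel M), then
    # reverse exclusion order
    pair_sorted = sorted(pair, key=lambda g: (m_values[g], g))
    order = list(pair_sorted) + exclusion[::-1]

    # pairwise variation V(n, n+1) between normalization factors
    idx = {g: i for i, g in enumerate(genes)}
    v_series: dict[int, float] = {}
    for n in range(2, len(genes)):
        top_n = [idx[g] for g in order[:n]]
        top_n1 = [idx[g] for g in order[: n + 1]]
        nf_n = logq[top_n].mean(axis=0)  # log2 of geometric mean
        nf_n1 = logq[top_n1].mean(axis=0)
        v_series[n] = float(np.std(nf_n - nf_n1, ddof=1))
    optimal_n = next(
        (n for n in sorted(v_series) if v_series[n] < thresholds.v_cutoff), len(genes)
    )
    return GeNormResult(
        m_values=m_values,
        exclusion_order=exclusion,
        final_pair=pair,
        final_pair_m=final_m,
        v_series=v_series,
        optimal_n=optimal_n,
        stepwise_m=stepwise,
    )


# --------------------------------------------------------------------------
# NormFinder
# --------------------------------------------------------------------------


@dataclass
class NormFinderResult:
    stability_values: dict[str, float]
    intra_group_variances: pd.DataFrame  # genes x groups
    group_differences: pd.DataFrame  # genes x groups (shrunken)
    groups: list[str]
    best_gene: str
    best_pair: tuple[str, str]
    best_pair_value: float

    def ranks(self) -> dict[str, float]:
        genes = list(self.stability_values)
        r = rankdata([self.stability_values[g] for g in genes])
        return dict(zip(genes, r.tolist()))


def _normfinder_intra_variance(z: np.ndarray) -> np.ndarray:
    """Unbiased per-gene intra-group variances from sample-centered log data.

    ``z`` is genes x samples for ONE group, already centered by the per-sample
    candidate-set average. Centering couples the genes, so the naive sample
    variances s2_i are corrected via
        sigma2_i = (s2_i - mean(s2)/(k-1)) * k/(k-2),   k = number of genes,
    clamped at zero.
    """
    k = z.shape[0]
    if k < 3:
        raise ValueError("NormFinder variance decomposition needs >= 3 genes")
    s2 = np.var(z, axis=1, ddof=1)
    sigma2 = (s2 - s2.mean() / (k - 1)) * k / (k - 2)
    return np.clip(sigma2, 0.0, None)


def normfinder(
    q: QuantityMatrix, groups: Sequence[str] | None = None
) -> NormFinderResult:
    """Model-based stability values on log quantities, grouped by subgroup.

    ``groups`` assigns each sample to a group; defaults to the 4 subgroup
    labels carried by the matrix. Lower stability value = more stable.
    """
    genes = q.genes
    if len(genes) < 3:
        raise ValueError("NormFinder needs >= 3 genes")
    if groups is None:
        groups = q.subgroups().tolist()
    groups = list(groups)
    if len(groups) != q.n_samples:
        raise ValueError("groups must label every sample")
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("NormFinder needs >= 2 groups")

    y = np.log2(q.values.to_numpy(float))
    z = y - y.mean(axis=0, keepdims=True)  # center by candidate-set average
    garr = np.asarray(groups)

    k, G = len(genes), len(labels)
    sigma2 = np.zeros((k, G))
    zbar = np.zeros((k, G))
    n_g = np.zeros(G)
    for gi, lab in enumerate(labels):
        cols = garr == lab
        n_g[gi] = cols.sum()
        if n_g[gi] < 2:
            raise ValueError(f"group {lab!r} has < 2 samples")
        sigma2[:, gi] = _normfinder_intra_variance(z[:, cols])
        zbar[:, gi] = z[:, cols].mean(axis=1)

    d = zbar - zbar.mean(axis=1, keepdims=True)  # inter-group differences
    c = sigma2 / n_g  # sampling variance of each d entry (approx.)
    if G > 1 and k > 1:
        gamma2 = max(0.0, (d**2).sum() / ((k - 1) * (G - 1)) - c.mean())
    else:
        gamma2 = 0.0
    shrink = gamma2 / (gamma2 + c) if gamma2 > 0 else np.zeros_like(c)
    d_tilde = d * shrink
    var_tilde = gamma2 * c / (gamma2 + c) if gamma2 > 0 else c

    rho = (np.abs(d_tilde) + np.sqrt(var_tilde)).mean(axis=1)
    stability = dict(zip(genes, rho.tolist()))
    best_gene = min(genes, key=lambda g: (stability[g], g))

    # best two-gene combination: biases average (opposite signs cancel),
    # variances average with 1/2 weight each
    best_pair, best_val = None, np.inf
    for i, j in combinations(range(k), 2):
        dp = (d_tilde[i] + d_tilde[j]) / 2.0
        vp = (var_tilde[i] + var_tilde[j]) / 4.0
        val = float((np.abs(dp) + np.sqrt(vp)).mean())
        if val < best_val:
            best_val, best_pair = val, (genes[i], genes[j])

    return NormFinderResult(
        stability_values=stability,
        intra_group_variances=pd.DataFrame(sigma2, index=genes, columns=labels),
        group_differences=pd.DataFrame(d_tilde, index=genes, columns=labels),
        groups=labels,
        best_gene=best_gene,
        best_pair=best_pair,
        best_pair_value=best_val,
    )


# --------------------------------------------------------------------------
# BestKeeper
# --------------------------------------------------------------------------


@dataclass
class BestKeeperResult:
    sd_values: dict[str, float]
    cv_values: dict[str, float]
    index: pd.Series  # per-sample geometric mean Cq of included genes
    correlations: dict[str, float]
    correlation_p: dict[str, float]
    excluded_from_correlation: list[str]
    unstable_genes: list[str]  # SD above threshold
    advisory_heterogeneous: list[str]  # mean Cq far from panel mean

    def ranks(self) -> dict[str, float]:
        genes = list(self.sd_values)
        r = rankdata([self.sd_values[g] for g in genes])
        return dict(zip(genes, r.tolist()))


def bestkeeper(
    cq: pd.DataFrame,
    include_in_index: Sequence[str] | None = None,
    exclude_from_correlation: Sequence[str] | None = None,
    thresholds: StabilityThresholds = StabilityThresholds(),
) -> BestKeeperResult:
    """Descriptive Cq variability plus correlation with the BestKeeper index.

    ``cq`` is a genes x samples matrix of raw (replicate-averaged) Cq values.
    SD/CV are reported for every gene regardless of index membership. The
    correlation for each non-excluded gene is computed against an index built
    from the included genes minus the exclusion set (a gene whose expression
    level is wildly different — advisory flag at |mean - panel mean| > 5 Cq —
    has heterogeneous variance, where a Pearson coefficient is not valid).
    """
    genes = list(cq.index)
    if cq.shape[1] < 3:
        raise ValueError("BestKeeper needs >= 3 samples")
    include = list(include_in_index) if include_in_index is not None else genes
    if not include:
        raise ValueError("include_in_index must contain >= 1 gene")
    exclude = list(exclude_from_correlation or [])

    arr = cq.to_numpy(float)
    sd = {g: float(np.std(cq.loc[g], ddof=1)) for g in genes}
    cv = {g: 100.0 * sd[g] / float(np.mean(cq.loc[g])) for g in genes}

    index_genes = [g for g in include if g not in exclude]
    if not index_genes:
        raise ValueError("no genes left in the index after exclusions")
    index = np.exp(np.log(cq.loc[index_genes].to_numpy(float)).mean(axis=0))
    index_s = pd.Series(index, index=cq.columns, name="bestkeeper_index")

    correlations: dict[str, float] = {}
    corr_p: dict[str, float] = {}
    if np.ptp(index) == 0.0:
        for g in genes:
            if g not in exclude:
                correlations[g] = np.nan
                corr_p[g] = np.nan
    else:
        for g in genes:
            if g in exclude:
                continue
            x = cq.loc[g].to_numpy(float)
            if np.ptp(x) == 0.0:
                correlations[g], corr_p[g] = np.nan, np.nan
            else:
                r, p = pearsonr(x, index)
                correlations[g], corr_p[g] = float(r), float(p)

    panel_mean = float(arr.mean())
    advisory = [g for g in genes if abs(float(np.mean(cq.loc[g])) - panel_mean) > 5.0]
    unstable = [g for g in genes if sd[g] > thresholds.sd_unstable]
    return BestKeeperResult(
        sd_values=sd,
        cv_values=cv,
        index=index_s,
        correlations=correlations,
        correlation_p=corr_p,
        excluded_from_correlation=exclude,
        unstable_genes=unstable,
        advisory_heterogeneous=advisory,
    )


# --------------------------------------------------------------------------
# deltaCq and deltaCq*M
# --------------------------------------------------------------------------


@dataclass
class DeltaCqResult:
    mean_sd: dict[str, float]
    pair_sd: pd.DataFrame  # symmetric genes x genes SD matrix

    def ranks(self) -> dict[str, float]:
        genes = list(self.mean_sd)
        r = rankdata([self.mean_sd[g] for g in genes])
        return dict(zip(genes, r.tolist()))


def delta_cq_stability(cq: pd.DataFrame) -> DeltaCqResult:
    """SD of within-sample Cq differences over all gene pairs."""
    genes = list(cq.index)
    if len(genes) < 2:
        raise ValueError("deltaCq needs >= 2 genes")
    if cq.shape[1] < 2:
        raise ValueError("deltaCq needs >= 2 samples")
    arr = cq.to_numpy(float)
    g = len(genes)
    M = np.zeros((g, g))
    for j, k in combinations(range(g), 2):
        M[j, k] = M[k, j] = np.std(arr[j] - arr[k], ddof=1)
    mean_sd = dict(zip(genes, (M.sum(axis=1) / (g - 1)).tolist()))
    return DeltaCqResult(
        mean_sd=mean_sd, pair_sd=pd.DataFrame(M, index=genes, columns=genes)
    )


@dataclass
class DeltaCqMResult:
    per_comparison: dict[tuple[str, str], dict[str, float]]
    per_comparison_ranks: dict[tuple[str, str], dict[str, float]]
    comprehensive_gm: dict[str, float]
    comprehensive_rank: list[str]
    comparisons_used: list[tuple[str, str]]

    def ranks(self) -> dict[str, float]:
        genes = list(self.comprehensive_gm)
        r = rankdata([self.comprehensive_gm[g] for g in genes])
        return dict(zip(genes, r.tolist()))


def delta_cq_m(
    cq: pd.DataFrame,
    groups: Sequence[str],
    m_values: Mapping[str, float],
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> DeltaCqMResult:
    """Group-bias penalty: |mean Cq difference between two groups| x geNorm M.

    Ranked ascending within each group-pair comparison; the comprehensive
    ranking orders genes by the geometric mean of those per-comparison ranks.
    Default comparisons: all unordered pairs of observed groups.
    """
    genes = list(cq.index)
    missing = [g for g in genes if g not in m_values]
    if missing:
        raise ValueError(f"missing geNorm M value for: {missing}")
    garr = np.asarray(list(groups))
    if len(garr) != cq.shape[1]:
        raise ValueError("groups must label every sample column")
    labels = sorted(set(garr.tolist()))
    if comparisons is None:
        comparisons = list(combinations(labels, 2))
    comparisons = [tuple(c) for c in comparisons]
    for a, b in comparisons:
        for lab in (a, b):
            if (garr == lab).sum() == 0:
                raise ValueError(f"comparison references empty group {lab!r}")

    per_comp: dict[tuple[str, str], dict[str, float]] = {}
    per_ranks: dict[tuple[str, str], dict[str, float]] = {}
    for a, b in comparisons:
        ca, cb = garr == a, garr == b
        vals = {
            g: abs(float(cq.loc[g, cq.columns[ca]].mean() - cq.loc[g, cq.columns[cb]].mean()))
            * float(m_values[g])
            for g in genes
        }
        per_comp[(a, b)] = vals
        r = rankdata([vals[g] for g in genes])
        per_ranks[(a, b)] = dict(zip(genes, r.tolist()))

    gm = {
        g: float(np.exp(np.mean([np.log(per_ranks[c][g]) for c in per_comp])))
        for g in genes
    }
    order = sorted(genes, key=lambda g: (gm[g], np.mean([per_ranks[c][g] for c in per_comp]), g))
    return DeltaCqMResult(
        per_comparison=per_comp,
        per_comparison_ranks=per_ranks,
        comprehensive_gm=gm,
        comprehensive_rank=order,
        comparisons_used=comparisons,
    )


# --------------------------------------------------------------------------
# consensus
# --------------------------------------------------------------------------


@dataclass
class ConsensusRanking:
    per_method_ranks: dict[str, dict[str, float]]
    geo_mean_rank: dict[str, float]
    final_order: list[str]
    ties: list[tuple[str, str]]

    def position(self, gene: str) -> int:
        return self.final_order.index(gene) + 1


def consensus_rank(per_method_ranks: Mapping[str, Mapping[str, float]]) -> ConsensusRanking:
    """Geometric mean of per-method ranks; ascending = most stable first.

    Ties on the geometric mean are broken by arithmetic mean rank, then by
    gene symbol; tied pairs are reported.
    """
    methods = list(per_method_ranks)
    if not methods:
        raise ValueError("need at least one method")
    gene_sets = {m: frozenset(per_method_ranks[m]) for m in methods}
    ref = gene_sets[methods[0]]
    for m, s in gene_sets.items():
        if s != ref:
            diff = sorted(ref ^ s)
            raise ValueError(f"method {m!r} ranks a different gene set; difference: {diff}")
    genes = sorted(ref)
    gm = {
        g: float(np.exp(np.mean([np.log(per_method_ranks[m][g]) for m in methods])))
        for g in genes
    }
    am = {g: float(np.mean([per_method_ranks[m][g] for m in methods])) for g in genes}
    order = sorted(genes, key=lambda g: (gm[g], am[g], g))
    ties = [
        (a, b)
        for a, b in combinations(genes, 2)
        if np.isclose(gm[a], gm[b], rtol=0, atol=1e-12)
    ]
    return ConsensusRanking(
        per_method_ranks={m: dict(per_method_ranks[m]) for m in methods},
        geo_mean_rank=gm,
        final_order=order,
        ties=ties,
    )


# --------------------------------------------------------------------------
# facade
# --------------------------------------------------------------------------


@dataclass
class StabilityReport:
    """Per-method scores/ranks and the consensus for one candidate panel."""

    genes: list[str]
    genorm_result: GeNormResult | None
    normfinder_result: NormFinderResult | None
    bestkeeper_result: BestKeeperResult
    delta_cq_result: DeltaCqResult | None
    delta_cq_m_result: DeltaCqMResult | None
    consensus: ConsensusRanking | None
    thresholds: StabilityThresholds
    degraded: bool = False
    notice: str | None = None

    def summary(self) -> pd.DataFrame:
        """Table-style summary: one score + rank column block per method."""
        df = pd.DataFrame(index=self.genes)
        bk = self.bestkeeper_result
        df["bestkeeper_sd"] = [bk.sd_values[g] for g in self.genes]
        df["bestkeeper_rank"] = [bk.ranks()[g] for g in self.genes]
        if not self.degraded:
            nf, dc, gn, dm = (
                self.normfinder_result,
                self.delta_cq_result,
                self.genorm_result,
                self.delta_cq_m_result,
            )
            df["normfinder_value"] = [nf.stability_values[g] for g in self.genes]
            df["normfinder_rank"] = [nf.ranks()[g] for g in self.genes]
            df["delta_cq_mean_sd"] = [dc.mean_sd[g] for g in self.genes]
            df["delta_cq_rank"] = [dc.ranks()[g] for g in self.genes]
            df["genorm_m"] = [gn.m_values[g] for g in self.genes]
            df["genorm_rank"] = [gn.ranks()[g] for g in self.genes]
            df["delta_cq_m_gm_rank"] = [dm.comprehensive_gm[g] for g in self.genes]
            df["delta_cq_m_rank"] = [dm.ranks()[g] for g in self.genes]
            df["consensus_gm_rank"] = [self.consensus.geo_mean_rank[g] for g in self.genes]
            df["consensus_position"] = [self.consensus.position(g) for g in self.genes]
            df = df.sort_values("consensus_position")
        else:
            df = df.sort_values("bestkeeper_rank")
        return df

    def to_jsonable(self) -> dict:
        out: dict = {
            "genes": self.genes,
            "degraded": self.degraded,
            "notice": self.notice,
            "thresholds": vars(self.thresholds),
            "bestkeeper": {
                "sd": self.bestkeeper_result.sd_values,
                "unstable": self.bestkeeper_result.unstable_genes,
            },
        }
        if not self.degraded:
            out["genorm"] = {
                "m_values": self.genorm_result.m_values,
                "v_series": {str(k): v for k, v in self.genorm_result.v_series.items()},
                "optimal_n": self.genorm_result.optimal_n,
                "final_pair": list(self.genorm_result.final_pair),
            }
            out["normfinder"] = {
                "stability_values": self.normfinder_result.stability_values,
                "best_gene": self.normfinder_result.best_gene,
                "best_pair": list(self.normfinder_result.best_pair),
                "best_pair_value": self.normfinder_result.best_pair_value,
            }
            out["consensus_order"] = self.consensus.final_order
        return out


class StabilityAnalysis:
    """Run the five-method panel on a screened candidate set.

    Build from a single-timepoint :class:`CqDataset` (replicates are averaged
    internally) and call :meth:`fit`. With fewer than 3 candidate genes the
    multi-gene algorithms are undefined and the analysis degrades to
    BestKeeper's SD report with an explanatory notice.
    """

    def __init__(
        self,
        ds: CqDataset,
        genes: Sequence[str] | None = None,
        normfinder_groups: Sequence[str] | None = None,
        delta_cq_m_comparisons: Sequence[tuple[str, str]] | None = None,
        bestkeeper_exclude_from_correlation: Sequence[str] | None = None,
        thresholds: StabilityThresholds = StabilityThresholds(),
    ):
        self.ds = ds
        self.genes = list(genes) if genes is not None else ds.genes
        self.normfinder_groups = normfinder_groups
        self.delta_cq_m_comparisons = delta_cq_m_comparisons
        self.bk_exclude = list(bestkeeper_exclude_from_correlation or [])
        self.thresholds = thresholds

    def fit(self) -> StabilityReport:
        wide, info = cq_matrix(self.ds)
        wide = wide.loc[self.genes]
        bk_all = bestkeeper(
            wide, exclude_from_correlation=self.bk_exclude, thresholds=self.thresholds
        )
        if len(self.genes) < 3:
            return StabilityReport(
                genes=self.genes,
                genorm_result=None,
                normfinder_result=None,
                bestkeeper_result=bk_all,
                delta_cq_result=None,
                delta_cq_m_result=None,
                consensus=None,
                thresholds=self.thresholds,
                degraded=True,
                notice=(
                    "fewer than 3 candidate genes passed screening: the "
                    "multi-gene stability algorithms (geNorm, NormFinder, "
                    "deltaCq, deltaCq*M) are undefined; reporting BestKeeper "
                    "SD only, which is independent of the other genes"
                ),
            )
        q = quantity_matrix(self.ds, genes=self.genes)
        gn = genorm(q, self.thresholds)
        nf = normfinder(q, self.normfinder_groups)
        dc = delta_cq_stability(wide)
        groups = info["subgroup"].tolist()
        dm = delta_cq_m(wide, groups, gn.m_values, self.delta_cq_m_comparisons)
        per_method = {
            "normfinder": nf.ranks(),
            "delta_cq": dc.ranks(),
            "bestkeeper": bk_all.ranks(),
            "genorm": gn.ranks(),
            "delta_cq_m": dm.ranks(),
        }
        cons = consensus_rank(per_method)
        return StabilityReport(
            genes=self.genes,
            genorm_result=gn,
            normfinder_result=nf,
            bestkeeper_result=bk_all,
            delta_cq_result=dc,
            delta_cq_m_result=dm,
            consensus=cons,
            thresholds=self.thresholds,
        )
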