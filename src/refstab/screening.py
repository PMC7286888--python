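"""Subgroup screening of candidate reference genes.

Before stability ranking, every candidate gene is tested for differential
expression between the four experimental subgroups (NV/EM x rest/activated)
at one activation timepoint. Per gene, a linear mixed-effects model is
fitted to the replicate-averaged Cq values:

    Cq ~ cell_type * activation        (fixed, 2x2 with interaction)
    + donor intercept + donor-level activation effect   (random)

by REML. All six pairwise contrasts of the four subgroup means are formed
from the fixed effects and given Tukey family-wise adjusted p-values (the
studentized-range construction for all-pairwise comparisons of k = 4
estimated marginal means, with paired-design degrees of freedom
df = n_donors - 1). A gene is declared differentially expressed — and hence
excluded from reference-gene candidacy — iff some contrast has adjusted
p < alpha AND |estimate| > min_effect (both strict; defaults 0.05 and 0.5 Cq,
the within-subgroup variation scale).

Normality of Cq per (gene, subgroup) is reported via the Lilliefors-corrected
Kolmogorov-Smirnov test; it is reported, never gated on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data import CqDataset, collapse_replicates, subgroup_label

logger = logging.getLogger(__name__)

SUBGROUPS = ("NV_rest", "NV_act", "EM_rest", "EM_act")

# subgroup mean = L @ [intercept, em, act, em:act]
_L_ROWS = {
    "NV_rest": np.array([1.0, 0.0, 0.0, 0.0]),
    "NV_act": np.array([1.0, 0.0, 1.0, 0.0]),
    "EM_rest": np.array([1.0, 1.0, 0.0, 0.0]),
    "EM_act": np.array([1.0, 1.0, 1.0, 1.0]),
}


@dataclass(frozen=True)
class ScreeningCriteria:
    """Dual exclusion rule: significance AND effect size, both strict."""

    alpha: float = 0.05
    min_effect: float = 0.5  # Cq units

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_effect < 0:
            raise ValueError("min_effect must be >= 0")


@dataclass(frozen=True)
class SubgroupContrast:
    gene: str
    group_a: str
    group_b: str
    estimate: float  # mean Cq difference, a - b
    se: float
    df: float
    p_unadjusted: float
    adjusted_p: float


@dataclass
class SubgroupModelResults:
    """Fixed-effect estimates and contrast machinery for one gene's model."""

    gene: str
    params: np.ndarray  # [intercept, em, act, em:act]
    cov_params: np.ndarray
    n_donors: int
    random_structure: str  # "intercept+activation", "intercept", or "ols"
    converged: bool
    scale: float

    @property
    def df(self) -> float:
        return float(self.n_donors - 1)

    def subgroup_means(self) -> dict[str, float]:
        return {g: float(_L_ROWS[g] @ self.params) for g in SUBGROUPS}

    def contrasts(self) -> list[SubgroupContrast]:
        return pairwise_subgroup_contrasts(self)


def fit_subgroup_model(ds: CqDataset, gene: str) -> SubgroupModelResults:
    """Fit the per-gene mixed model on replicate-averaged Cq at one timepoint.

    Falls back to a random-intercept-only model when the donor-activation
    variance component is singular, and to plain OLS when the residual
    variance itself is (numerically) zero — on a balanced design the fixed
    effects coincide, so no information is lost for the contrasts.
    """
    sub = ds.data[ds.data["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} not in dataset")
    if sub["timepoint_h"].nunique() != 1:
        raise ValueError(
            "fit_subgroup_model expects a single analysis timepoint; "
            "use subset_timepoint first"
        )
    if sub.duplicated(["donor_id", "cell_type", "activated"]).any():
        ds = collapse_replicates(
            CqDataset(sub.copy(), {gene: ds.efficiencies.get(gene, 2.0)})
        )
        sub = ds.data

    d = pd.DataFrame(
        {
            "cq": sub["cq"].to_numpy(float),
            "em": (sub["cell_type"] == "EM").to_numpy(float),
            "act": sub["activated"].to_numpy(float),
            "donor": sub["donor_id"].to_numpy(),
        }
    )
    d["em_act"] = d["em"] * d["act"]
    n_donors = d["donor"].nunique()
    X = np.column_stack([np.ones(len(d)), d["em"], d["act"], d["em_act"]])

    import statsmodels.formula.api as smf

    def _mixed(re_formula: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                "cq ~ em + act + em_act", d, groups="donor", re_formula=re_formula
            )
            return md.fit(reml=True, method=["lbfgs", "bfgs", "cg"])

    structure = "intercept+activation"
    res = None
    try:
        res = _mixed("~act")
        ev = np.linalg.eigvalsh(np.asarray(res.cov_re, dtype=float))
        if (not res.converged) or ev.min() < 1e-6 * max(1.0, ev.max()):
            logger.info(
                "%s: singular donor-activation variance component; "
                "downgrading to random intercept only",
                gene,
            )
            res = None
            structure = "intercept"
    except (np.linalg.LinAlgError, ValueError):
        res = None
        structure = "intercept"
    if res is None and structure == "intercept":
        try:
            res = _mixed("1")
            if not res.converged:
                res = None
        except (np.linalg.LinAlgError, ValueError):
            res = None

    if res is not None and np.isfinite(res.scale):
        params = np.asarray(res.fe_params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)[:4, :4]
        return SubgroupModelResults(
            gene=gene,
            params=params,
            cov_params=cov,
            n_donors=n_donors,
            random_structure=structure,
            converged=bool(res.converged),
            scale=float(res.scale),
        )

    # degenerate (e.g. noiseless) data: OLS is exact on the balanced design
    logger.info("%s: mixed fit degenerate; falling back to OLS", gene)
    beta, _, _, _ = np.linalg.lstsq(X, d["cq"].to_numpy(), rcond=None)
    resid = d["cq"].to_numpy() - X @ beta
    dof = max(len(d) - 4, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(X.T @ X)
    return SubgroupModelResults(
        gene=gene,
        params=beta,
        cov_params=cov,
        n_donors=n_donors,
        random_structure="ols",
        converged=True,
        scale=s2,
    )


def pairwise_subgroup_contrasts(fit: SubgroupModelResults) -> list[SubgroupContrast]:
    """All six pairwise subgroup-mean contrasts with Tukey adjustment."""
    out = []
    df = fit.df
    for a, b in combinations(SUBGROUPS, 2):
        c = _L_ROWS[a] - _L_ROWS[b]
        est = float(c @ fit.params)
        var = float(c @ fit.cov_params @ c)
        se = float(np.sqrt(max(var, 0.0)))
        if se > 0:
            t = est / se
            p_un = 2.0 * stats.t.sf(abs(t), df)
            p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), 4, df))
        else:
            p_un = 0.0 if est != 0.0 else 1.0
            p_adj = p_un
        out.append(
            SubgroupContrast(
                gene=fit.gene,
                group_a=a,
                group_b=b,
                estimate=est,
                se=se,
                df=df,
                p_unadjusted=float(p_un),
                adjusted_p=float(min(max(p_adj, 0.0), 1.0)),
            )
        )
    return out


@dataclass
class GeneScreeningResult:
    gene: str
    normality_p: dict[str, float]
    contrasts: list[SubgroupContrast]
    verdict: str  # "stable" | "differentially_expressed"
    triggering_contrasts: list[SubgroupContrast]
    random_structure: str = "intercept+activation"


def classify_stability(
    contrasts: list[SubgroupContrast], criteria: ScreeningCriteria = ScreeningCriteria()
) -> tuple[str, list[SubgroupContrast]]:
    """Apply the dual exclusion rule; returns (verdict, triggering contrasts)."""
    trig = [
        c
        for c in contrasts
        if c.adjusted_p < criteria.alpha and abs(c.estimate) > criteria.min_effect
    ]
    verdict = "differentially_expressed" if trig else "stable"
    return verdict, trig


def test_normality(ds: CqDataset, min_n: int = 4) -> pd.DataFrame:
    """Lilliefors-corrected KS normality p-values per (gene, subgroup).

    Cells with zero variance (or fewer than ``min_n`` samples) get a NaN
    p-value and an explanatory flag rather than a number.
    """
    from statsmodels.stats.diagnostic import lilliefors

    work = ds
    if ds.data.duplicated(["gene", "donor_id", "cell_type", "activated", "timepoint_h"]).any():
        work = collapse_replicates(ds)
    rows = []
    for (gene, sg), grp in work.data.groupby(["gene", "subgroup"], sort=False):
        x = grp["cq"].to_numpy(float)
        flag = ""
        p = np.nan
        if len(x) < min_n:
            flag = "too_few_samples"
        elif np.ptp(x) == 0.0:
            flag = "zero_variance"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p = lilliefors(x, dist="norm")
            p = float(p)
        rows.append({"gene": gene, "subgroup": sg, "n": len(x), "p_value": p, "flag": flag})
    return pd.DataFrame(rows)


@dataclass
class ScreeningReport:
    """Per-gene verdicts for one timepoint's dataset."""

    timepoint_h: float
    results: dict[str, GeneScreeningResult]
    criteria: ScreeningCriteria

    @property
    def stable_genes(self) -> list[str]:
        return [g for g, r in self.results.items() if r.verdict == "stable"]

    @property
    def unstable_genes(self) -> list[str]:
        return [g for g, r in self.results.items() if r.verdict == "differentially_expressed"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, r in self.results.items():
            for c in r.contrasts:
                rows.append(
                    {
                        "gene": g,
                        "contrast": f"{c.group_a} - {c.group_b}",
                        "estimate": c.estimate,
                        "se": c.se,
                        "adjusted_p": c.adjusted_p,
                        "verdict": r.verdict,
                    }
                )
        return pd.DataFrame(rows)

    def verdict_summary(self) -> dict[str, str]:
        return {g: r.verdict for g, r in self.results.items()}


def screen_genes(
    ds: CqDataset,
    criteria: ScreeningCriteria = ScreeningCriteria(),
    genes: list[str] | None = None,
) -> ScreeningReport:
    """Run the full screening step on a single-timepoint dataset."""
    tps = ds.timepoints
    if len(tps) != 1:
        raise ValueError(
            f"screening operates on one timepoint at a time; found {tps}"
        )
    normality = test_normality(ds)
    results: dict[str, GeneScreeningResult] = {}
    for gene in genes or ds.genes:
        fit = fit_subgroup_model(ds, gene)
        contrasts = pairwise_subgroup_contrasts(fit)
        verdict, trig = classify_stability(contrasts, criteria)
        np_map = {
            row.subgroup: row.p_value
            for row in normality[normality["gene"] == gene].itertuples()
        }
        results[gene] = GeneScreeningResult(
            gene=gene,
            normality_p=np_map,
            contrasts=contrasts,
            verdict=verdict,
            triggering_contrasts=trig,
            random_structure=fit.random_structure,
        )
    return ScreeningReport(timepoint_h=float(tps[0]), results=results, criteria=criteria)


class SubgroupModel:
    """statsmodels-style front door: build from data, ``fit()`` for results."""

    def __init__(self, ds: CqDataset, gene: str):
        self.ds = ds
        self.gene = gene

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gene: str, efficiencies=None):
        return cls(CqDataset(df, dict(efficiencies or {})), gene)

    def fit(self) -> SubgroupModelResults:
        return fit_subgroup_model(self.ds, self.gene)
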