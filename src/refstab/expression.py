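"""Efficiency-corrected relative expression (2^-ddCq generalized to E^-ddCq).

For a target gene t and reference set R, the per-donor fold change of the
activated over the paired non-activated state is

    ratio_d = E_t^(Cq_t,rest - Cq_t,act) / gmean_{r in R} E_r^(Cq_r,rest - Cq_r,act)

with E the per-gene amplification factor. log2 fold changes are computed per
donor and then averaged; the spread over donors is reported as an SD. A
reference gene whose own Cq shifts under activation biases every donor's
log2FC by exactly that shift times log2(E_ref) — the reason unstable
references distort target-gene conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CqDataset, collapse_replicates

__all__ = [
    "FoldChangeResult",
    "ddcq_fold_change",
    "fold_ratio_between_normalizations",
    "normalization_sensitivity",
]


@dataclass
class FoldChangeResult:
    target: str
    references: tuple[str, ...]
    cell_type: str
    timepoint_h: float
    per_donor_log2fc: dict[str, float]
    mean_log2fc: float
    sd_log2fc: float
    skipped_donors: list[str]
    adjusted_p: float | None = None

    @property
    def n_donors(self) -> int:
        return len(self.per_donor_log2fc)

    def summary(self) -> str:
        refs = "+".join(self.references)
        return (
            f"{self.target} vs {refs} [{self.cell_type}, {self.timepoint_h:g} h]: "
            f"mean log2FC = {self.mean_log2fc:.2f} (SD {self.sd_log2fc:.2f}, "
            f"n = {self.n_donors})"
        )


def _paired_delta_cq(sub: pd.DataFrame, gene: str, donor: str) -> float | None:
    """Cq(rest) - Cq(act) for one donor/gene, or None if unpaired."""
    rows = sub[(sub["gene"] == gene) & (sub["donor_id"] == donor)]
    rest = rows[~rows["activated"]]["cq"]
    act = rows[rows["activated"]]["cq"]
    if len(rest) != 1 or len(act) != 1:
        return None
    return float(rest.iloc[0] - act.iloc[0])


def ddcq_fold_change(
    ds: CqDataset,
    target: str,
    references: Sequence[str],
    cell_type: str,
    timepoint_h: float,
    annotate_significance: bool = False,
) -> FoldChangeResult:
    """Per-donor efficiency-corrected fold change, activated vs non-activated.

    Donors missing either paired sample for the target or any reference are
    skipped (and listed). ``annotate_significance`` refits the screening
    module's mixed model on the normalized log2 values and attaches the Tukey
    adjusted p-value of the activation contrast within ``cell_type``.
    """
    references = tuple(references)
    if not references:
        raise ValueError("reference set must be non-empty")
    for g in (target, *references):
        if g not in ds.genes:
            raise ValueError(f"gene {g!r} not in dataset")

    work = ds
    if ds.data.duplicated(["gene", "donor_id", "cell_type", "activated", "timepoint_h"]).any():
        work = collapse_replicates(ds)
    sub = work.data[
        (work.data["timepoint_h"] == float(timepoint_h))
        & (work.data["cell_type"] == cell_type)
    ]
    if sub.empty:
        raise ValueError(f"no data for {cell_type} at {timepoint_h} h")

    e_t = ds.efficiencies[target]
    per_donor: dict[str, float] = {}
    skipped: list[str] = []
    for donor in sorted(sub["donor_id"].unique()):
        d_t = _paired_delta_cq(sub, target, donor)
        d_refs = [_paired_delta_cq(sub, r, donor) for r in references]
        if d_t is None or any(v is None for v in d_refs):
            skipped.append(donor)
            continue
        log2_target = d_t * np.log2(e_t)
        log2_ref = float(
            np.mean([dv * np.log2(ds.efficiencies[r]) for r, dv in zip(references, d_refs)])
        )  # geometric mean of per-reference ratios, on the log2 scale
        per_donor[donor] = log2_target - log2_ref

    vals = np.array(list(per_donor.values()))
    mean = float(vals.mean()) if len(vals) else np.nan
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan

    adj_p = None
    if annotate_significance:
        adj_p = _normalized_activation_p(work, target, references, cell_type, timepoint_h)

    return FoldChangeResult(
        target=target,
        references=references,
        cell_type=cell_type,
        timepoint_h=float(timepoint_h),
        per_donor_log2fc=per_donor,
        mean_log2fc=mean,
        sd_log2fc=sd,
        skipped_donors=skipped,
        adjusted_p=adj_p,
    )


def _normalized_activation_p(
    ds: CqDataset,
    target: str,
    references: tuple[str, ...],
    cell_type: str,
    timepoint_h: float,
) -> float | None:
    """Tukey adjusted p for the activation contrast on normalized log2 values.

    Builds a pseudo-Cq response (-log2 normalized expression, so the screening
    machinery's sign conventions apply unchanged) per (donor, cell type,
    state) and reuses the mixed-model + Tukey contrast pipeline.
    """
    from .data import CqDataset as _DS
    from .screening import fit_subgroup_model, pairwise_subgroup_contrasts

    sub = ds.data[ds.data["timepoint_h"] == float(timepoint_h)]
    rows = []
    for (donor, ct, act), grp in sub.groupby(["donor_id", "cell_type", "activated"]):
        vals = {r.gene: r.cq for r in grp.itertuples()}
        if target not in vals or any(r not in vals for r in references):
            continue
        y = vals[target] * np.log2(ds.efficiencies[target]) - float(
            np.mean([vals[r] * np.log2(ds.efficiencies[r]) for r in references])
        )
        rows.append(
            {
                "gene": "normalized",
                "donor_id": donor,
                "cell_type": ct,
                "activated": act,
                "timepoint_h": float(timepoint_h),
                "replicate": 1,
                # shift into the valid Cq range; constants do not affect contrasts
                "cq": y + 50.0,
            }
        )
    if not rows:
        return None
    pseudo = _DS(pd.DataFrame(rows), {"normalized": 2.0})
    fit = fit_subgroup_model(pseudo, "normalized")
    contrasts = pairwise_subgroup_contrasts(fit)
    want = {f"{cell_type}_act", f"{cell_type}_rest"}
    for c in contrasts:
        if {c.group_a, c.group_b} == want:
            return c.adjusted_p
    return None


def fold_ratio_between_normalizations(log2fc_a: float, log2fc_b: float) -> float:
    """Linear fold ratio implied by two log2 fold changes, 2^(a - b)."""
    if not (np.isfinite(log2fc_a) and np.isfinite(log2fc_b)):
        raise ValueError("both log2 fold changes must be finite")
    return float(2.0 ** (log2fc_a - log2fc_b))


def normalization_sensitivity(
    ds: CqDataset,
    target: str,
    reference_panels: Sequence[Sequence[str]],
    cell_types: Sequence[str] = ("NV", "EM"),
    timepoint_h: float = 20.0,
    annotate_significance: bool = False,
) -> list[FoldChangeResult]:
    """Fold changes of one target under several candidate normalizations."""
    if not reference_panels:
        raise ValueError("reference_panels must be non-empty")
    out = []
    for panel in reference_panels:
        for ct in cell_types:
            out.append(
                ddcq_fold_change(
                    ds, target, panel, ct, timepoint_h,
                    annotate_significance=annotate_significance,
                )
            )
    return out


def fold_change_report(results: Sequence[FoldChangeResult]) -> pd.DataFrame:
    donors = sorted({d for r in results for d in r.per_donor_log2fc})
    rows = []
    for r in results:
        row = {
            "target": r.target,
            "references": "+".join(r.references),
            "cell_type": r.cell_type,
            "timepoint_h": r.timepoint_h,
            "mean_log2fc": r.mean_log2fc,
            "sd_log2fc": r.sd_log2fc,
            "n_donors": r.n_donors,
            "adjusted_p": r.adjusted_p,
        }
        for d in donors:
            row[f"log2fc_{d}"] = r.per_donor_log2fc.get(d, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
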