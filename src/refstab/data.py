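"""Cq data model and tabular I/O.

The central container is :class:`CqDataset`, a thin wrapper around a long-format
pandas DataFrame with one row per (donor, cell type, activation state,
timepoint, gene, replicate) quantification cycle (Cq) measurement, plus a
per-gene amplification-factor table (E, fold amplification per PCR cycle,
1 < E <= 2 for real assays; E = 2 means perfect doubling).

Samples are annotated with a derived ``subgroup`` label, the cross of cell
type (NV = naive, EM = effector memory) and activation state — the four
experimental cells the screening step compares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL_TYPES = ("NV", "EM")

#: Canonical long-format columns, in storage order.
MANDATORY_COLUMNS = (
    "gene",
    "donor_id",
    "cell_type",
    "activated",
    "timepoint_h",
    "replicate",
    "cq",
)

# Common synonyms accepted on input; the internal representation is canonical.
_CELL_TYPE_SYNONYMS = {
    "nv": "NV",
    "naive": "NV",
    "naïve": "NV",
    "n": "NV",
    "em": "EM",
    "effector memory": "EM",
    "effector_memory": "EM",
    "effector-memory": "EM",
}

_ACTIVATED_SYNONYMS = {
    "true": True, "t": True, "1": True, "yes": True, "y": True,
    "act": True, "activated": True, "stimulated": True,
    "false": False, "f": False, "0": False, "no": False, "n": False,
    "rest": False, "resting": False, "non-activated": False,
    "nonactivated": False, "non_activated": False, "unstimulated": False,
}


class CqFormatError(ValueError):
    """A table does not conform to the expected long Cq format."""


def subgroup_label(cell_type: str, activated: bool) -> str:
    """Subgroup is a pure function of (cell_type, activated)."""
    return f"{cell_type}_{'act' if activated else 'rest'}"


def canonical_cell_type(value) -> str:
    s = str(value).strip()
    if s in CELL_TYPES:
        return s
    try:
        return _CELL_TYPE_SYNONYMS[s.lower()]
    except KeyError:
        raise CqFormatError(
            f"unrecognized cell_type {value!r}; expected one of {CELL_TYPES} or a synonym"
        ) from None


def canonical_activated(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    try:
        return _ACTIVATED_SYNONYMS[s]
    except KeyError:
        raise CqFormatError(f"unrecognized activation state {value!r}") from None


@dataclass(frozen=True)
class SampleKey:
    """Identity of one biological sample (before gene/replicate indexing)."""

    donor_id: str
    cell_type: str
    activated: bool
    timepoint_h: float

    @property
    def subgroup(self) -> str:
        return subgroup_label(self.cell_type, self.activated)


@dataclass
class CqDataset:
    """Long-format Cq measurements plus per-gene amplification factors.

    Parameters
    ----------
    data:
        DataFrame with at least :data:`MANDATORY_COLUMNS`. Unknown columns are
        preserved untouched.
    efficiencies:
        Mapping gene -> amplification factor E. Genes present in ``data`` but
        absent here default to E = 2 (100 % efficiency) with a logged warning.
    discordance:
        Optional report of replicate pairs whose spread exceeded the QC
        threshold during :func:`collapse_replicates`.
    """

    data: pd.DataFrame
    efficiencies: dict[str, float] = field(default_factory=dict)
    discordance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data)
        for gene in self.genes:
            if gene not in self.efficiencies:
                logger.warning(
                    "no amplification efficiency supplied for %s; defaulting to E = 2 (100%%)",
                    gene,
                )
                self.efficiencies[gene] = 2.0
        for gene, e in self.efficiencies.items():
            if not (1.0 < e <= 2.2):
                raise ValueError(
                    f"amplification factor for {gene} must be in (1, 2.2], got {e}"
                )

    # ---- basic introspection -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.data["gene"]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.data["timepoint_h"].unique().tolist())

    @property
    def donors(self) -> list[str]:
        return sorted(self.data["donor_id"].unique().tolist())

    def __len__(self) -> int:
        return len(self.data)

    def unpaired_samples(self) -> pd.DataFrame:
        """Samples lacking their activation-state partner.

        The design is paired: each (donor, cell_type, timepoint) should appear
        both non-activated and activated. Unpaired records are permitted but
        flagged here.
        """
        key = ["donor_id", "cell_type", "timepoint_h"]
        states = self.data.groupby(key)["activated"].nunique()
        bad = states[states < 2]
        return bad.reset_index().drop(columns=["activated"])

    # ---- I/O -----------------------------------------------------------------

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        cols = [c for c in MANDATORY_COLUMNS] + [
            c for c in self.data.columns if c not in MANDATORY_COLUMNS and c != "subgroup"
        ]
        self.data[cols].to_csv(path, sep=sep, index=False)

    def copy(self) -> "CqDataset":
        return CqDataset(
            self.data.copy(),
            dict(self.efficiencies),
            None if self.discordance is None else self.discordance.copy(),
        )


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CqFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.copy()
    df["gene"] = df["gene"].astype(str)
    df["donor_id"] = df["donor_id"].astype(str)
    df["cell_type"] = [canonical_cell_type(v) for v in df["cell_type"]]
    df["activated"] = [canonical_activated(v) for v in df["activated"]]
    df["timepoint_h"] = pd.to_numeric(df["timepoint_h"], errors="raise").astype(float)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)

    cq = pd.to_numeric(df["cq"], errors="coerce")
    bad = df.index[cq.isna() | ~np.isfinite(cq) | (cq <= 0)]
    if len(bad):
        raise CqFormatError(
            f"non-numeric, non-finite or non-positive Cq at row(s) {bad.tolist()[:10]}"
        )
    df["cq"] = cq.astype(float)

    key = ["donor_id", "cell_type", "activated", "timepoint_h", "gene", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise CqFormatError(
            f"duplicate (sample, gene, replicate) records at rows {df.index[dup].tolist()[:10]}"
        )
    df["subgroup"] = [
        subgroup_label(c, a) for c, a in zip(df["cell_type"], df["activated"])
    ]
    return df.reset_index(drop=True)


def read_cq_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    efficiencies: Mapping[str, float] | None = None,
    sep: str | None = None,
) -> CqDataset:
    """Read a long-format Cq table (CSV/TSV) into a :class:`CqDataset`.

    ``dialect`` maps source column names to canonical ones, e.g.
    ``{"Ct": "cq", "subset": "cell_type"}``. Unknown columns are preserved as
    opaque metadata.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if dialect:
        df = df.rename(columns=dict(dialect))
    return CqDataset(df, dict(efficiencies or {}))


def read_efficiency_table(path: str | Path, sep: str | None = None) -> dict[str, float]:
    """Read a per-gene efficiency table.

    Columns: ``gene`` plus at least one of ``slope`` (standard-curve slope
    magnitude, Cq per log10 input) or ``efficiency_percent``. Returns gene ->
    amplification factor E = 1 + efficiency/100.
    """
    from .standard_curve import efficiency_from_slope

    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if "gene" not in df.columns:
        raise CqFormatError("efficiency table missing mandatory column: gene")
    if "efficiency_percent" not in df.columns and "slope" not in df.columns:
        raise CqFormatError(
            "efficiency table needs at least one of: slope, efficiency_percent"
        )
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        if "efficiency_percent" in df.columns and pd.notna(row.get("efficiency_percent")):
            pct = float(row["efficiency_percent"])
        else:
            pct = efficiency_from_slope(float(row["slope"]))
        out[str(row["gene"])] = 1.0 + pct / 100.0
    return out


def collapse_replicates(ds: CqDataset, max_spread: float = 0.5) -> CqDataset:
    """Average technical replicates to one record per (sample, gene).

    Replicate groups whose Cq spread (max − min) exceeds ``max_spread`` are
    recorded in the returned dataset's ``discordance`` report but are still
    averaged — the QC rule flags, it never drops data.
    """
    if max_spread <= 0:
        raise ValueError("max_spread must be > 0")
    key = ["donor_id", "cell_type", "activated", "timepoint_h", "gene"]
    g = ds.data.groupby(key, sort=False)["cq"]
    agg = g.agg(cq="mean", spread=lambda x: x.max() - x.min(), n="size").reset_index()
    discordant = agg.loc[agg["spread"] > max_spread, key + ["cq", "spread", "n"]]
    out = agg[key + ["cq"]].copy()
    out["replicate"] = 1
    return CqDataset(out, dict(ds.efficiencies), discordance=discordant.reset_index(drop=True))


def subset_timepoint(ds: CqDataset, timepoint_h: float) -> CqDataset:
    """Restrict to one activation timepoint (activated plus paired resting).

    Non-activated samples carry the timepoint of their paired activated
    sample, so a plain equality filter keeps the pairs together.
    """
    available = ds.timepoints
    if float(timepoint_h) not in available:
        raise ValueError(
            f"timepoint {timepoint_h} h not present; available: {available}"
        )
    sub = ds.data[ds.data["timepoint_h"] == float(timepoint_h)].reset_index(drop=True)
    genes = set(sub["gene"])
    eff = {g: e for g, e in ds.efficiencies.items() if g in genes}
    return CqDataset(sub, eff)
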