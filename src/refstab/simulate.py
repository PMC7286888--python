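"""Synthetic Cq data with planted ground truth.

The generator emulates a paired RT-qPCR design: matched donors contribute
naive (NV) and effector-memory (EM) CD8+ T-cell samples, each measured
non-activated and activated at one or more timepoints, with technical
replicates. For gene g, donor d, cell type c, activation a, timepoint t and
replicate r:

    Cq = baseline(g) + ct_shift(g)*[c=EM] + act_shift(g,t,c)*[a]
         + b_d + u_d*[a] + eps(g,d,c,a,t) + eps_rep

with b_d ~ N(0, donor_sd^2) a donor intercept shared across genes,
u_d ~ N(0, donor_activation_sd^2) a donor-level "this donor activates
strongly" effect shared across genes, eps a per-gene biological residual and
eps_rep technical replicate noise. All noise is Gaussian on the Cq scale.

Per-gene/per-donor RNG streams are derived deterministically from the root
seed, so adding a gene to a config does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CELL_TYPES, CqDataset

__all__ = [
    "GeneSimSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_cq_dataset",
    "simulate_dilution_series",
    "tcell_panel_config",
    "TCELL_PANEL_SLOPES",
]


def _normalize_shift(shift, timepoints: Sequence[float]) -> dict[float, dict[str, float]]:
    """Accept a scalar, {tp: scalar} or {tp: {cell_type: scalar}}; return nested dict."""
    out: dict[float, dict[str, float]] = {}
    for t in timepoints:
        t = float(t)
        if isinstance(shift, Mapping):
            v = shift.get(t, shift.get(int(t), 0.0))
        else:
            v = shift
        if isinstance(v, Mapping):
            out[t] = {c: float(v.get(c, 0.0)) for c in CELL_TYPES}
        else:
            out[t] = {c: float(v) for c in CELL_TYPES}
    return out


@dataclass
class GeneSimSpec:
    """Ground-truth expression behaviour of one simulated gene.

    ``activation_shift`` is the Cq offset applied under activation (negative
    = induction, i.e. lower Cq = more template). It may be a scalar, a map
    timepoint -> scalar, or a map timepoint -> {cell_type: scalar}.
    ``residual_sd`` overrides the config-wide biological residual SD for this
    gene; real panels show per-gene spreads (from ~0.4 to ~0.9 Cq within a
    subgroup), which a single shared SD cannot emulate.
    """

    gene: str
    baseline_cq: float
    cell_type_shift: float = 0.0
    activation_shift: float | Mapping = 0.0
    stable: bool = False
    residual_sd: float | None = None
    stability_margin: float = 0.1

    def shifts_at(self, timepoints: Sequence[float]) -> dict[float, dict[str, float]]:
        return _normalize_shift(self.activation_shift, timepoints)

    def validate(self, timepoints: Sequence[float]) -> None:
        if self.baseline_cq <= 0:
            raise ValueError(f"{self.gene}: baseline_cq must be > 0")
        if self.residual_sd is not None and self.residual_sd < 0:
            raise ValueError(f"{self.gene}: residual_sd must be >= 0")
        if self.stable:
            shifts = self.shifts_at(timepoints)
            mags = [abs(v) for per_ct in shifts.values() for v in per_ct.values()]
            mags.append(abs(self.cell_type_shift))
            if any(m > self.stability_margin for m in mags):
                raise ValueError(
                    f"{self.gene}: stable=True but a planted shift exceeds the "
                    f"stability margin {self.stability_margin} Cq"
                )


@dataclass
class SimConfig:
    genes: list[GeneSimSpec]
    n_donors: int = 11
    timepoints_h: tuple[float, ...] = (2.0,)
    donor_sd: float = 0.35
    donor_activation_sd: float = 0.15
    residual_sd: float = 0.5
    replicate_sd: float = 0.1
    n_replicates: int = 2
    seed: int | None = None

    def validate(self) -> None:
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for sd in (self.donor_sd, self.donor_activation_sd, self.residual_sd, self.replicate_sd):
            if sd < 0:
                raise ValueError("all SDs must be >= 0")
        if not self.genes:
            raise ValueError("at least one gene required")
        names = [g.gene for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene symbols in config")
        for g in self.genes:
            g.validate(self.timepoints_h)


@dataclass
class GroundTruth:
    """Realized ground truth for one simulated dataset."""

    gene_specs: dict[str, GeneSimSpec]
    donor_intercepts: dict[str, float]
    donor_activation_effects: dict[str, float]
    config: SimConfig

    @property
    def stable_genes(self) -> list[str]:
        return [g for g, s in self.gene_specs.items() if s.stable]

    def to_jsonable(self) -> dict:
        d = {
            "gene_specs": {g: asdict(s) for g, s in self.gene_specs.items()},
            "donor_intercepts": self.donor_intercepts,
            "donor_activation_effects": self.donor_activation_effects,
        }
        # asdict leaves Mapping shift values as-is; make keys JSON-safe
        for spec in d["gene_specs"].values():
            shift = spec["activation_shift"]
            if isinstance(shift, Mapping):
                spec["activation_shift"] = {
                    str(k): (dict(v) if isinstance(v, Mapping) else v)
                    for k, v in shift.items()
                }
        return d


def _gene_seed(root: int, gene: str) -> np.random.Generator:
    # crc32 is stable across runs/platforms (unlike hash())
    return np.random.default_rng(np.random.SeedSequence([root, zlib.crc32(gene.encode())]))


def simulate_cq_dataset(
    cfg: SimConfig, seed: int | None = None
) -> tuple[CqDataset, GroundTruth]:
    """Draw one dataset from the generative model; identical seed, identical data."""
    cfg.validate()
    root = int(cfg.seed if seed is None else seed) if (seed is not None or cfg.seed is not None) else 0

    donors = [f"D{i + 1:02d}" for i in range(cfg.n_donors)]
    donor_rng = np.random.default_rng(np.random.SeedSequence([root, 0xD0_0D]))
    b = donor_rng.normal(0.0, cfg.donor_sd, size=cfg.n_donors)
    u = donor_rng.normal(0.0, cfg.donor_activation_sd, size=cfg.n_donors)

    timepoints = tuple(float(t) for t in cfg.timepoints_h)
    rows: list[dict] = []
    for spec in cfg.genes:
        rng = _gene_seed(root, spec.gene)
        res_sd = cfg.residual_sd if spec.residual_sd is None else spec.residual_sd
        shifts = spec.shifts_at(timepoints)
        for di, donor in enumerate(donors):
            for c in CELL_TYPES:
                for t in timepoints:
                    for a in (False, True):
                        mu = (
                            spec.baseline_cq
                            + (spec.cell_type_shift if c == "EM" else 0.0)
                            + (shifts[t][c] if a else 0.0)
                            + b[di]
                            + (u[di] if a else 0.0)
                        )
                        eps = rng.normal(0.0, res_sd)
                        for r in range(1, cfg.n_replicates + 1):
                            cq = mu + eps + rng.normal(0.0, cfg.replicate_sd)
                            rows.append(
                                {
                                    "gene": spec.gene,
                                    "donor_id": donor,
                                    "cell_type": c,
                                    "activated": a,
                                    "timepoint_h": t,
                                    "replicate": r,
                                    "cq": cq,
                                }
                            )
    df = pd.DataFrame(rows)
    # the generator owns its efficiencies: perfect doubling unless the caller
    # attaches assay-specific values afterwards
    ds = CqDataset(df, efficiencies={g.gene: 2.0 for g in cfg.genes})
    truth = GroundTruth(
        gene_specs={g.gene: g for g in cfg.genes},
        donor_intercepts=dict(zip(donors, b.tolist())),
        donor_activation_effects=dict(zip(donors, u.tolist())),
        config=cfg,
    )
    return ds, truth


def simulate_dilution_series(
    efficiency_percent: float,
    intercept: float,
    dilution_factor: float = 5.0,
    n_points: int = 5,
    n_replicates: int = 2,
    noise_sd: float = 0.0,
    seed: int | None = None,
    gene: str = "gene",
) -> pd.DataFrame:
    """Simulate a qPCR dilution-series table for standard-curve fitting.

    Point i (i = 0 most concentrated) sits at log10 relative input
    x_i = -i*log10(dilution_factor), with
    Cq_i = intercept - x_i / log10(1 + efficiency/100) + N(0, noise_sd^2).
    """
    if not (0.0 < efficiency_percent <= 110.0):
        raise ValueError("efficiency_percent must be in (0, 110]")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    if n_points < 3:
        raise ValueError("n_points must be >= 3 to fit a line meaningfully")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    log10_e = np.log10(1.0 + efficiency_percent / 100.0)
    rows = []
    for i in range(n_points):
        x = -i * np.log10(dilution_factor)
        for r in range(1, n_replicates + 1):
            cq = intercept - x / log10_e + rng.normal(0.0, noise_sd)
            rows.append({"gene": gene, "log10_input": x, "replicate": r, "cq": cq})
    return pd.DataFrame(rows)


# Standard-curve slopes typical of well-optimized assays (Cq per log10 input,
# magnitudes); used to attach realistic per-gene amplification factors.
TCELL_PANEL_SLOPES: dict[str, float] = {
    "ACTB": 3.491,
    "B2M": 3.482,
    "CASC3": 3.519,
    "GAPDH": 3.574,
    "HMBS": 3.459,
    "HPRT1": 3.535,
    "IPO8": 3.579,
    "PPIB": 3.510,
    "RPLP0": 3.435,
    "SDHA": 3.566,
    "UBE2D2": 3.378,
    "18S rRNA": 3.583,
    "IFNG": 3.520,
}


def tcell_panel_config(
    n_donors: int = 11,
    timepoints_h: tuple[float, ...] = (2.0, 10.0, 20.0),
    seed: int | None = None,
) -> SimConfig:
    """Ready-made config emulating a 13-gene T-cell activation panel.

    Twelve candidate reference genes plus an IFNG-like strongly induced
    target. Baselines span ~6.9 (18S rRNA) to ~28.5 (HMBS) Cq. Ground-truth
    stable genes are 18S rRNA and SDHA: zero planted shifts and the lowest
    biological noise. Classic housekeeping genes (ACTB, GAPDH, HMBS, HPRT1,
    PPIB) are induced already at 2 h; a second tier (B2M, CASC3, IPO8, RPLP0,
    UBE2D2) stays flat at 2 h but is induced by 10-20 h. Negative shifts mean
    induction. Per-gene residual SDs mirror the within-subgroup spreads such
    panels show (~0.25-0.8 Cq on top of the shared donor variance).
    """

    def spec(gene, baseline, ct=0.0, shift=0.0, stable=False, res=0.5):
        return GeneSimSpec(
            gene=gene,
            baseline_cq=baseline,
            cell_type_shift=ct,
            activation_shift=shift,
            stable=stable,
            residual_sd=res,
        )

    genes = [
        spec("ACTB", 16.5, shift={2.0: -1.2, 10.0: -1.5, 20.0: -1.5}),
        spec("B2M", 14.9, shift={2.0: 0.0, 10.0: -1.2, 20.0: -1.2}),
        spec("CASC3", 24.2, shift={2.0: 0.0, 10.0: -2.0, 20.0: -2.0}, res=0.8),
        spec("GAPDH", 16.0, ct=-0.8, shift={2.0: -1.3, 10.0: -2.0, 20.0: -2.5}),
        spec("HMBS", 28.5, shift={2.0: {"NV": -1.2, "EM": 0.0}, 10.0: -1.5, 20.0: -1.8}),
        spec("HPRT1", 24.5, shift={2.0: {"NV": -0.4, "EM": -1.2}, 10.0: -1.5, 20.0: -1.5}),
        spec("IPO8", 23.5, shift={2.0: 0.0, 10.0: -1.2, 20.0: -1.2}),
        spec("PPIB", 20.5, ct=1.0, shift={2.0: -0.4, 10.0: -1.2, 20.0: -1.2}),
        spec("RPLP0", 18.0, shift={2.0: 0.0, 10.0: -1.2, 20.0: -1.4}),
        spec("SDHA", 23.0, stable=True, res=0.3),
        spec("UBE2D2", 21.5, shift={2.0: 0.0, 10.0: -1.2, 20.0: -1.2}, res=0.55),
        spec("18S rRNA", 6.9, stable=True, res=0.25),
        spec("IFNG", 26.0, shift={2.0: -3.0, 10.0: -5.5, 20.0: -7.0}, res=0.6),
    ]
    return SimConfig(
        genes=genes,
        n_donors=n_donors,
        timepoints_h=tuple(float(t) for t in timepoints_h),
        donor_sd=0.35,
        donor_activation_sd=0.15,
        residual_sd=0.5,
        replicate_sd=0.1,
        n_replicates=2,
        seed=seed,
    )


def tcell_panel_efficiencies() -> dict[str, float]:
    """Amplification factors (E) for the 13-gene panel, from typical slopes."""
    from .standard_curve import efficiency_from_slope

    return {
        g: 1.0 + efficiency_from_slope(s) / 100.0
        for g, s in TCELL_PANEL_SLOPES.items()
    }
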