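"""Config-driven orchestration of the full evaluation workflow.

A pipeline run mirrors the analysis flow of a reference-gene study: primer
standard curves (if dilution data is given), per-timepoint subgroup
screening, stability ranking of the screened-stable candidates, consensus,
and ddCq validation of target genes under chosen normalizations. Everything
is written as TSV/JSON reports plus a manifest that suffices to reproduce
the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .data import CqDataset, collapse_replicates, read_cq_table, read_efficiency_table, subset_timepoint
from .expression import fold_change_report, normalization_sensitivity
from .screening import ScreeningCriteria, screen_genes, test_normality
from .simulate import SimConfig, tcell_panel_config, tcell_panel_efficiencies, simulate_cq_dataset
from .stability import StabilityAnalysis, StabilityThresholds
from .standard_curve import fit_standard_curve, standard_curve_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Either input paths or a simulation config — never neither."""

    cq_table: str | None = None
    efficiency_table: str | None = None
    dilution_series: str | None = None
    simulation: dict | SimConfig | None = None  # dict config or "tcell_panel"
    dialect: dict[str, str] = field(default_factory=dict)
    max_replicate_spread: float = 0.5
    criteria: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    thresholds: StabilityThresholds = field(default_factory=StabilityThresholds)
    normfinder_groups: list[str] | None = None
    delta_cq_m_comparisons: list[tuple[str, str]] | None = None
    bestkeeper_exclude_from_correlation: list[str] = field(default_factory=list)
    validation_targets: list[str] = field(default_factory=list)
    reference_panels: list[list[str]] = field(default_factory=list)
    validation_timepoint_h: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.cq_table is None and self.simulation is None:
            raise ValueError("config needs either input paths or a simulation config")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "criteria" in d and isinstance(d["criteria"], dict):
            d["criteria"] = ScreeningCriteria(**d["criteria"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = StabilityThresholds(**d["thresholds"])
        if "delta_cq_m_comparisons" in d and d["delta_cq_m_comparisons"]:
            d["delta_cq_m_comparisons"] = [tuple(c) for c in d["delta_cq_m_comparisons"]]
        return cls(**d)


def _load_config_file(path: str | Path) -> PipelineConfig:
    import yaml

    text = Path(path).read_text()
    d = yaml.safe_load(text)
    return PipelineConfig.from_dict(d)


def _resolve_inputs(cfg: PipelineConfig) -> CqDataset:
    if cfg.cq_table is not None:
        eff = read_efficiency_table(cfg.efficiency_table) if cfg.efficiency_table else {}
        return read_cq_table(cfg.cq_table, dialect=cfg.dialect, efficiencies=eff)
    sim = cfg.simulation
    if sim == "tcell_panel" or sim is None:
        sim_cfg = tcell_panel_config(seed=cfg.seed)
        eff = tcell_panel_efficiencies()
    elif isinstance(sim, SimConfig):
        sim_cfg, eff = sim, {}
    else:
        d = dict(sim)
        eff = d.pop("efficiencies", {})
        from .simulate import GeneSimSpec

        d["genes"] = [GeneSimSpec(**g) for g in d["genes"]]
        sim_cfg = SimConfig(**d)
    ds, _ = simulate_cq_dataset(sim_cfg, seed=cfg.seed)
    ds.efficiencies.update(eff)
    return ds


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the full workflow; returns a summary dict (also written to disk)."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"timepoints": {}}

    # standard curves
    if cfg.dilution_series:
        series = pd.read_csv(
            cfg.dilution_series,
            sep="\t" if str(cfg.dilution_series).endswith((".tsv", ".tab")) else ",",
        )
        fits = [fit_standard_curve(grp, gene) for gene, grp in series.groupby("gene", sort=False)]
        standard_curve_report(fits).to_csv(outdir / "standard_curves.tsv", sep="\t", index=False)
        summary["standard_curves"] = {
            f.gene: {"slope": f.slope, "efficiency_percent": f.efficiency_percent, "r_squared": f.r_squared}
            for f in fits
        }

    ds = _resolve_inputs(cfg)
    collapsed = collapse_replicates(ds, cfg.max_replicate_spread)
    if collapsed.discordance is not None and len(collapsed.discordance):
        collapsed.discordance.to_csv(outdir / "replicate_discordance.tsv", sep="\t", index=False)

    candidate_genes = [g for g in ds.genes if g not in cfg.validation_targets]

    for tp in collapsed.timepoints:
        tp_dir = outdir / f"timepoint_{tp:g}h"
        tp_dir.mkdir(exist_ok=True)
        sub = subset_timepoint(collapsed, tp)

        normality = test_normality(sub)
        normality.to_csv(tp_dir / "normality.tsv", sep="\t", index=False)

        report = screen_genes(sub, cfg.criteria, genes=candidate_genes)
        report.to_frame().to_csv(tp_dir / "screening.tsv", sep="\t", index=False)
        stable = report.stable_genes
        tp_summary: dict[str, Any] = {
            "screening_verdicts": report.verdict_summary(),
            "stable_genes": stable,
        }

        if len(stable) < 3:
            notice = (
                f"only {len(stable)} gene(s) passed screening at {tp:g} h; "
                "multi-gene stability ranking skipped, reporting BestKeeper SD "
                "for the full panel instead"
            )
            logger.warning(notice)
            tp_summary["notice"] = notice
            # BestKeeper SD is per-gene and independent of the other genes,
            # so it can still be reported for the full candidate panel
            from .stability import bestkeeper, cq_matrix

            wide, _ = cq_matrix(sub)
            bk = bestkeeper(wide.loc[candidate_genes], thresholds=cfg.thresholds)
            pd.DataFrame(
                {
                    "gene": candidate_genes,
                    "bestkeeper_sd": [bk.sd_values[g] for g in candidate_genes],
                    "unstable": [g in bk.unstable_genes for g in candidate_genes],
                }
            ).to_csv(tp_dir / "stability_bestkeeper_sd_only.tsv", sep="\t", index=False)
            tp_summary["stability"] = {
                "degraded": True,
                "bestkeeper_sd": bk.sd_values,
            }
        else:
            stab = StabilityAnalysis(
                sub,
                genes=stable,
                normfinder_groups=cfg.normfinder_groups,
                delta_cq_m_comparisons=cfg.delta_cq_m_comparisons,
                bestkeeper_exclude_from_correlation=cfg.bestkeeper_exclude_from_correlation,
                thresholds=cfg.thresholds,
            ).fit()
            stab.summary().to_csv(tp_dir / "stability.tsv", sep="\t")
            tp_summary["stability"] = stab.to_jsonable()
        summary["timepoints"][f"{tp:g}"] = tp_summary

    # validation fold changes
    if cfg.validation_targets and cfg.reference_panels:
        tp = cfg.validation_timepoint_h or collapsed.timepoints[-1]
        val_rows = []
        for target in cfg.validation_targets:
            results = normalization_sensitivity(
                collapsed, target, cfg.reference_panels, timepoint_h=tp,
                annotate_significance=True,
            )
            val_rows.extend(results)
        fold_change_report(val_rows).to_csv(outdir / "validation_fold_changes.tsv", sep="\t", index=False)
        summary["validation"] = [
            {
                "target": r.target,
                "references": list(r.references),
                "cell_type": r.cell_type,
                "mean_log2fc": r.mean_log2fc,
                "sd_log2fc": r.sd_log2fc,
                "adjusted_p": r.adjusted_p,
            }
            for r in val_rows
        ]

    manifest = {
        "refstab_version": __version__,
        "seed": cfg.seed,
        "config": _jsonable_config(cfg),
        "versions": _env_versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=_json_default))
    return summary


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _jsonable_config(cfg: PipelineConfig) -> dict:
    d = {}
    for k, v in vars(cfg).items():
        if isinstance(v, (ScreeningCriteria, StabilityThresholds)):
            d[k] = vars(v)
        elif isinstance(v, SimConfig):
            d[k] = "inline SimConfig"
        else:
            try:
                json.dumps(v)
                d[k] = v
            except TypeError:
                d[k] = str(v)
    return d


def _env_versions() -> dict[str, str]:
    import pandas
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.version.version,
        "statsmodels": statsmodels.__version__,
    }
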