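"""Small plotting helpers for Cq distributions and geNorm diagnostics."""

from __future__ import annotations

from .data import CqDataset
from .stability import GeNormResult


def cq_boxplot(ds: CqDataset, genes=None, ax=None):
    """Boxplots of Cq per gene and subgroup (the classic screening figure)."""
    import matplotlib.pyplot as plt

    genes = genes or ds.genes
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(genes) + 2, 4))
    order = ["NV_rest", "NV_act", "EM_rest", "EM_act"]
    data, labels = [], []
    for g in genes:
        for sg in order:
            vals = ds.data.loc[
                (ds.data["gene"] == g) & (ds.data["subgroup"] == sg), "cq"
            ]
            data.append(vals.to_numpy())
            labels.append(f"{g}\n{sg}")
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("Cq")
    ax.tick_params(axis="x", labelrotation=90, labelsize=7)
    return ax


def v_series_plot(result: GeNormResult, v_cutoff: float = 0.15, ax=None):
    """Bar chart of geNorm pairwise variation V(n, n+1)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ns = sorted(result.v_series)
    ax.bar([f"V{n}/{n + 1}" for n in ns], [result.v_series[n] for n in ns])
    ax.axhline(v_cutoff, color="red", linestyle="--", linewidth=1)
    ax.set_ylabel("pairwise variation V")
    return ax
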