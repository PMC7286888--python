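import numpy as np
import pandas as pd
import pytest

from refstab import (
    CqDataset,
    GeneSimSpec,
    SimConfig,
    collapse_replicates,
    tcell_panel_config,
    tcell_panel_efficiencies,
    simulate_cq_dataset,
)
from refstab.data import subset_timepoint


def make_long_table(genes, donors, cell_types=("NV", "EM"), timepoints=(2.0,),
                    n_replicates=1, cq=20.0):
    """Minimal valid long-format frame with a constant (or callable) Cq."""
    rows = []
    for g in genes:
        for d in donors:
            for c in cell_types:
                for t in timepoints:
                    for a in (False, True):
                        for r in range(1, n_replicates + 1):
                            val = cq(g, d, c, a, t, r) if callable(cq) else cq
                            rows.append(
                                dict(gene=g, donor_id=d, cell_type=c, activated=a,
                                     timepoint_h=t, replicate=r, cq=val)
                            )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_dataset():
    df = make_long_table(["G1", "G2"], ["D1", "D2"], cq=lambda g, d, c, a, t, r: 20.0 + hash((g, d)) % 3)
    return CqDataset(df, {"G1": 2.0, "G2": 2.0})


@pytest.fixture(scope="session")
def tcell_panel_2h():
    """One collapsed simulated T-cell panel dataset restricted to the 2 h timepoint."""
    cfg = tcell_panel_config(seed=11, timepoints_h=(2.0,))
    ds, truth = simulate_cq_dataset(cfg, seed=11)
    ds.efficiencies.update(tcell_panel_efficiencies())
    return subset_timepoint(collapse_replicates(ds), 2.0), truth


@pytest.fixture(scope="session")
def single_null_gene():
    """A zero-shift gene's collapsed paired dataset (for null calibration)."""
    cfg = SimConfig(genes=[GeneSimSpec("NULL1", 20.0)], n_donors=11, seed=7)
    ds, _ = simulate_cq_dataset(cfg, seed=7)
    return collapse_replicates(ds)
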