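import numpy as np
import pandas as pd
import pytest

import nashtx as nx


def make_design(n_per_cell: int = 4, sexes=("F", "M")) -> nx.DesignTable:
    """Balanced 2x2 design helper with n_per_cell samples per diet x time."""
    rows = []
    for time in (1, 40):
        for diet in ("LFD", "WD"):
            for i in range(n_per_cell):
                rows.append(
                    {"sample_id": f"{diet}_{time}wk_{i}", "diet": diet,
                     "time": time, "sex": sexes[i % len(sexes)]}
                )
    return nx.DesignTable(pd.DataFrame(rows))


def log2_expr(values: np.ndarray, design: nx.DesignTable) -> nx.ExprMatrix:
    genes = [f"g{i:04d}" for i in range(values.shape[0])]
    return nx.ExprMatrix(values, genes, design.sample_ids, scale="log2")


@pytest.fixture(scope="session")
def bulk_sim():
    """One moderately sized bulk simulation shared across tests."""
    cfg = nx.BulkSimConfig(n_genes=800, seed=42)
    counts, design, truth = nx.simulate_bulk_counts(cfg)
    return cfg, counts, design, truth


@pytest.fixture(scope="session")
def sc_sim():
    """One single-cell simulation at strong marker separation."""
    cfg = nx.ScSimConfig(n_cell_types=3, cells_per_type=100, n_genes=900,
                         markers_per_type=15, marker_fold=8.0, seed=7)
    counts, labels, truth = nx.simulate_sc_umis(cfg)
    return cfg, counts, labels, truth


@pytest.fixture(scope="session")
def linked_sim():
    """Matched bulk + sc simulation over one gene universe."""
    return nx.simulate_linked(
        nx.BulkSimConfig(n_genes=1200, nb_dispersion=0.1, seed=3),
        nx.ScSimConfig(n_genes=1200, n_cell_types=3, cells_per_type=100,
                       markers_per_type=20, marker_fold=8.0, seed=3),
    )
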