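import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from hexniche.annotate import build_labels
from hexniche.spatial_io import SpotDataset
from hexniche.synthetic_data import SimConfig, simulate_dataset


def make_dataset(counts, coords, genes, sample_id="S01", layer="middle epidermis"):
    """Small hand-built dataset: counts (n_spots x n_genes) array,
    coords list of (row, col)."""
    counts = np.asarray(counts)
    spots = pd.DataFrame(
        {
            "sample_id": sample_id,
            "barcode": [f"BC{i:04d}" for i in range(len(coords))],
            "in_tissue": 1,
            "array_row": [r for r, _ in coords],
            "array_col": [c for _, c in coords],
            "layer": layer,
        }
    )
    meta = pd.DataFrame(
        {
            "sample_id": [sample_id],
            "patient_id": ["P01"],
            "project_id": ["PRJ1"],
            "disease": ["Pso"],
            "condition": ["lesional"],
        }
    ).set_index("sample_id")
    ds = SpotDataset(
        counts=sparse.csr_matrix(counts.astype(np.int64)),
        genes=pd.Index(genes),
        spots=spots,
        meta=meta,
    )
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def sim_small():
    """Two-sample simulated dataset with all planted structure."""
    cfg = SimConfig(n_samples=2, seed=11)
    ds, gt = simulate_dataset(cfg)
    return cfg, ds, gt


@pytest.fixture(scope="session")
def sim_labeled(sim_small):
    cfg, ds, gt = sim_small
    return cfg, ds, gt, build_labels(ds)
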