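"""Per-spot leukocyte/cytokine labeling, layer grouping and spatial
enrichment testing.

A spot is leukocyte-positive when it carries at least one UMI of any
T-cell marker gene (default CD2, CD3D, CD3E, CD3G, CD247, PTPRC) and
cytokine-positive when it carries at least one UMI of that cytokine;
spots positive for several cytokines stay in every matching set.

Layer enrichment compares per-sample cytokine UMI sums between two
disjoint layer groups with a two-sided Wilcoxon signed-rank test on the
paired per-sample sums (exact null for up to 25 informative pairs, normal
approximation with continuity correction above).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spatial_io import LAYER_VOCAB, SpotDataset, DatasetError

__all__ = [
    "DEFAULT_MARKERS",
    "DEFAULT_CYTOKINES",
    "SpotLabels",
    "EnrichmentResult",
    "label_leukocytes",
    "label_cytokines",
    "build_labels",
    "layer_enrichment_test",
    "cytokine_distribution",
]

DEFAULT_MARKERS = ("CD2", "CD3D", "CD3E", "CD3G", "CD247", "PTPRC")
DEFAULT_CYTOKINES = ("IFNG", "IL13", "IL17A")


@dataclass
class SpotLabels:
    """Per-spot flags and counts, aligned with the dataset's spot table."""

    leukocyte_pos: np.ndarray  # bool per spot
    cytokine_umi: dict[str, np.ndarray]  # cytokine -> int per spot
    cytokine_pos: dict[str, np.ndarray]  # cytokine -> bool per spot

    @property
    def cytokines(self) -> list[str]:
        return list(self.cytokine_umi)

    def to_frame(self, ds: SpotDataset) -> pd.DataFrame:
        df = ds.spots[["sample_id", "barcode"]].copy()
        df["leukocyte_pos"] = self.leukocyte_pos
        for cyt in self.cytokine_umi:
            df[f"{cyt}_umi"] = self.cytokine_umi[cyt]
            df[f"{cyt}_pos"] = self.cytokine_pos[cyt]
        return df


def label_leukocytes(ds: SpotDataset, markers=DEFAULT_MARKERS) -> np.ndarray:
    """Flag spots with >= 1 UMI summed over the marker genes."""
    present = [m for m in markers if m in ds.genes]
    missing = [m for m in markers if m not in ds.genes]
    if not present:
        raise DatasetError(f"no leukocyte marker genes present; missing: {missing}")
    cols = [ds.gene_index(m) for m in present]
    total = np.asarray(ds.counts[:, cols].sum(axis=1)).ravel()
    return total >= 1


def label_cytokines(
    ds: SpotDataset, cytokines=DEFAULT_CYTOKINES
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-cytokine UMI counts and >= 1 positivity flags."""
    umi: dict[str, np.ndarray] = {}
    pos: dict[str, np.ndarray] = {}
    for cyt in cytokines:
        if cyt not in ds.genes:
            raise DatasetError(f"cytokine gene {cyt!r} absent from dataset")
        col = ds.gene_index(cyt)
        u = np.asarray(ds.counts[:, [col]].todense()).ravel().astype(np.int64)
        umi[cyt] = u
        pos[cyt] = u >= 1
    return umi, pos


def build_labels(
    ds: SpotDataset, markers=DEFAULT_MARKERS, cytokines=DEFAULT_CYTOKINES
) -> SpotLabels:
    leuk = label_leukocytes(ds, markers)
    umi, pos = label_cytokines(ds, cytokines)
    return SpotLabels(leukocyte_pos=leuk, cytokine_umi=umi, cytokine_pos=pos)


@dataclass
class EnrichmentResult:
    cytokine: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    statistic: float
    p_value: float
    per_sample_sums: pd.DataFrame = field(repr=False, default=None)


def layer_enrichment_test(
    ds: SpotDataset,
    labels: SpotLabels,
    cytokine: str,
    group_a,
    group_b,
) -> EnrichmentResult:
    """Two-sided Wilcoxon signed-rank test of per-sample cytokine UMI sums
    between two disjoint layer groups, on raw counts.

    Zero-difference samples are dropped (classical procedure); if every
    difference is zero the result is p = 1 with a warning.
    """
    group_a, group_b = tuple(group_a), tuple(group_b)
    for layer in (*group_a, *group_b):
        if layer not in LAYER_VOCAB:
            raise DatasetError(f"unknown layer {layer!r}")
    if set(group_a) & set(group_b):
        raise ValueError("layer groups must be disjoint")
    if cytokine not in labels.cytokine_umi:
        raise DatasetError(f"no labels for cytokine {cytokine!r}")

    umi = labels.cytokine_umi[cytokine]
    df = ds.spots[["sample_id", "layer"]].copy()
    df["umi"] = umi
    samples = ds.sample_ids
    if len(samples) < 2:
        raise DatasetError("need >= 2 samples for the signed-rank test")
    sums_a, sums_b = [], []
    for s in samples:
        sub = df[df["sample_id"] == s]
        sums_a.append(int(sub.loc[sub["layer"].isin(group_a), "umi"].sum()))
        sums_b.append(int(sub.loc[sub["layer"].isin(group_b), "umi"].sum()))
    a = np.array(sums_a, dtype=float)
    b = np.array(sums_b, dtype=float)
    diff = a - b
    nonzero = diff != 0
    table = pd.DataFrame({"sample_id": samples, "sum_a": a, "sum_b": b})

    if not nonzero.any():
        warnings.warn("all per-sample differences are zero; p set to 1")
        return EnrichmentResult(cytokine, group_a, group_b, 0.0, 1.0, table)
    n_eff = int(nonzero.sum())
    method = "exact" if n_eff <= 25 else "approx"
    res = stats.wilcoxon(
        a[nonzero],
        b[nonzero],
        alternative="two-sided",
        zero_method="wilcox",
        correction=(method == "approx"),
        method=method,
    )
    return EnrichmentResult(
        cytokine, group_a, group_b, float(res.statistic), float(res.pvalue), table
    )


def cytokine_distribution(
    ds: SpotDataset, labels: SpotLabels, per: str = "disease"
) -> pd.DataFrame:
    """Per-disease cytokine UMI totals rescaled to sum to 100.

    Rows with zero total yield NaN with a warning.
    """
    meta_col = ds.meta[per].reindex(ds.spots["sample_id"]).to_numpy()
    groups = pd.unique(meta_col)
    rows = {}
    for g in groups:
        mask = meta_col == g
        totals = np.array(
            [labels.cytokine_umi[c][mask].sum() for c in labels.cytokines], dtype=float
        )
        total = totals.sum()
        if total == 0:
            warnings.warn(f"{per}={g!r}: no cytokine UMIs; percentages undefined")
            rows[g] = np.full(len(totals), np.nan)
        else:
            rows[g] = 100.0 * totals / total
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels.cytokines)
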