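"""High-level orchestration: per-sample cluster construction, pooled
radius sweeps and pseudo-bulk correlation on a labeled dataset.

The correlation analysis operates on the epidermal spot universe by
default (responder signatures derive from keratinocyte stimulation);
override ``layers`` to analyse other compartments.
"""

from __future__ import annotations

import warnings

import numpy as np

from .annotate import SpotLabels
from .hexcluster import (
    DensityCluster,
    build_adjacency,
    cluster_readout,
    expand_and_merge,
    seed_clusters,
)
from .signatures import ResponderSignature
from .spatial_correlation import (
    CorrelationResult,
    RadiusSweepResult,
    pseudo_bulk_correlation,
    radius_sweep,
)
from .spatial_io import EPIDERMIS_LAYERS, SpotDataset

__all__ = [
    "build_clusters",
    "sweep_cytokine",
    "pseudo_bulk_cytokine",
]


def _signature_cols(ds: SpotDataset, signature: ResponderSignature) -> list[int]:
    cols = []
    missing = []
    for g in signature.genes:
        if g in ds.genes:
            cols.append(ds.gene_index(g))
        else:
            missing.append(g)
    if missing:
        warnings.warn(f"signature genes absent from matrix, skipped: {missing}")
    return cols


def build_clusters(
    ds: SpotDataset,
    labels: SpotLabels,
    cytokine: str,
    signature: ResponderSignature,
    radius: int,
    layers=EPIDERMIS_LAYERS,
    require_leukocyte: bool = True,
    strict_hex: bool = False,
) -> list[DensityCluster]:
    """Density clusters at one radius, pooled over samples and read out.

    Seeds are cytokine-positive (optionally also leukocyte-positive) spots
    within ``layers``; the expansion universe is every QC-passing spot of
    those layers in the same sample.
    """
    in_layers = ds.spots["layer"].isin(layers).to_numpy()
    seed_mask = labels.cytokine_pos[cytokine] & in_layers
    if require_leukocyte:
        seed_mask &= labels.leukocyte_pos
    cyt_col = ds.gene_index(cytokine)
    resp_cols = _signature_cols(ds, signature)

    clusters: list[DensityCluster] = []
    for sample_id in ds.sample_ids:
        smask = (ds.spots["sample_id"] == sample_id).to_numpy()
        sel = smask & seed_mask
        if not sel.any():
            continue
        coords = ds.spots.loc[sel, ["array_row", "array_col"]].to_numpy()
        umis = labels.cytokine_umi[cytokine][sel]
        graph = build_adjacency(coords, umis=umis, strict_hex=strict_hex)
        comps = seed_clusters(graph)
        universe = {
            (int(r), int(c))
            for r, c in ds.spots.loc[smask & in_layers, ["array_row", "array_col"]].to_numpy()
        }
        sample_clusters = expand_and_merge(comps, graph, radius, universe, sample_id)
        cmap = ds.coord_map(sample_id)
        for cl in sample_clusters:
            cluster_readout(cl, cmap, ds.counts, cyt_col, resp_cols)
        clusters.extend(sample_clusters)
    return clusters


def sweep_cytokine(
    ds: SpotDataset,
    labels: SpotLabels,
    cytokine: str,
    signature: ResponderSignature,
    radii=range(0, 10),
    layers=EPIDERMIS_LAYERS,
    require_leukocyte: bool = True,
    strict_hex: bool = False,
    p_method: str = "t",
    rng=None,
) -> RadiusSweepResult:
    """Radius sweep for one cytokine; optimum maximizes the weighted
    Spearman correlation across pooled clusters."""

    def builder(r: int) -> list[DensityCluster]:
        return build_clusters(
            ds,
            labels,
            cytokine,
            signature,
            r,
            layers=layers,
            require_leukocyte=require_leukocyte,
            strict_hex=strict_hex,
        )

    return radius_sweep(builder, radii=radii, p_method=p_method, rng=rng)


def pseudo_bulk_cytokine(
    ds: SpotDataset,
    labels: SpotLabels,
    cytokine: str,
    signature: ResponderSignature,
    layers=EPIDERMIS_LAYERS,
    p_method: str = "t",
    rng=None,
) -> CorrelationResult:
    """Per-section correlation of summed cytokine vs responder UMIs over
    the layer universe, ignoring spatial structure."""
    in_layers = ds.spots["layer"].isin(layers).to_numpy()
    resp_cols = _signature_cols(ds, signature)
    cyt_umi = labels.cytokine_umi[cytokine]
    x, y = [], []
    for sample_id in ds.sample_ids:
        smask = (ds.spots["sample_id"] == sample_id).to_numpy() & in_layers
        x.append(float(cyt_umi[smask].sum()))
        rows = np.flatnonzero(smask)
        y.append(
            float(ds.counts[rows][:, resp_cols].sum()) if len(rows) and resp_cols else 0.0
        )
    return pseudo_bulk_correlation(x, y, p_method=p_method, rng=rng)
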