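"""Spot/gene quality control, size-factor normalization and per-spot
covariates.

QC applies the spot rules first (minimum detected genes, UMI window,
mitochondrial fraction), then removes genes observed in too few of the
surviving spots.  Size factors are library sizes divided by their
geometric mean — a documented simplification of pooled deconvolution
factors; any externally computed positive factor vector can be supplied
instead.  Normalization is ``log10(count / size_factor + 1)`` — note the
base-10 log with pseudocount 1, not the usual natural/2-based ``log1p``.
Raw counts are always retained; differential expression and cluster
readout operate on raw counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse

from .spatial_io import SpotDataset

__all__ = [
    "QcParams",
    "QcReport",
    "QcError",
    "NormFactors",
    "apply_qc",
    "compute_norm_factors",
    "normalize_log",
]


class QcError(ValueError):
    pass


@dataclass
class QcParams:
    min_genes_per_spot: int = 30
    min_spots_per_gene: int = 20
    min_umi: int = 50
    max_umi: int = 500_000
    max_mt_fraction: float = 0.25
    mt_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_umi >= self.max_umi:
            raise ValueError("min_umi must be < max_umi")
        if not 0.0 <= self.max_mt_fraction <= 1.0:
            raise ValueError("max_mt_fraction must be in [0, 1]")


@dataclass
class QcReport:
    n_spots_in: int
    n_spots_out: int
    n_genes_in: int
    n_genes_out: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_spots_removed_unique: int = 0
    removed_spot_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def apply_qc(ds: SpotDataset, params: QcParams | None = None) -> tuple[SpotDataset, QcReport]:
    """Remove failing spots, then under-observed genes.

    Spot rules (all evaluated on the raw input, so a spot can violate
    several and is counted once per rule it breaks):

    * fewer than ``min_genes_per_spot`` detected genes;
    * total UMI outside ``[min_umi, max_umi]`` (bounds inclusive-keep);
    * mitochondrial fraction strictly above ``max_mt_fraction``.

    Genes observed (count > 0) in fewer than ``min_spots_per_gene`` of the
    *surviving* spots are then removed.
    """
    params = params or QcParams()
    X = ds.counts
    n_spots, n_genes = X.shape

    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    umi = np.asarray(X.sum(axis=1)).ravel()
    mt_mask = np.asarray(
        ds.genes.str.upper().str.startswith(params.mt_prefix.upper()), dtype=bool
    )
    mt_umi = np.asarray(X[:, mt_mask].sum(axis=1)).ravel() if mt_mask.any() else np.zeros(n_spots)
    with np.errstate(invalid="ignore", divide="ignore"):
        mt_frac = np.where(umi > 0, mt_umi / np.maximum(umi, 1), 0.0)

    fail_genes = detected < params.min_genes_per_spot
    fail_min_umi = umi < params.min_umi
    fail_max_umi = umi > params.max_umi
    fail_mt = mt_frac > params.max_mt_fraction
    fail_any = fail_genes | fail_min_umi | fail_max_umi | fail_mt

    keep_spots = ~fail_any
    if n_spots and not keep_spots.any():
        raise QcError(
            "QC removed every spot "
            f"(min_genes={int(fail_genes.sum())}, min_umi={int(fail_min_umi.sum())}, "
            f"max_umi={int(fail_max_umi.sum())}, mt_fraction={int(fail_mt.sum())})"
        )

    filtered = ds.subset_spots(keep_spots)
    spots_per_gene = np.asarray((filtered.counts > 0).sum(axis=0)).ravel()
    keep_genes = spots_per_gene >= params.min_spots_per_gene
    out = filtered.subset_genes(keep_genes)

    removed_ids = [
        f"{s}:{b}"
        for s, b in ds.spots.loc[fail_any, ["sample_id", "barcode"]].itertuples(index=False)
    ]
    report = QcReport(
        n_spots_in=n_spots,
        n_spots_out=out.n_spots,
        n_genes_in=n_genes,
        n_genes_out=out.n_genes,
        removed_by_rule={
            "min_genes_per_spot": int(fail_genes.sum()),
            "min_umi": int(fail_min_umi.sum()),
            "max_umi": int(fail_max_umi.sum()),
            "max_mt_fraction": int(fail_mt.sum()),
            "min_spots_per_gene": int((~keep_genes).sum()),
        },
        n_spots_removed_unique=int(fail_any.sum()),
        removed_spot_ids=removed_ids,
    )
    return out, report


@dataclass
class NormFactors:
    size_factor: np.ndarray  # positive, geometric mean 1
    cdr: np.ndarray  # fraction of genes detected per spot, in [0, 1]


def compute_norm_factors(
    ds: SpotDataset, size_factors: np.ndarray | None = None
) -> NormFactors:
    """Per-spot size factors and cellular detection rate.

    Default size factors are library sizes divided by their geometric
    mean, so the factors themselves have geometric mean 1.  A precomputed
    positive factor vector (e.g. pooled deconvolution factors computed
    externally) may be passed instead and is rescaled to geometric mean 1.
    """
    lib = ds.library_sizes().astype(float)
    if (lib <= 0).any():
        bad = ds.spots.loc[lib <= 0, "barcode"].tolist()[:5]
        raise QcError(f"zero-library spots present (apply QC first): {bad}")
    if size_factors is None:
        size_factors = lib
    else:
        size_factors = np.asarray(size_factors, dtype=float)
        if size_factors.shape != (ds.n_spots,):
            raise ValueError("size_factors length must equal number of spots")
        if (size_factors <= 0).any():
            raise ValueError("size factors must be positive")
    sf = size_factors / np.exp(np.mean(np.log(size_factors)))
    detected = np.asarray((ds.counts > 0).sum(axis=1)).ravel()
    cdr = detected / ds.n_genes if ds.n_genes else np.zeros(ds.n_spots)
    return NormFactors(size_factor=sf, cdr=cdr)


def normalize_log(ds: SpotDataset, factors: NormFactors) -> sparse.csr_matrix:
    """Size-factor-scaled, log10(x+1)-transformed expression.

    Returns a new sparse matrix; the dataset's raw counts are untouched
    (downstream DEG and cluster readout consume raw counts).
    A zero count maps to exactly 0.
    """
    X = ds.counts.tocoo(copy=True).astype(float)
    X.data = np.log10(X.data / factors.size_factor[X.row] + 1.0)
    return X.tocsr()
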