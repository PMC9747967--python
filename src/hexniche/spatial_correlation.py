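"""Weighted Spearman correlation of cytokine and responder counts, the
radius sweep with optimum selection, and the origin-constrained line fit.

The weighted Spearman coefficient is defined as the weighted Pearson
correlation of the mid-rank vectors (ties averaged, ranks computed
unweighted).  The two-sided p-value uses a t statistic with ``n - 2``
degrees of freedom applied to the weighted coefficient, where ``n`` counts
the units with positive weight; a seeded permutation alternative is
available since the weighted null is not exactly t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hexcluster import DensityCluster

__all__ = [
    "CorrelationResult",
    "CorrelationError",
    "RadiusSweepResult",
    "weighted_spearman",
    "clustered_correlation",
    "pseudo_bulk_correlation",
    "radius_sweep",
    "fit_origin_line",
]


class CorrelationError(ValueError):
    """Raised when a correlation is undefined (too few units, zero rank
    variance, all-zero weights)."""


@dataclass
class CorrelationResult:
    method: str  # weighted_spearman | spearman | pearson
    r: float
    p_value: float
    n_units: int
    weights: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "r": self.r,
            "p_value": self.p_value,
            "n_units": self.n_units,
        }


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    mx = np.dot(w, x) / wsum
    my = np.dot(w, y) / wsum
    dx, dy = x - mx, y - my
    cov = np.dot(w, dx * dy)
    vx = np.dot(w, dx * dx)
    vy = np.dot(w, dy * dy)
    if vx <= 0 or vy <= 0:
        raise CorrelationError("zero variance in ranks; correlation undefined")
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def _t_pvalue(r: float, n: int) -> float:
    if n < 3:
        raise CorrelationError(f"need at least 3 units for a p-value, got {n}")
    if abs(r) >= 1.0:
        return np.finfo(float).tiny
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def weighted_spearman(
    x,
    y,
    w=None,
    p_method: str = "t",
    n_permutations: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> CorrelationResult:
    """Weighted Spearman correlation with a two-sided p-value.

    Parameters
    ----------
    x, y
        Equal-length observation vectors.
    w
        Nonnegative weights with positive sum; ``None`` means uniform.
        Zero-weight observations are dropped entirely (they influence
        neither ranks nor the coefficient).
    p_method
        ``"t"`` (default) for the t approximation with ``df = n - 2``,
        ``"permutation"`` for a seeded permutation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if w is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != x.shape:
            raise ValueError("w must match x in length")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
    keep = w > 0
    x, y, w = x[keep], y[keep], w[keep]
    n = int(keep.sum())
    if n < 3:
        raise CorrelationError(f"need at least 3 positively weighted units, got {n}")
    if w.sum() <= 0:
        raise CorrelationError("weights sum to zero")

    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    r = _weighted_pearson(rx, ry, w)

    if p_method == "t":
        p = _t_pvalue(r, n)
    elif p_method == "permutation":
        gen = np.random.default_rng(rng)
        count = 0
        for _ in range(n_permutations):
            perm = gen.permutation(n)
            try:
                rp = _weighted_pearson(rx, ry[perm], w)
            except CorrelationError:
                continue
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return CorrelationResult("weighted_spearman", r, p, n, weights=w)


def clustered_correlation(
    clusters: list[DensityCluster], p_method: str = "t", rng=None
) -> CorrelationResult:
    """Weighted Spearman between per-cluster cytokine and responder sums,
    weighting each cluster by its cytokine count."""
    if len(clusters) < 3:
        raise CorrelationError(
            f"need at least 3 clusters, got {len(clusters)}"
        )
    x = np.array([c.cytokine_count for c in clusters], dtype=float)
    y = np.array([c.responder_count for c in clusters], dtype=float)
    w = np.array([c.weight for c in clusters], dtype=float)
    return weighted_spearman(x, y, w, p_method=p_method, rng=rng)


def pseudo_bulk_correlation(
    cytokine_totals,
    responder_totals,
    p_method: str = "t",
    rng=None,
) -> CorrelationResult:
    """Per-section correlation ignoring spatial structure.

    ``cytokine_totals`` and ``responder_totals`` are per-section sums over
    epidermal spots; sections are weighted by their cytokine totals.
    Sections with zero cytokine counts carry zero weight and drop out.
    """
    x = np.asarray(cytokine_totals, dtype=float)
    y = np.asarray(responder_totals, dtype=float)
    usable = int((x > 0).sum())
    if usable < 3:
        raise CorrelationError(
            f"need at least 3 sections with cytokine counts, got {usable}"
        )
    return weighted_spearman(x, y, w=x, p_method=p_method, rng=rng)


@dataclass
class RadiusSweepResult:
    """Per-radius correlation table plus the selected optimum."""

    radii: list[int]
    correlations: dict[int, CorrelationResult]
    n_clusters: dict[int, int]
    errors: dict[int, str] = field(default_factory=dict)
    optimal_radius: int | None = None
    pearson: dict[int, float] = field(default_factory=dict)

    @property
    def significant(self) -> dict[int, bool]:
        return {r: bool(c.p_value < 0.05) for r, c in self.correlations.items()}

    def as_dict(self) -> dict:
        return {
            "radii": self.radii,
            "optimal_radius": self.optimal_radius,
            "per_radius": {
                str(r): {
                    **(
                        self.correlations[r].as_dict()
                        if r in self.correlations
                        else {"error": self.errors.get(r, "skipped")}
                    ),
                    "n_clusters": self.n_clusters.get(r, 0),
                    "pearson_r": self.pearson.get(r),
                    "significant": self.significant.get(r),
                }
                for r in self.radii
            },
        }


def radius_sweep(
    cluster_builder,
    radii=range(0, 10),
    p_method: str = "t",
    rng=None,
) -> RadiusSweepResult:
    """Sweep cluster radii and select the one maximizing the weighted
    Spearman correlation (ties broken toward the smallest radius).

    ``cluster_builder(r)`` must return the pooled list of read-out
    :class:`DensityCluster` at radius ``r``.  Radii yielding fewer than
    three clusters (or an otherwise undefined correlation) are recorded as
    errors and skipped; if every radius errors a
    :class:`CorrelationError` is raised.
    """
    radii = list(radii)
    res = RadiusSweepResult(radii=radii, correlations={}, n_clusters={})
    for r in radii:
        clusters = cluster_builder(r)
        res.n_clusters[r] = len(clusters)
        try:
            cr = clustered_correlation(clusters, p_method=p_method, rng=rng)
        except CorrelationError as exc:
            res.errors[r] = str(exc)
            continue
        res.correlations[r] = cr
        # secondary Pearson readout on the raw sums (unweighted)
        x = np.array([c.cytokine_count for c in clusters])
        y = np.array([c.responder_count for c in clusters])
        if np.std(x) > 0 and np.std(y) > 0:
            res.pearson[r] = float(stats.pearsonr(x, y).statistic)
    if not res.correlations:
        raise CorrelationError("correlation undefined at every swept radius")
    best = max(res.correlations, key=lambda r: (res.correlations[r].r, -r))
    res.optimal_radius = best
    return res


def fit_origin_line(x, y) -> float:
    """Least-squares slope of a line through the origin:
    ``slope = Σxy / Σx²``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 1:
        raise ValueError("x and y must be equal-length, nonempty")
    sxx = np.dot(x, x)
    if sxx <= 0:
        raise CorrelationError("all x are zero; slope undefined")
    return float(np.dot(x, y) / sxx)
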