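"""Per-gene negative-binomial GLM differential expression.

Raw counts are modeled with a log link and a log(size factor) offset;
biological covariates (cellular detection rate, project, patient, layer
annotation) enter as fixed effects, and the tested condition is a binary
contrast.  Per-gene dispersion is initialized by method of moments on
Poisson residuals and refined by maximum likelihood, alternating with the
IRLS mean fit.  Inference is a two-sided Wald test on the condition
coefficient; p-values are Benjamini–Hochberg corrected and genes are
called at inclusive cutoffs ``|log2FC| >= 1`` and ``p <= 0.05``.

The dispersion parameterization here is ``variance = mu + alpha * mu²``
(so ``alpha = 1/theta`` for the NB size ``theta``); ``alpha`` is floored
at 1e-8, where the model is numerically Poisson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .annotate import SpotLabels
from .hexcluster import DensityCluster
from .preprocess import NormFactors
from .spatial_io import EPIDERMIS_LAYERS, SpotDataset

__all__ = [
    "DesignSpec",
    "DesignError",
    "build_design",
    "fit_nb_glm",
    "bh_adjust",
    "call_degs",
    "contrast_noncluster",
]

ALPHA_FLOOR = 1e-8
ALPHA_CEIL = 1e8


class DesignError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Which covariates enter the design, beyond the tested condition.

    ``covariates`` may contain any of ``cdr``, ``project``, ``patient``,
    ``annotation``; reference levels default to the first sorted level of
    each categorical.
    """

    covariates: tuple[str, ...] = ("cdr", "project", "patient", "annotation")
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = {"cdr", "project", "patient", "annotation"}
        unknown = set(self.covariates) - allowed
        if unknown:
            raise DesignError(f"unknown covariates: {sorted(unknown)}")


def _one_hot(values: pd.Series, name: str, reference: str | None) -> pd.DataFrame:
    levels = sorted(values.unique())
    if len(levels) < 2:
        return pd.DataFrame(index=values.index)
    ref = reference if reference in levels else levels[0]
    cols = {}
    for lev in levels:
        if lev == ref:
            continue
        cols[f"{name}[{lev}]"] = (values == lev).astype(float)
    return pd.DataFrame(cols, index=values.index)


def build_design(
    ds: SpotDataset,
    factors: NormFactors,
    condition: np.ndarray,
    spec: DesignSpec | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the fixed-effect design matrix and the log-size-factor
    offset.

    Categoricals are reference-coded; cdr is centered.  Columns that are
    collinear with earlier columns are dropped with a warning.  The
    condition column comes last and is named ``condition``.
    """
    spec = spec or DesignSpec()
    condition = np.asarray(condition).astype(float)
    if condition.shape != (ds.n_spots,):
        raise DesignError("condition length must equal number of spots")
    if len(np.unique(condition)) < 2:
        raise DesignError("condition is constant; contrast undefined")

    idx = ds.spots.index
    parts = [pd.DataFrame({"intercept": np.ones(ds.n_spots)}, index=idx)]
    if "cdr" in spec.covariates:
        cdr = factors.cdr - factors.cdr.mean()
        parts.append(pd.DataFrame({"cdr": cdr}, index=idx))
    if "project" in spec.covariates:
        proj = ds.meta["project_id"].reindex(ds.spots["sample_id"]).set_axis(idx)
        parts.append(_one_hot(proj, "project", spec.reference_levels.get("project")))
    if "patient" in spec.covariates:
        pat = ds.meta["patient_id"].reindex(ds.spots["sample_id"]).set_axis(idx)
        parts.append(_one_hot(pat, "patient", spec.reference_levels.get("patient")))
    if "annotation" in spec.covariates:
        parts.append(
            _one_hot(ds.spots["layer"], "annotation", spec.reference_levels.get("annotation"))
        )
    parts.append(pd.DataFrame({"condition": condition}, index=idx))
    X = pd.concat(parts, axis=1)

    # greedy rank repair: drop columns not increasing matrix rank.
    # Intercept and condition are admitted first so a confounded covariate
    # is dropped rather than the tested contrast.
    cols = list(X.columns)
    priority = ["intercept", "condition"] + [
        c for c in cols if c not in ("intercept", "condition")
    ]
    arr = X.to_numpy()
    keep: list[str] = []
    dropped: list[str] = []
    current = np.empty((arr.shape[0], 0))
    rank = 0
    for col in priority:
        trial = np.column_stack([current, arr[:, cols.index(col)]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            keep.append(col)
            current = trial
            rank = r
        else:
            dropped.append(col)
    if dropped:
        warnings.warn(f"dropped collinear design columns: {dropped}")
        X = X[[c for c in cols if c in keep]]

    offset = np.log(factors.size_factor)
    return X, offset


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha < ALPHA_FLOOR:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    theta = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _estimate_alpha(y: np.ndarray, mu: np.ndarray, alpha0: float) -> float:
    """MLE of the NB dispersion given the fitted means, moments-seeded."""
    lo, hi = np.log(ALPHA_FLOOR), np.log(ALPHA_CEIL)
    res = optimize.minimize_scalar(
        lambda la: -_nb_loglik(y, mu, np.exp(la)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-3},
    )
    if not res.success:
        return alpha0
    return float(np.exp(res.x))


def _moments_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    denom = float(np.sum(mu**2))
    if denom <= 0:
        return ALPHA_FLOOR
    excess = float(np.sum((y - mu) ** 2 - mu)) / denom
    return float(np.clip(excess, ALPHA_FLOOR, ALPHA_CEIL))


def fit_nb_glm(
    counts,
    design: pd.DataFrame,
    offset: np.ndarray,
    condition_col: str = "condition",
    n_dispersion_rounds: int = 2,
) -> pd.DataFrame:
    """Fit one NB GLM per gene and Wald-test the condition coefficient.

    ``counts`` is (spots x genes), sparse or dense; all-zero genes are
    excluded.  Returns a DataFrame indexed like the gene axis with columns
    ``gene, log2FC, p_value, adj_p_value, mean_count, alpha, converged``.
    Non-converged genes are flagged and assigned p = 1.
    """
    X = design.to_numpy(dtype=float)
    cond_idx = list(design.columns).index(condition_col)
    n_genes = counts.shape[1]
    genes = (
        list(counts.columns) if isinstance(counts, pd.DataFrame) else list(range(n_genes))
    )
    if isinstance(counts, pd.DataFrame):
        counts = counts.to_numpy()

    records = []
    ln2 = np.log(2.0)
    for g in range(n_genes):
        if hasattr(counts, "toarray"):
            y = np.asarray(counts[:, [g]].todense()).ravel().astype(float)
        else:
            y = np.asarray(counts[:, g]).ravel().astype(float)
        mean_count = float(y.mean())
        if not np.any(y > 0):
            continue
        log2fc = np.nan
        p = 1.0
        alpha = np.nan
        converged = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(
                    maxiter=50
                )
                mu = np.clip(pois.mu, 1e-10, None)
                alpha = _moments_alpha(y, mu)
                fit = pois
                for _ in range(n_dispersion_rounds):
                    alpha = _estimate_alpha(y, mu, alpha)
                    if alpha < ALPHA_FLOOR * 1.0001:
                        fit = pois
                        break
                    fam = sm.families.NegativeBinomial(alpha=alpha)
                    fit = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=50)
                    mu = np.clip(fit.mu, 1e-10, None)
            coef = fit.params[cond_idx]
            bse = fit.bse[cond_idx]
            converged = bool(getattr(fit, "converged", True)) and np.isfinite(bse) and bse > 0
            if converged:
                z = coef / bse
                p = float(2.0 * stats.norm.sf(abs(z)))
                p = min(max(p, np.finfo(float).tiny), 1.0)
                log2fc = float(coef / ln2)
            else:
                p = 1.0
        except Exception:
            converged = False
            p = 1.0
        records.append(
            {
                "gene": genes[g],
                "log2FC": log2fc,
                "p_value": p,
                "mean_count": mean_count,
                "alpha": alpha,
                "converged": converged,
            }
        )
    table = pd.DataFrame(records)
    if len(table):
        table["adj_p_value"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["adj_p_value"] = []
    return table[
        ["gene", "log2FC", "p_value", "adj_p_value", "mean_count", "alpha", "converged"]
    ]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with monotonicity
    enforcement; permutation-equivariant."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_degs(
    table: pd.DataFrame,
    fc_cut: float = 1.0,
    p_cut: float = 0.05,
    use_adjusted: bool = True,
) -> list[str]:
    """Genes with ``|log2FC| >= fc_cut`` and ``p <= p_cut`` (both cutoffs
    inclusive), on adjusted or raw p per ``use_adjusted``."""
    pcol = "adj_p_value" if use_adjusted else "p_value"
    mask = (table["log2FC"].abs() >= fc_cut) & (table[pcol] <= p_cut)
    mask &= table["converged"]
    return sorted(table.loc[mask, "gene"].tolist())


def contrast_noncluster(
    ds: SpotDataset,
    labels: SpotLabels,
    clusters: list[DensityCluster],
    cytokine: str,
    epidermis_layers=EPIDERMIS_LAYERS,
) -> tuple[np.ndarray, np.ndarray]:
    """Condition vector for the cytokine-related-gene contrast.

    Within the epidermal spot universe: positives are cytokine-positive
    spots; negatives are spots belonging to no density cluster at the
    optimal radius; cytokine-negative spots inside a cluster ring are
    excluded from both groups.  Returns ``(condition, include)`` boolean
    arrays over all dataset spots.
    """
    epidermal = ds.spots["layer"].isin(epidermis_layers).to_numpy()
    pos = labels.cytokine_pos[cytokine] & epidermal

    in_cluster = np.zeros(ds.n_spots, dtype=bool)
    by_sample: dict[str, set] = {}
    for c in clusters:
        by_sample.setdefault(c.sample_id, set()).update(c.member_spots)
    for sample_id, members in by_sample.items():
        cmap = ds.coord_map(sample_id)
        rows = [cmap[m] for m in members if m in cmap]
        in_cluster[rows] = True

    neg = epidermal & ~in_cluster & ~labels.cytokine_pos[cytokine]
    include = pos | neg
    if not neg.any():
        raise DesignError("empty negative set: every epidermal spot is clustered")
    return pos, include
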