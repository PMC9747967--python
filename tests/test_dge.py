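"""Design construction, NB GLM inference, BH correction and contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from conftest import make_dataset
from hexniche import dge
from hexniche.annotate import build_labels
from hexniche.hexcluster import DensityCluster
from hexniche.preprocess import NormFactors, compute_norm_factors


def nb_counts(rng, mu, theta, size):
    lam = rng.gamma(theta, np.asarray(mu) / theta, size=size)
    return rng.poisson(lam)


def simple_design(n, rng, frac=0.5):
    cond = (rng.random(n) < frac).astype(float)
    X = pd.DataFrame({"intercept": np.ones(n), "condition": cond})
    return X, cond


# --- build_design ----------------------------------------------------------


def design_dataset():
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(5)]
    counts = rng.integers(0, 9, size=(8, 5))
    coords = [(r, r % 2) for r in range(8)]
    coords = [(r, c if (r + c) % 2 == 0 else c + 1) for r, c in coords]
    ds = make_dataset(counts, coords, genes)
    # two patients, two layers
    ds.spots["layer"] = ["upper epidermis"] * 4 + ["basal epidermis"] * 4
    ds.meta = pd.DataFrame(
        {
            "sample_id": ["S01"],
            "patient_id": ["P01"],
            "project_id": ["PRJ1"],
            "disease": ["Pso"],
            "condition": ["lesional"],
        }
    ).set_index("sample_id")
    return ds


def test_reference_coding_columns():
    ds = design_dataset()
    nf = compute_norm_factors(ds)
    cond = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    X, offset = dge.build_design(
        ds, nf, cond, dge.DesignSpec(covariates=("cdr", "annotation"))
    )
    assert list(X.columns) == ["intercept", "cdr", "annotation[upper epidermis]", "condition"]
    assert X["cdr"].mean() == pytest.approx(0.0, abs=1e-12)


def test_constant_condition_fatal():
    ds = design_dataset()
    nf = compute_norm_factors(ds)
    with pytest.raises(dge.DesignError, match="constant"):
        dge.build_design(ds, nf, np.zeros(8))


def test_confounded_covariate_dropped_with_warning():
    ds = design_dataset()
    nf = compute_norm_factors(ds)
    cond = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)  # == layer split
    with pytest.warns(UserWarning, match="collinear"):
        X, _ = dge.build_design(
            ds, nf, cond, dge.DesignSpec(covariates=("annotation",))
        )
    # the confounded covariate is dropped, never the tested contrast
    assert "condition" in X.columns
    assert not any(c.startswith("annotation") for c in X.columns)


def test_unit_size_factors_zero_offset():
    ds = design_dataset()
    lib = ds.library_sizes().astype(float)
    nf = NormFactors(size_factor=np.ones(8), cdr=lib / lib)
    cond = np.array([0, 1] * 4, dtype=float)
    _, offset = dge.build_design(ds, nf, cond)
    assert np.allclose(offset, 0.0)


# --- bh_adjust -------------------------------------------------------------


def test_bh_hand_example():
    assert dge.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_single_and_equal():
    assert dge.bh_adjust([0.2]) == pytest.approx([0.2])
    assert dge.bh_adjust([0.04, 0.04, 0.04]) == pytest.approx([0.04, 0.04, 0.04])


def test_bh_permutation_equivariant():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=50)
    adj = dge.bh_adjust(p)
    perm = rng.permutation(50)
    assert dge.bh_adjust(p[perm]) == pytest.approx(adj[perm])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(2)
    p = rng.uniform(size=200) ** 2
    ref = multipletests(p, method="fdr_bh")[1]
    assert dge.bh_adjust(p) == pytest.approx(ref)


def test_bh_adjusted_geq_raw():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=100)
    assert (dge.bh_adjust(p) >= p - 1e-12).all()


# --- call_degs -------------------------------------------------------------


def deg_table(rows):
    df = pd.DataFrame(rows, columns=["gene", "log2FC", "p_value", "adj_p_value"])
    df["converged"] = True
    return df


def test_cutoffs_inclusive():
    t = deg_table([("A", 1.0, 0.05, 0.05), ("B", 0.9, 0.01, 0.01), ("C", -1.2, 0.01, 0.01)])
    assert dge.call_degs(t) == ["A", "C"]
    assert dge.call_degs(t, use_adjusted=False) == ["A", "C"]


def test_call_degs_monotone_in_cutoffs():
    rng = np.random.default_rng(4)
    t = deg_table(
        [(f"G{i}", fc, p, p) for i, (fc, p) in enumerate(zip(rng.normal(0, 2, 50), rng.uniform(size=50)))]
    )
    loose = set(dge.call_degs(t, fc_cut=0.5, p_cut=0.2))
    tight = set(dge.call_degs(t, fc_cut=1.0, p_cut=0.05))
    assert tight <= loose


# --- fit_nb_glm ------------------------------------------------------------


def test_null_type_one_error_calibrated():
    rng = np.random.default_rng(5)
    n, G = 500, 200
    X, _ = simple_design(n, rng)
    Y = nb_counts(rng, 2.0, 2.0, (n, G))
    tab = dge.fit_nb_glm(Y, X, np.zeros(n))
    frac = (tab["p_value"] < 0.05).mean()
    assert 0.03 <= frac <= 0.07


def test_planted_fold_change_recovered():
    rng = np.random.default_rng(6)
    n = 600
    cond = np.repeat([0.0, 1.0], n // 2)
    X = pd.DataFrame({"intercept": np.ones(n), "condition": cond})
    mu = 2.0 * 4.0**cond  # 4-fold in the condition arm
    Y = nb_counts(rng, np.tile(mu[:, None], (1, 20)), 2.0, (n, 20))
    tab = dge.fit_nb_glm(Y, X, np.zeros(n))
    assert tab["log2FC"].mean() == pytest.approx(2.0, abs=0.5)
    assert (tab["adj_p_value"] < 0.05).all()


def test_poisson_limit_matches_poisson_glm():
    rng = np.random.default_rng(7)
    n = 400
    X, cond = simple_design(n, rng)
    mu = 3.0 * 2.0**cond
    Y = rng.poisson(np.tile(mu[:, None], (1, 5)))
    tab = dge.fit_nb_glm(Y, X, np.zeros(n))
    for g in range(5):
        ref = sm.GLM(Y[:, g], X.to_numpy(), family=sm.families.Poisson()).fit()
        assert tab.loc[g, "log2FC"] == pytest.approx(ref.params[1] / np.log(2), abs=1e-3)


def test_offset_absorbs_depth():
    rng = np.random.default_rng(8)
    n = 400
    X, cond = simple_design(n, rng)
    depth = rng.uniform(0.5, 2.0, n)
    mu = 2.0 * depth  # no condition effect beyond depth
    Y = nb_counts(rng, np.tile(mu[:, None], (1, 30)), 2.0, (n, 30))
    with_offset = dge.fit_nb_glm(Y, X, np.log(depth))
    assert (with_offset["p_value"] < 0.05).mean() < 0.15


def test_all_zero_genes_excluded():
    rng = np.random.default_rng(9)
    n = 100
    X, _ = simple_design(n, rng)
    Y = np.zeros((n, 3), dtype=int)
    Y[:, 1] = rng.poisson(2.0, n)
    tab = dge.fit_nb_glm(Y, X, np.zeros(n))
    assert list(tab["gene"]) == [1]


def test_wald_p_uniform_under_null():
    """KS test against uniform at 2000 simulated null genes."""
    rng = np.random.default_rng(10)
    n, G = 300, 2000
    X, _ = simple_design(n, rng)
    Y = nb_counts(rng, 1.5, 2.0, (n, G))
    tab = dge.fit_nb_glm(Y, X, np.zeros(n))
    p = tab.loc[tab["converged"], "p_value"].to_numpy()
    assert len(p) > 1900
    ks = stats.kstest(p, "uniform")
    assert ks.pvalue > 1e-3


# --- contrast_noncluster ---------------------------------------------------


def contrast_fixture():
    genes = ["IL17A", "CD3D", "R1"]
    coords = [(0, 0), (0, 2), (0, 4), (0, 6), (0, 8), (2, 0)]
    counts = np.zeros((6, 3), dtype=int)
    counts[0] = [2, 1, 5]  # cytokine+ seed
    counts[1] = [0, 0, 9]  # ring spot (cytokine-)
    counts[2:] = [0, 1, 1]
    ds = make_dataset(counts, coords, genes)
    ds.spots.loc[5, "layer"] = "dermis 1"  # non-epidermal spot
    labels = build_labels(ds, markers=["CD3D"], cytokines=["IL17A"])
    cluster = DensityCluster(
        "S01:0_0:r1", "S01", 1, frozenset({(0, 0)}), frozenset({(0, 2)})
    )
    return ds, labels, cluster


def test_contrast_groups():
    ds, labels, cluster = contrast_fixture()
    cond, include = dge.contrast_noncluster(ds, labels, [cluster], "IL17A")
    assert cond.tolist() == [True, False, False, False, False, False]
    # ring spot (idx 1) excluded; dermal spot (idx 5) excluded from universe
    assert include.tolist() == [True, False, True, True, True, False]


def test_contrast_no_clusters_all_negatives():
    ds, labels, _ = contrast_fixture()
    cond, include = dge.contrast_noncluster(ds, labels, [], "IL17A")
    assert include.tolist() == [True, True, True, True, True, False]
    assert cond.sum() == 1


def test_contrast_all_clustered_fatal():
    ds, labels, _ = contrast_fixture()
    big = DensityCluster(
        "S01:big", "S01", 9,
        frozenset({(0, 0)}),
        frozenset({(0, 2), (0, 4), (0, 6), (0, 8)}),
    )
    with pytest.raises(dge.DesignError, match="negative"):
        dge.contrast_noncluster(ds, labels, [big], "IL17A")
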