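"""Constrained ordination, variance partitioning, dbMEM, forward selection,
loading-based outliers, the genotype-temperature GLM and PAV consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from landgea.environment import EnvTable
from landgea.rda import (
    RdaModel,
    anova_axes,
    consensus_outliers,
    dbmem_basis,
    ezekiel_adjusted_r2,
    forward_select,
    glm_binomial_gea,
    rda_fit,
    rda_outliers,
    variance_partition,
    vif_prune,
)


def _transect_coords(n=39):
    return pd.DataFrame(
        {"population": [f"p{i}" for i in range(n)], "lat": np.linspace(68, 50, n), "lon": 24.0}
    )


# ---------------------------------------------------------------------------
# vif_prune


def test_vif_prune_duplicate_and_orthogonal():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(30, 3))
    df = pd.DataFrame(base, columns=["a", "b", "c"])
    df["a_copy"] = df["a"]
    kept, dropped = vif_prune(df)
    assert len([v for v in ("a", "a_copy") if v in kept]) == 1
    # near-orthogonal variables all retained
    kept2, dropped2 = vif_prune(pd.DataFrame(rng.normal(size=(200, 4)), columns=list("wxyz")))
    assert kept2 == list("wxyz") and not dropped2


def test_vif_prune_drops_linear_combination_first():
    rng = np.random.default_rng(1)
    x1, x2 = rng.normal(size=(2, 100))
    x3 = x1 + x2 + rng.normal(0, 0.05, 100)
    df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
    kept, dropped = vif_prune(df, r_max=0.95)
    assert "x3" in dropped and kept == ["x1", "x2"]


# ---------------------------------------------------------------------------
# rda_fit


def test_rda_single_column_equals_ols_r2():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = 1.5 * x + rng.normal(size=40)
    m = rda_fit(y[:, None], x[:, None])
    assert m.r2 == pytest.approx(stats.linregress(x, y).rvalue ** 2, abs=1e-12)


def test_rda_conditioning_on_itself_removes_everything():
    rng = np.random.default_rng(3)
    x = rng.normal(size=30)
    y = rng.normal(size=(30, 5))
    m = rda_fit(y, x[:, None], Z=x[:, None])
    assert abs(m.r2) < 1e-10


def test_ezekiel_arithmetic():
    assert ezekiel_adjusted_r2(0.5, 11, 1) == pytest.approx(4.0 / 9.0)


def test_rda_with_orthonormal_x_matches_pca_of_fitted_subspace():
    rng = np.random.default_rng(4)
    Y = rng.normal(size=(25, 40))
    Q, _ = np.linalg.qr(rng.normal(size=(25, 3)))
    m = rda_fit(Y, Q)
    Yc = Y - Y.mean(axis=0)
    fitted = Q @ np.linalg.lstsq((Q - Q.mean(0)) / Q.std(0, ddof=1), Yc, rcond=None)[0] * 0
    # eigenvalues of the ordination equal PCA eigenvalues of the projection
    Xs = (Q - Q.mean(axis=0)) / Q.std(axis=0, ddof=1)
    H = Xs @ np.linalg.pinv(Xs)
    proj = H @ Yc
    eig_pca = np.linalg.svd(proj, compute_uv=False) ** 2 / (25 - 1)
    assert np.allclose(m.eigenvalues, eig_pca[: len(m.eigenvalues)], atol=1e-10)


def test_rda_too_many_predictors_errors():
    rng = np.random.default_rng(5)
    with pytest.raises(ValueError, match="cannot constrain"):
        rda_fit(rng.normal(size=(5, 3)), rng.normal(size=(5, 6)))


# ---------------------------------------------------------------------------
# anova_axes


def test_anova_axes_detects_planted_axis_and_respects_lower_bound():
    rng = np.random.default_rng(6)
    n = 30
    x = rng.normal(size=(n, 2))
    Y = np.outer(x[:, 0], rng.normal(size=20)) + 0.1 * rng.normal(size=(n, 20))
    m = rda_fit(Y, x)
    p = anova_axes(m, n_perm=199, rng=0)
    assert p[0] == pytest.approx(1 / 200)
    assert np.all(p >= 1 / 200)


def test_anova_axes_null_uniform():
    rng = np.random.default_rng(7)
    pvals = []
    for rep in range(100):
        Y = rng.normal(size=(18, 30))
        x = rng.normal(size=(18, 1))
        m = rda_fit(Y, x)
        pvals.append(anova_axes(m, n_perm=99, rng=rng)[0])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# variance partitioning


def test_variance_partition_identity_and_orthogonal_blocks():
    rng = np.random.default_rng(8)
    n = 50
    Xe = rng.normal(size=(n, 2))
    Xg = rng.normal(size=(n, 2))
    Y = Xe @ rng.normal(size=(2, 30)) + Xg @ rng.normal(size=(2, 30)) + rng.normal(size=(n, 30))
    part = variance_partition(Y, Xe, Xg)
    total = part.env_exclusive + part.confounded + part.geo_exclusive
    assert total == pytest.approx(part.adj_r2_combined, abs=1e-10)
    assert part.unexplained == pytest.approx(1 - part.adj_r2_combined, abs=1e-10)

    bs = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        Xe = r.normal(size=(40, 2))
        Xg = r.normal(size=(40, 2))
        Y = Xe @ r.normal(size=(2, 20)) + Xg @ r.normal(size=(2, 20)) + r.normal(size=(40, 20))
        bs.append(variance_partition(Y, Xe, Xg).confounded)
    assert abs(np.mean(bs)) < 0.02


def test_variance_partition_invariant_to_reparameterization():
    rng = np.random.default_rng(9)
    Xe = rng.normal(size=(40, 3))
    Xg = rng.normal(size=(40, 2))
    Y = Xe @ rng.normal(size=(3, 25)) + rng.normal(size=(40, 25))
    A = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible
    p1 = variance_partition(Y, Xe, Xg)
    p2 = variance_partition(Y, Xe @ A, Xg)
    assert p1.env_exclusive == pytest.approx(p2.env_exclusive, abs=1e-8)
    assert p1.confounded == pytest.approx(p2.confounded, abs=1e-8)


# ---------------------------------------------------------------------------
# dbMEM and forward selection


def test_dbmem_transect_counts_and_orthogonality():
    mem = dbmem_basis(_transect_coords(39))
    assert mem.n_candidates == 38  # n - 1 after Gower centering
    V = mem.eigenvectors.to_numpy()
    assert V.shape[0] == 39 and V.shape[1] <= 38
    assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
    assert np.all(mem.eigenvalues > 0)
    with pytest.raises(ValueError, match="duplicate"):
        coords = _transect_coords(5)
        coords.loc[1, ["lat", "lon"]] = coords.loc[0, ["lat", "lon"]]
        dbmem_basis(coords)


def test_forward_select_null_and_planted():
    rng = np.random.default_rng(10)
    empty_runs = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        Y = r.normal(size=(30, 10))
        cands = pd.DataFrame(r.normal(size=(30, 5)), columns=list("abcde"))
        if not forward_select(Y, cands, n_perm=99, rng=r):
            empty_runs += 1
    assert empty_runs >= 8  # pure noise rarely admits a variable

    # the strongest true candidate is admitted first; a second, weaker true
    # candidate keeps the global-adjusted-R^2 guard from binding at step 1
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(100 + seed)
        cands = pd.DataFrame(r.normal(size=(30, 5)), columns=list("abcde"))
        Y = (
            np.outer(cands["c"], np.ones(10))
            + 0.5 * np.outer(cands["a"], np.ones(10))
            + 0.5 * r.normal(size=(30, 10))
        )
        sel = forward_select(Y, cands, n_perm=99, rng=r)
        if sel and sel[0] == "c":
            hits += 1
    assert hits >= 9


# ---------------------------------------------------------------------------
# loading outliers


def _model_with_loadings(loadings: np.ndarray) -> RdaModel:
    m, k = loadings.shape
    return RdaModel(
        coefficients=np.zeros((1, m)),
        eigenvalues=np.ones(k),
        site_scores=np.zeros((3, k)),
        locus_loadings=loadings,
        biplot_scores=pd.DataFrame(np.ones((1, k)), index=["x"],
                                   columns=[f"RDA{i+1}" for i in range(k)]),
        r2=0.5, adj_r2=0.4, total_variance=1.0,
        predictor_names=["x"], locus_names=[f"L{j}" for j in range(m)],
        site_names=["s1", "s2", "s3"],
        x_mean=np.zeros(1), x_sd=np.ones(1), y_mean=np.zeros(m),
    )


def test_rda_outliers_normal_tail_fraction():
    rng = np.random.default_rng(11)
    m = 10_000
    model = _model_with_loadings(rng.standard_normal((m, 1)))
    out = rda_outliers(model, sd_mult=2.5, axes=[1])
    expect = 2 * stats.norm.sf(2.5)
    ci = stats.binom.interval(0.999, m, expect)
    assert ci[0] <= len(out) <= ci[1]


def test_rda_outliers_sign_flip_invariant():
    rng = np.random.default_rng(12)
    L = rng.standard_normal((500, 2))
    out1 = rda_outliers(_model_with_loadings(L), axes=[1, 2])
    out2 = rda_outliers(_model_with_loadings(L * np.array([-1, 1])), axes=[1, 2])
    assert set(out1.index) == set(out2.index)


def test_rda_outliers_annotates_best_predictor(qc_default, default_panel):
    _, _, freq = qc_default
    env = EnvTable(default_panel.env.data)
    model = rda_fit(freq, env.data)
    out = rda_outliers(model, axes=[1], freqs=freq, env=env)
    adaptive = set(default_panel.adaptive_loci)
    flagged_adaptive = [l for l in out.index if l in adaptive]
    assert len(flagged_adaptive) >= 0.7 * len(adaptive)
    best = out.loc[flagged_adaptive, "best_predictor"]
    assert (best == "mean_temp").mean() > 0.8  # clines are temperature-driven


# ---------------------------------------------------------------------------
# GLM


def test_glm_odds_ratio_and_null_behaviour():
    res_or = np.exp(0.37)
    assert round(res_or, 2) == 1.45
    rng = np.random.default_rng(13)
    x = rng.normal(size=200)
    d = rng.binomial(2, 0.3, size=200)
    res = glm_binomial_gea(d, x)
    assert res.converged and abs(res.beta1) < 2 * res.se * 2
    assert res.odds_ratio == pytest.approx(np.exp(res.beta1))


def test_glm_degenerate_dosages_flagged():
    x = np.linspace(-1, 1, 50)
    res = glm_binomial_gea(np.full(50, 2.0), x)
    assert not res.converged


def test_glm_homozygote_coding():
    rng = np.random.default_rng(14)
    x = rng.normal(size=500)
    p = 1 / (1 + np.exp(-(0.8 * x)))
    d = rng.binomial(2, p)
    res = glm_binomial_gea(d, x, coding="homozygote")
    assert res.converged and res.beta1 > 0


# ---------------------------------------------------------------------------
# consensus


def test_consensus_set_algebra():
    res = consensus_outliers({"a", "b", "c"}, {"b", "c"}, {"c"})
    assert res.pav == ["c"]
    assert res.two_of_three == ["b", "c"]
    assert res.venn_counts["pav"] == 1
    assert consensus_outliers(set(), {"a"}, {"a"}).pav == []
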