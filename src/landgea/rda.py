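"""Redundancy analysis engine for genotype-environment association.

Implements constrained ordination (RDA) of population allele frequencies
on environmental predictors, partial RDA by residualizing response and
predictors on a conditioning matrix, adjusted-R^2 variance partitioning
between environment and geography, distance-based Moran's eigenvector
maps (dbMEM) as spatial predictors with two-criterion forward selection,
loading-based outlier detection at +/- 2.5 SD, a per-locus binomial GLM
of genotype on temperature, and the three-method consensus that defines
potential adaptive variants (PAVs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree

from .environment import EnvTable
from .popgen import geodesic_distances

_EIG_TOL = 1e-10


def ezekiel_adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _standardize(X: np.ndarray, mean=None, sd=None):
    mean = X.mean(axis=0) if mean is None else mean
    sd = X.std(axis=0, ddof=1) if sd is None else sd
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


@dataclass
class RdaModel:
    """A fitted (partial) redundancy analysis."""

    coefficients: np.ndarray  # predictors x loci, on standardized X
    eigenvalues: np.ndarray  # canonical, descending
    site_scores: np.ndarray  # sites x axes
    locus_loadings: np.ndarray  # loci x axes
    biplot_scores: pd.DataFrame  # predictors x axes (corr with site scores)
    r2: float
    adj_r2: float
    total_variance: float
    predictor_names: list[str]
    locus_names: list[str]
    site_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    conditioned: bool = False
    # retained for permutation tests
    _Y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def linear_predictions(self, env_std: np.ndarray) -> np.ndarray:
        """Fitted frequencies (uncentering included) at standardized env."""
        return env_std @ self.coefficients + self.y_mean


def _fit_r2(Yc: np.ndarray, Xs: np.ndarray, total: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares fit of Yc on Xs via SVD projection.

    Singular values below an absolute tolerance (relative to the sqrt(n)
    scale of standardized columns) are discarded, so predictors reduced to
    numerical noise by residualization span nothing.
    """
    n = Xs.shape[0]
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    keep = S > 1e-8 * np.sqrt(n)
    Ur, Sr, Vr = U[:, keep], S[keep], Vt[keep]
    coef_r = Ur.T @ Yc
    B = Vr.T @ (coef_r / Sr[:, None])
    fitted = Ur @ coef_r
    return B, fitted, float((fitted**2).sum()) / total


def rda_fit(
    Y: pd.DataFrame | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    Z: pd.DataFrame | np.ndarray | None = None,
) -> RdaModel:
    """Fit a redundancy analysis of Y on X, optionally conditioned on Z.

    Y is column-centered, X (and Z) standardized.  With a conditioning
    matrix, both Y and X are first residualized on Z (the standard pCCA
    construction); R^2 is reported relative to the total variance of the
    unconditioned response, and the adjusted R^2 of a partial model is the
    semipartial difference adjR2([X Z]) - adjR2(Z).
    """
    y_df = isinstance(Y, pd.DataFrame)
    x_df = isinstance(X, pd.DataFrame)
    site_names = list(Y.index) if y_df else [f"site{i}" for i in range(np.asarray(Y).shape[0])]
    locus_names = list(Y.columns) if y_df else [f"y{j}" for j in range(np.asarray(Y).shape[1])]
    predictor_names = list(X.columns) if x_df else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    Ya = np.asarray(Y, float)
    Xa = np.asarray(X, float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    n, p = Xa.shape
    if Ya.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    if Z is None and n <= p:
        raise ValueError(f"n={n} sites cannot constrain p={p} predictors")

    y_mean = Ya.mean(axis=0)
    Yc = Ya - y_mean
    total = float((Yc**2).sum())
    if total == 0:
        raise ValueError("response matrix is constant")
    Xs, x_mean, x_sd = _standardize(Xa)

    adj_r2: float
    if Z is not None:
        Za = np.asarray(Z, float)
        if Za.ndim == 1:
            Za = Za[:, None]
        Zs, _, _ = _standardize(Za)
        # semipartial adjusted R^2 from the combined and conditioning models
        _, _, r2_comb = _fit_r2(Yc, np.column_stack([Xs, Zs]), total)
        _, _, r2_z = _fit_r2(Yc, Zs, total)
        adj_r2 = ezekiel_adjusted_r2(r2_comb, n, p + Zs.shape[1]) - ezekiel_adjusted_r2(
            r2_z, n, Zs.shape[1]
        )
        Hz = Zs @ np.linalg.pinv(Zs)
        Yc = Yc - Hz @ Yc
        Xs = Xs - Hz @ Xs

    B, fitted, r2 = _fit_r2(Yc, Xs, total)
    if Z is None:
        adj_r2 = ezekiel_adjusted_r2(r2, n, p)

    U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
    keep = S**2 > _EIG_TOL * max(S[0] ** 2, 1.0) if S.size else np.array([], bool)
    U, S, Vt = U[:, keep], S[keep], Vt[keep]
    eigenvalues = S**2 / (n - 1)
    site_scores = U * S
    loadings = Vt.T

    bip = np.zeros((p, len(S)))
    for k in range(len(S)):
        ss = site_scores[:, k]
        for j in range(p):
            xj = Xs[:, j]
            if ss.std() > 0 and xj.std() > 0:
                bip[j, k] = np.corrcoef(xj, ss)[0, 1]
    biplot = pd.DataFrame(
        bip, index=predictor_names, columns=[f"RDA{k + 1}" for k in range(len(S))]
    )

    return RdaModel(
        coefficients=B,
        eigenvalues=eigenvalues,
        site_scores=site_scores,
        locus_loadings=loadings,
        biplot_scores=biplot,
        r2=r2,
        adj_r2=adj_r2,
        total_variance=total,
        predictor_names=predictor_names,
        locus_names=locus_names,
        site_names=site_names,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        conditioned=Z is not None,
        _Y=Yc,
        _X=Xs,
    )


def anova_axes(
    model: RdaModel,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sequential permutation test of each canonical axis.

    For axis k, rows of the response residuals around the first k-1 axes'
    reconstruction are permuted, the ordination refitted, and the axis-k
    eigenvalue compared with the observed one (add-one convention).
    """
    import warnings

    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a coarse p-value resolution")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Yc, Xs = model._Y, model._X
    n = Yc.shape[0]
    p_values = np.empty(model.n_axes)
    for k in range(model.n_axes):
        structure = model.site_scores[:, :k] @ model.locus_loadings[:, :k].T
        resid = Yc - structure
        obs = model.eigenvalues[k]
        count = 0
        for _ in range(n_perm):
            Ystar = structure + resid[rng.permutation(n)]
            _, fitted, _ = _fit_r2(Ystar, Xs, 1.0)
            s = np.linalg.svd(fitted, compute_uv=False)
            eig = s**2 / (n - 1)
            if len(eig) > k and eig[k] >= obs:
                count += 1
        p_values[k] = (count + 1) / (n_perm + 1)
    return p_values


@dataclass
class VariancePartition:
    env_exclusive: float  # [a]
    confounded: float  # [b]
    geo_exclusive: float  # [c]
    unexplained: float
    adj_r2_env: float
    adj_r2_geo: float
    adj_r2_combined: float
    r2_env: float
    r2_geo: float
    r2_combined: float


def variance_partition(
    Y: pd.DataFrame | np.ndarray,
    X_env: pd.DataFrame | np.ndarray,
    X_geo: pd.DataFrame | np.ndarray,
) -> VariancePartition:
    """Adjusted-R^2 partition of Y between environment and geography.

    a = adjR2(env+geo) - adjR2(geo) (environment-exclusive),
    c = adjR2(env+geo) - adjR2(env) (geography-exclusive),
    b = adjR2(env+geo) - a - c (confounded); a + b + c equals the combined
    adjusted R^2 by construction.
    """
    Xe = np.asarray(X_env, float)
    Xg = np.asarray(X_geo, float)
    if Xe.ndim == 1:
        Xe = Xe[:, None]
    if Xg.ndim == 1:
        Xg = Xg[:, None]
    m_env = rda_fit(Y, Xe)
    m_geo = rda_fit(Y, Xg)
    m_comb = rda_fit(Y, np.column_stack([Xe, Xg]))
    a = m_comb.adj_r2 - m_geo.adj_r2
    c = m_comb.adj_r2 - m_env.adj_r2
    b = m_comb.adj_r2 - a - c
    return VariancePartition(
        env_exclusive=a,
        confounded=b,
        geo_exclusive=c,
        unexplained=1.0 - m_comb.adj_r2,
        adj_r2_env=m_env.adj_r2,
        adj_r2_geo=m_geo.adj_r2,
        adj_r2_combined=m_comb.adj_r2,
        r2_env=m_env.r2,
        r2_geo=m_geo.r2,
        r2_combined=m_comb.r2,
    )


# ---------------------------------------------------------------------------
# predictor preparation


def vif_prune(
    env: EnvTable | pd.DataFrame, r_max: float = 0.7, vif_max: float = 10.0
) -> tuple[list[str], dict[str, str]]:
    """Drop collinear predictors by pairwise |r|, then by VIF.

    First iteratively removes the variable with the highest mean absolute
    correlation among pairs with |r| >= r_max, then iteratively removes the
    highest-VIF variable while any VIF >= vif_max.  Returns the retained
    variable names and a {dropped: reason} report.
    """
    df = env.data if isinstance(env, EnvTable) else env
    if df.shape[1] < 2:
        raise ValueError("vif_prune needs >= 2 variables")
    dropped: dict[str, str] = {}
    cols = list(df.columns)

    while len(cols) > 1:
        corr = df[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        violating = corr >= r_max
        if not violating.any():
            break
        mean_r = np.where(violating.any(axis=1), corr.mean(axis=1), -1.0)
        worst = int(np.argmax(mean_r))
        dropped[cols[worst]] = f"pairwise |r| >= {r_max}"
        cols.pop(worst)

    while len(cols) > 1:
        X = df[cols].to_numpy(float)
        Xs, _, _ = _standardize(X)
        vifs = []
        for j in range(len(cols)):
            others = np.delete(Xs, j, axis=1)
            _, _, r2 = _fit_r2(Xs[:, [j]], others, float((Xs[:, j] ** 2).sum()))
            vifs.append(1.0 / max(1.0 - r2, 1e-12))
        vifs = np.asarray(vifs)
        if vifs.max() < vif_max:
            break
        worst = int(np.argmax(vifs))
        dropped[cols[worst]] = f"VIF {vifs[worst]:.1f} >= {vif_max}"
        cols.pop(worst)

    if not cols:
        raise ValueError("all variables collinear; nothing retained")
    return cols, dropped


@dataclass
class DbMemBasis:
    eigenvectors: pd.DataFrame  # sites x positive axes (MEM1, MEM2, ...)
    eigenvalues: np.ndarray  # positive, descending
    truncation: float  # meters
    n_candidates: int  # nonzero axes before positivity filtering


def dbmem_basis(coords: pd.DataFrame, eig_tol: float = 1e-8) -> DbMemBasis:
    """Distance-based Moran's eigenvector maps from geodesic distances.

    The distance matrix is truncated at the longest minimum-spanning-tree
    edge t (entries beyond t replaced by 4t), Gower-centered as -D.^2/2,
    and eigen-decomposed; positive-eigenvalue eigenvectors become the
    spatial predictors.
    """
    if coords.shape[0] < 3:
        raise ValueError("dbmem_basis needs >= 3 sites")
    D = geodesic_distances(coords).to_numpy()
    n = D.shape[0]
    off = D[~np.eye(n, dtype=bool)]
    if (off == 0).any():
        raise ValueError("duplicate coordinates: zero off-diagonal distance")
    mst = minimum_spanning_tree(D).toarray()
    t = float(mst.max())
    Dt = np.where(D > t, 4.0 * t, D)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    Gc = J @ A @ J
    w, V = np.linalg.eigh((Gc + Gc.T) / 2.0)
    w, V = w[::-1], V[:, ::-1]
    scale = max(abs(w[0]), 1.0)
    nonzero = np.abs(w) > eig_tol * scale
    positive = (w > eig_tol * scale)
    vecs = V[:, positive]
    pops = list(coords["population"])
    basis = pd.DataFrame(
        vecs, index=pops, columns=[f"MEM{k + 1}" for k in range(vecs.shape[1])]
    )
    return DbMemBasis(
        eigenvectors=basis,
        eigenvalues=w[positive],
        truncation=t,
        n_candidates=int(nonzero.sum()),
    )


def forward_select(
    Y: pd.DataFrame | np.ndarray,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Two-criterion forward selection of constraining variables.

    At each step the candidate giving the largest adjusted R^2 is admitted
    if its marginal permutation p-value is below ``alpha`` and the
    cumulative adjusted R^2 stays at or below the global (all-candidate)
    model's adjusted R^2; selection stops otherwise.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    Ya = np.asarray(Y, float)
    n = Ya.shape[0]
    Yc = Ya - Ya.mean(axis=0)
    total = float((Yc**2).sum())
    names = list(candidates.columns)
    global_adj = rda_fit(Yc, candidates).adj_r2

    selected: list[str] = []
    remaining = list(names)
    r2_old = 0.0
    while remaining:
        best_name, best_adj, best_r2 = None, -np.inf, 0.0
        for cand in remaining:
            cols = selected + [cand]
            Xs, _, _ = _standardize(candidates[cols].to_numpy(float))
            _, _, r2 = _fit_r2(Yc, Xs, total)
            adj = ezekiel_adjusted_r2(r2, n, len(cols))
            if adj > best_adj:
                best_name, best_adj, best_r2 = cand, adj, r2
        if best_name is None or best_adj > global_adj:
            break
        # marginal permutation test of the admitted candidate
        cols_new = selected + [best_name]
        p_new = len(cols_new)
        f_obs = _pseudo_f(best_r2, r2_old, n, p_new)
        if selected:
            Xs_old, _, _ = _standardize(candidates[selected].to_numpy(float))
            _, fit_old, _ = _fit_r2(Yc, Xs_old, total)
        else:
            fit_old = np.zeros_like(Yc)
        resid = Yc - fit_old
        Xs_new, _, _ = _standardize(candidates[cols_new].to_numpy(float))
        if selected:
            Xs_old_only = Xs_new[:, :-1]
        count = 0
        for _ in range(n_perm):
            Ystar = fit_old + resid[rng.permutation(n)]
            tot_star = float(((Ystar - Ystar.mean(axis=0)) ** 2).sum())
            _, _, r2_new_s = _fit_r2(Ystar - Ystar.mean(axis=0), Xs_new, tot_star)
            if selected:
                _, _, r2_old_s = _fit_r2(Ystar - Ystar.mean(axis=0), Xs_old_only, tot_star)
            else:
                r2_old_s = 0.0
            if _pseudo_f(r2_new_s, r2_old_s, n, p_new) >= f_obs:
                count += 1
        p_val = (count + 1) / (n_perm + 1)
        if p_val >= alpha:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        r2_old = best_r2
    return selected


def _pseudo_f(r2_new: float, r2_old: float, n: int, p_new: int) -> float:
    denom = (1.0 - r2_new) / max(n - p_new - 1, 1)
    return (r2_new - r2_old) / max(denom, 1e-300)


# ---------------------------------------------------------------------------
# outlier calling and the GLM


def rda_outliers(
    model: RdaModel,
    sd_mult: float = 2.5,
    axes: list[int] | None = None,
    freqs: pd.DataFrame | None = None,
    env: EnvTable | None = None,
) -> pd.DataFrame:
    """Loci with loadings beyond ``sd_mult`` SD on the retained axes.

    ``axes`` are 1-based canonical-axis numbers (default: axis 1).  When
    population frequencies and an environment table are supplied, each
    flagged locus is annotated with the predictor of maximum absolute
    correlation with its frequencies.
    """
    import warnings

    if axes is None:
        axes = [1]
    axes = [a for a in axes if 1 <= a <= model.n_axes]
    if not axes:
        warnings.warn("no significant axes; empty outlier set")
        return pd.DataFrame(columns=["axis", "loading", "best_predictor"])
    rows = []
    flagged: dict[str, dict] = {}
    for a in axes:
        lo = model.locus_loadings[:, a - 1]
        mu, sd = lo.mean(), lo.std(ddof=1)
        for j in np.flatnonzero(np.abs(lo - mu) > sd_mult * sd):
            lid = model.locus_names[j]
            if lid not in flagged:
                flagged[lid] = {"axis": a, "loading": float(lo[j])}
    for lid, info in flagged.items():
        best = None
        if freqs is not None and env is not None:
            f = freqs[lid].to_numpy(float)
            corrs = {
                var: abs(np.corrcoef(f, env.data[var].to_numpy(float))[0, 1])
                for var in env.variables
                if np.std(env.data[var].to_numpy(float)) > 0 and np.std(f) > 0
            }
            if corrs:
                best = max(corrs, key=corrs.get)
        rows.append({"locus": lid, **info, "best_predictor": best})
    return pd.DataFrame(rows).set_index("locus") if rows else pd.DataFrame(
        columns=["axis", "loading", "best_predictor"]
    )


@dataclass
class GlmResult:
    beta0: float
    beta1: float
    odds_ratio: float
    se: float
    z: float
    p: float
    converged: bool


def glm_binomial_gea(
    dosages: np.ndarray, env_values: np.ndarray, coding: str = "dosage"
) -> GlmResult:
    """Binomial logistic regression of genotype on an environmental value.

    ``coding='dosage'`` treats each diploid as two Bernoulli trials
    (dosage successes out of 2); ``coding='homozygote'`` contrasts minor
    against major homozygotes, dropping heterozygotes.  Non-convergence or
    separation is flagged rather than raised.
    """
    import statsmodels.api as sm

    d = np.asarray(dosages, float)
    x = np.asarray(env_values, float)
    if d.size < 10:
        raise ValueError("glm_binomial_gea needs >= 10 individuals")
    if np.std(x) == 0:
        raise ValueError("environmental values are constant")
    if coding == "dosage":
        endog = np.column_stack([d, 2.0 - d])
    elif coding == "homozygote":
        keep = (d == 0) | (d == 2)
        d, x = d[keep], x[keep]
        endog = (d == 2).astype(float)
    else:
        raise ValueError("coding must be 'dosage' or 'homozygote'")
    exog = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-10
            )
        converged = bool(res.converged) and np.all(np.isfinite(res.bse)) and res.bse[1] < 1e3
        beta0, beta1 = float(res.params[0]), float(res.params[1])
        se = float(res.bse[1])
        z = beta1 / se if converged and se > 0 else np.nan
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    except Exception:
        return GlmResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False)
    return GlmResult(
        beta0=beta0,
        beta1=beta1,
        odds_ratio=float(np.exp(beta1)),
        se=se,
        z=z,
        p=p if converged else np.nan,
        converged=converged,
    )


@dataclass
class ConsensusResult:
    pav: list[str]  # three-way intersection
    two_of_three: list[str]  # union of pairwise intersections
    pairwise: dict[str, list[str]]
    venn_counts: dict[str, int]


def consensus_outliers(
    set_fst: set[str] | list[str],
    set_pca: set[str] | list[str],
    set_rda: set[str] | list[str],
) -> ConsensusResult:
    """Three-way consensus of outlier calls (the PAV panel) plus the
    two-of-three relaxation used for sensitivity analysis."""
    s1, s2, s3 = set(set_fst), set(set_pca), set(set_rda)
    pav = s1 & s2 & s3
    pairs = {
        "fst_pca": s1 & s2,
        "fst_rda": s1 & s3,
        "pca_rda": s2 & s3,
    }
    two = pairs["fst_pca"] | pairs["fst_rda"] | pairs["pca_rda"]
    venn = {
        "fst": len(s1),
        "pca": len(s2),
        "rda": len(s3),
        "fst_pca": len(pairs["fst_pca"]),
        "fst_rda": len(pairs["fst_rda"]),
        "pca_rda": len(pairs["pca_rda"]),
        "pav": len(pav),
    }
    return ConsensusResult(
        pav=sorted(pav),
        two_of_three=sorted(two),
        pairwise={k: sorted(v) for k, v in pairs.items()},
        venn_counts=venn,
    )
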