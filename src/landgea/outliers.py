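"""Genomic outlier scans: trimmed chi-square F_ST scan, PC-regression
Mahalanobis scan, and Storey q-values.

The F_ST scan models per-locus differentiation (without sample-size
correction) as a scaled chi-square, F_ST ~ (Fbar/df) * chi2_df, with the
degrees of freedom and mean fitted by truncated maximum likelihood on the
two-sided-trimmed bulk of supposedly neutral loci; right-tail p-values are
taken from the fitted distribution for every locus.  The PC scan regresses
each standardized locus on the leading principal components and measures
the Mahalanobis distance of the resulting z-score vector, rescaled by the
genomic inflation factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genotypes import MISSING, GenotypeMatrix, impute_within_population


# ---------------------------------------------------------------------------
# Storey q-values


def storey_qvalues(p_values: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with the lambda = 0.5 tail estimator of pi0.

    pi0_hat = min(1, mean(p > 0.5)/0.5); q_(i) = min_{j >= i} pi0 * m *
    p_(j) / j on the sorted p-values.  ``pi0`` overrides the estimate.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# trimmed chi-square F_ST scan


@dataclass
class OutflankFit:
    df_hat: float
    fst_bar: float
    trim: tuple[float, float]
    per_locus: pd.DataFrame  # fst, he, p, q, outlier (indexed by locus id)

    @property
    def outliers(self) -> list[str]:
        return list(self.per_locus.index[self.per_locus["outlier"]])


def uncorrected_fst(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus F_ST without finite-sample correction, plus heterozygosity.

    F_ST = s^2 / (pbar (1 - pbar)) with sample allele frequencies treated
    as population frequencies; the finite-sample inflation is common to
    all loci and is absorbed by the fitted chi-square scale.  Returns
    ``(fst, he)`` with he = 2 pbar (1 - pbar).
    """
    pops = np.asarray(G.population_labels)
    labels = G.populations
    m = G.n_loci
    n_mat = np.zeros((len(labels), m))
    p_mat = np.zeros((len(labels), m))
    for k, pop in enumerate(labels):
        vals = G.values[pops == pop]
        miss = vals == MISSING
        n_obs = (~miss).sum(axis=0).astype(float)
        n_mat[k] = n_obs
        with np.errstate(invalid="ignore", divide="ignore"):
            p_mat[k] = np.where(n_obs > 0, np.where(miss, 0, vals).sum(axis=0) / (2 * n_obs), 0.0)
    n_tot = n_mat.sum(axis=0)
    r = (n_mat > 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n_mat * p_mat).sum(axis=0) / n_tot
        nbar = n_tot / r
        s2 = (n_mat * (p_mat - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1) * nbar)
        he = 2 * pbar * (1 - pbar)
        fst = np.where(he > 0, s2 / (pbar * (1 - pbar)), 0.0)
    return np.nan_to_num(fst, nan=0.0), np.nan_to_num(he, nan=0.0)


def fit_trimmed_chisq(
    values: np.ndarray, trim: tuple[float, float] = (0.05, 0.05)
) -> tuple[float, float]:
    """Fit F_ST ~ (Fbar/df) * chi2_df on the two-sided-trimmed bulk.

    Fbar is profiled as the trimmed mean; df maximizes the truncated
    chi-square likelihood on values inside the trim bounds.  Returns
    ``(df_hat, fbar)``.
    """
    x = np.sort(np.asarray(values, float))
    m = x.size
    lo = int(np.floor(m * trim[0]))
    hi = m - int(np.floor(m * trim[1]))
    kept = x[lo:hi]
    kept = kept[kept > 0]
    if kept.size < 50:
        raise ValueError(f"only {kept.size} loci inside the trim; fit unstable")
    a, b = kept.min(), kept.max()
    fbar = float(kept.mean())

    def negloglik(df: float) -> float:
        scale = fbar / df
        ll = stats.chi2.logpdf(kept / scale, df).sum() - kept.size * np.log(scale)
        trunc = stats.chi2.cdf(b / scale, df) - stats.chi2.cdf(a / scale, df)
        if trunc <= 0:
            return np.inf
        return -(ll - kept.size * np.log(trunc))

    res = minimize_scalar(
        negloglik, bounds=(0.5, 1000.0), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), fbar


def outflank_scan(
    G: GenotypeMatrix,
    trim: float | tuple[float, float] = 0.05,
    h_min: float = 0.1,
    q_threshold: float = 0.05,
) -> OutflankFit:
    """Trimmed chi-square F_ST outlier scan with Storey FDR calling.

    Loci with expected heterozygosity below ``h_min`` are excluded both
    from distribution fitting and from outlier calling.
    """
    if len(G.populations) < 2:
        raise ValueError("outflank_scan needs >= 2 populations")
    trim_pair = (trim, trim) if np.isscalar(trim) else tuple(trim)
    fst, he = uncorrected_fst(G)
    eligible = he >= h_min
    df_hat, fbar = fit_trimmed_chisq(fst[eligible], trim=trim_pair)

    p = np.full(G.n_loci, np.nan)
    p[eligible] = stats.chi2.sf(fst[eligible] * df_hat / fbar, df_hat)
    q = np.full(G.n_loci, np.nan)
    q[eligible] = storey_qvalues(p[eligible])
    flag = np.zeros(G.n_loci, dtype=bool)
    flag[eligible] = q[eligible] <= q_threshold
    per_locus = pd.DataFrame(
        {"fst": fst, "he": he, "p": p, "q": q, "outlier": flag}, index=G.locus_ids
    )
    return OutflankFit(df_hat=df_hat, fst_bar=fbar, trim=trim_pair, per_locus=per_locus)


# ---------------------------------------------------------------------------
# PC-regression Mahalanobis scan


@dataclass
class PcadaptResult:
    K: int
    lam: float  # genomic inflation factor
    eigenvalues: np.ndarray
    per_locus: pd.DataFrame  # stat (Mahalanobis D^2), p, q, outlier

    @property
    def outliers(self) -> list[str]:
        return list(self.per_locus.index[self.per_locus["outlier"]])


def choose_k_cattell(eigenvalues: np.ndarray, drop_ratio: float = 0.05) -> int:
    """Automated Cattell elbow: keep axes while the eigenvalue drop between
    consecutive axes stays at or above ``drop_ratio`` of total variance."""
    props = np.asarray(eigenvalues, float)
    props = props / props.sum()
    diffs = props[:-1] - props[1:]
    k = 0
    for d in diffs:
        if d >= drop_ratio:
            k += 1
        else:
            break
    return max(k, 1)


def pcadapt_scan(
    G: GenotypeMatrix | np.ndarray,
    K: int | None = None,
    robust: bool = False,
    q_threshold: float = 0.05,
    locus_ids: list[str] | None = None,
    rng: int | None = 0,
) -> PcadaptResult:
    """PC-regression Mahalanobis outlier scan with genomic-inflation rescaling.

    Dosages are scaled to unit binomial variance, individuals are projected
    onto the leading ``K`` principal components (Cattell's rule when K is
    None), and each locus's K-vector of regression z-scores is measured by
    Mahalanobis distance under the empirical (or minimum-covariance-
    determinant, ``robust=True``) scatter.  p-values come from chi2_K after
    dividing by the inflation factor lambda = median(D^2)/median(chi2_K).
    """
    if isinstance(G, GenotypeMatrix):
        X = impute_within_population(G)
        locus_ids = locus_ids or G.locus_ids
    else:
        X = np.asarray(G, float)
        locus_ids = locus_ids or [f"locus_{j}" for j in range(X.shape[1])]
    n, m = X.shape
    phat = X.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * phat * (1.0 - phat))
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd

    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    eigenvalues = S**2 / (n - 1)
    if K is None:
        K = choose_k_cattell(eigenvalues)
    if not 1 <= K < min(n, m):
        raise ValueError(f"K={K} out of range for {n} individuals x {m} loci")

    Uk = U[:, :K]
    B = Uk.T @ Xs  # K x m regression coefficients (U orthonormal)
    resid = Xs - Uk @ B
    dof = max(n - K - 1, 1)
    sigma = np.sqrt((resid**2).sum(axis=0) / dof)
    sigma[sigma == 0] = 1.0
    Z = (B / sigma[None, :]).T  # loci x K

    if robust:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=rng).fit(Z)
        loc, cov = mcd.location_, mcd.covariance_
    else:
        loc = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False).reshape(K, K)
    diff = Z - loc
    d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
    lam = float(np.median(d2) / stats.chi2.ppf(0.5, K))
    p = stats.chi2.sf(d2 / lam, K)
    q = storey_qvalues(p)
    per_locus = pd.DataFrame(
        {"stat": d2, "p": p, "q": q, "outlier": q <= q_threshold}, index=locus_ids
    )
    return PcadaptResult(K=K, lam=lam, eigenvalues=eigenvalues, per_locus=per_locus)
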