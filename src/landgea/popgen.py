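"""Diversity statistics, Weir-Cockerham F-statistics and Mantel tests.

Expected heterozygosity follows Nei's unbiased within-population gene
diversity (2p(1-p) * 2n/(2n-1)); F_ST uses the Weir & Cockerham (1984)
variance-component estimator with the multilocus value taken as the ratio
of summed components.  Geographic distances are Vincenty geodesics on the
WGS84 ellipsoid; environmental distances are Mahalanobis distances on the
first two principal components of the standardized predictor table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .environment import EnvTable
from .genotypes import MISSING, GenotypeMatrix

# WGS84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)


@dataclass
class DiversityStats:
    per_population: pd.DataFrame  # columns: ho, he, fis, n_individuals
    overall: dict[str, float]  # unweighted means over populations


@dataclass
class FstResult:
    global_fst: float
    pairwise: pd.DataFrame | None
    per_locus_components: pd.DataFrame | None  # columns a, b, c


def _pop_blocks(G: GenotypeMatrix) -> dict[str, np.ndarray]:
    pops = np.asarray(G.population_labels)
    return {p: np.flatnonzero(pops == p) for p in G.populations}


def heterozygosity_stats(G: GenotypeMatrix) -> DiversityStats:
    """Observed/expected heterozygosity and F_IS per population and overall.

    Per-locus H_o is the heterozygote fraction among non-missing calls;
    H_e is Nei's unbiased gene diversity.  Population values average over
    loci with data; overall values are unweighted means over populations.
    Populations of size 1 get H_e (and F_IS) flagged as NaN.
    """
    rows = []
    for pop, idx in _pop_blocks(G).items():
        vals = G.values[idx]
        miss = vals == MISSING
        n_obs = (~miss).sum(axis=0).astype(float)
        het = ((vals == 1) & ~miss).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho_locus = np.where(n_obs > 0, het / n_obs, np.nan)
            p = np.where(n_obs > 0, np.where(miss, 0, vals).sum(axis=0) / (2 * n_obs), np.nan)
            he_locus = np.where(
                n_obs > 1, 2 * p * (1 - p) * (2 * n_obs) / (2 * n_obs - 1), np.nan
            )
        ho = float(np.nanmean(ho_locus))
        he = float(np.nanmean(he_locus)) if not np.isnan(he_locus).all() else np.nan
        fis = 1.0 - ho / he if he and he > 0 else np.nan
        rows.append({"population": pop, "ho": ho, "he": he, "fis": fis, "n_individuals": len(idx)})
    per_pop = pd.DataFrame(rows).set_index("population")
    overall = {
        "ho": float(per_pop["ho"].mean()),
        "he": float(per_pop["he"].mean()),
    }
    overall["fis"] = 1.0 - overall["ho"] / overall["he"] if overall["he"] > 0 else np.nan
    return DiversityStats(per_population=per_pop, overall=overall)


def _wc_components(G: GenotypeMatrix, pop_indices: list[np.ndarray]) -> pd.DataFrame:
    """Weir-Cockerham (1984) per-locus variance components a, b, c.

    Loci are evaluated over the populations with at least one call; loci
    with fewer than two such populations get zero components (they carry
    no among-population information).
    """
    m = G.n_loci
    r_max = len(pop_indices)
    n_mat = np.zeros((r_max, m))
    p_mat = np.zeros((r_max, m))
    h_mat = np.zeros((r_max, m))
    for k, idx in enumerate(pop_indices):
        vals = G.values[idx]
        miss = vals == MISSING
        n_obs = (~miss).sum(axis=0).astype(float)
        n_mat[k] = n_obs
        with np.errstate(invalid="ignore", divide="ignore"):
            p_mat[k] = np.where(n_obs > 0, np.where(miss, 0, vals).sum(axis=0) / (2 * n_obs), 0.0)
            h_mat[k] = np.where(n_obs > 0, ((vals == 1) & ~miss).sum(axis=0) / n_obs, 0.0)

    present = n_mat > 0
    r = present.sum(axis=0).astype(float)  # populations with data per locus
    n_tot = n_mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_tot / r
        nc = (n_tot - (n_mat**2).sum(axis=0) / n_tot) / (r - 1)
        pbar = (n_mat * p_mat).sum(axis=0) / n_tot
        s2 = (n_mat * (p_mat - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_mat * h_mat).sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    bad = (r < 2) | ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    a = np.where(bad, 0.0, a)
    b = np.where(bad, 0.0, b)
    c = np.where(bad, 0.0, c)
    return pd.DataFrame({"a": a, "b": b, "c": c}, index=G.locus_ids)


def wc_fst(G: GenotypeMatrix, mode: str = "global") -> FstResult:
    """Weir-Cockerham F_ST, globally and/or pairwise between populations.

    The multilocus estimate is the ratio of summed variance components
    sum(a) / sum(a+b+c), not a mean of per-locus ratios.  Negative pairwise
    estimates are reported as-is.
    """
    blocks = _pop_blocks(G)
    if len(blocks) < 2:
        raise ValueError("wc_fst needs >= 2 populations")
    comp = _wc_components(G, list(blocks.values()))
    denom = float((comp["a"] + comp["b"] + comp["c"]).sum())
    if denom == 0.0:
        raise ValueError("F_ST undefined: all loci monomorphic")
    global_fst = float(comp["a"].sum()) / denom

    pairwise = None
    if mode == "pairwise":
        pops = list(blocks)
        mat = pd.DataFrame(0.0, index=pops, columns=pops)
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                sub = _wc_components(G, [blocks[pops[i]], blocks[pops[j]]])
                d = float((sub["a"] + sub["b"] + sub["c"]).sum())
                val = float(sub["a"].sum()) / d if d != 0 else np.nan
                mat.iloc[i, j] = mat.iloc[j, i] = val
        pairwise = mat
    elif mode != "global":
        raise ValueError("mode must be 'global' or 'pairwise'")
    return FstResult(global_fst=global_fst, pairwise=pairwise, per_locus_components=comp)


def fst_linearize(fst: pd.DataFrame | np.ndarray | float):
    """Rousset linearization F_ST / (1 - F_ST) for distance-based tests."""
    return fst / (1.0 - fst)


# ---------------------------------------------------------------------------
# distances


def _vincenty_inverse(lat1: float, lon1: float, lat2: float, lon2: float,
                      max_iter: int = 1000, tol: float = 1e-12) -> float:
    """Vincenty inverse geodesic distance (meters) on the WGS84 ellipsoid."""
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1 - _WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1 - _WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.hypot(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sigma_m = cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha if cos2_alpha != 0 else 0.0
        C = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise ValueError(
            f"Vincenty iteration failed to converge for ({lat1},{lon1})-({lat2},{lon2}) "
            "(near-antipodal pair)"
        )
    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m
        + B / 4 * (
            cos_sigma * (-1 + 2 * cos_2sigma_m**2)
            - B / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sigma_m**2)
        )
    )
    return float(_WGS84_B * A * (sigma - delta_sigma))


def geodesic_distances(coords: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Vincenty geodesic distances (meters) between populations.

    ``coords`` needs columns ``population``, ``lat``, ``lon`` in WGS84
    decimal degrees.
    """
    pops = list(coords["population"])
    lat = coords["lat"].to_numpy(float)
    lon = coords["lon"].to_numpy(float)
    n = len(pops)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _vincenty_inverse(lat[i], lon[i], lat[j], lon[j])
    return pd.DataFrame(D, index=pops, columns=pops)


def env_distances(env: EnvTable, n_components: int = 2) -> pd.DataFrame:
    """Mahalanobis distances between populations on leading environment PCs.

    Variables are standardized, projected onto the first ``n_components``
    principal components, and pairwise Mahalanobis distances are taken
    under the empirical covariance of those scores.  Invariant to affine
    rescaling of any input variable.
    """
    X = env.data.to_numpy(float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("env_distances needs >= 3 populations and >= 2 variables")
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    if (S > 1e-10).sum() < n_components:
        raise ValueError("environment table has rank < requested components")
    scores = U[:, :n_components] * S[:n_components]
    VI = np.linalg.inv(np.cov(scores, rowvar=False))
    diff = scores[:, None, :] - scores[None, :, :]
    D = np.sqrt(np.einsum("ijk,kl,ijl->ij", diff, VI, diff))
    return pd.DataFrame(D, index=env.populations, columns=env.populations)


def mantel_test(
    D1: pd.DataFrame | np.ndarray,
    D2: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with a one-sided
    permutation p-value (add-one convention, rows/columns of D2 permuted
    jointly)."""
    A = np.asarray(D1, float)
    B = np.asarray(D2, float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrices must be square and same shape")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    va = squareform(A, checks=False)
    vb = squareform(B, checks=False)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("Mantel r undefined for a constant distance matrix")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    n = A.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = squareform(B[np.ix_(perm, perm)], checks=False)
        if np.corrcoef(va, vp)[0, 1] >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p
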