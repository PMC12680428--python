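"""Genomic-offset estimation under future climates.

Two complementary offsets are computed from a calibrated allele-frequency
vs environment ordination:

* RONA-RDA — a two-stage predictor (constrained ordination, then a
  per-locus binomial logit calibration that keeps predictions inside
  (0, 1)) yields future allele frequencies; the offset is the
  per-population mean absolute difference 1/n * sum |p_i - p_i*| between
  current and predicted frequencies over the adaptive loci.
* RDA adaptive-index offset — per-population Euclidean distance between
  adaptive indices (standardized environment projected through predictor
  biplot scores) under current and future climates.

An inverse-distance-weighting helper projects per-population scores onto
a regular grid for mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .environment import EnvTable
from .genotypes import PopAlleleFreq
from .rda import RdaModel, rda_fit


@dataclass
class AlleleEnvModel:
    """Two-stage allele-frequency vs environment calibration."""

    rda: RdaModel
    stage2: pd.DataFrame  # per locus: b0, b1, fixed flag
    variables: list[str]
    loci: list[str]


def _standardized_env(model: AlleleEnvModel | RdaModel, env: EnvTable) -> np.ndarray:
    rda = model.rda if isinstance(model, AlleleEnvModel) else model
    missing = [v for v in rda.predictor_names if v not in env.data.columns]
    if missing:
        raise ValueError(f"environment table missing calibration variables: {missing}")
    X = env.data[rda.predictor_names].to_numpy(float)
    return (X - rda.x_mean) / rda.x_sd  # current-climate constants, by design


def fit_allele_env_model(freqs: PopAlleleFreq, env: EnvTable, loci: list[str] | None = None) -> AlleleEnvModel:
    """Calibrate the two-stage bounded allele-frequency predictor.

    Stage 1 fits an RDA of population frequencies (restricted to ``loci``,
    typically the PAV panel) on the environment table; stage 2 fits, per
    locus, a binomial logistic regression of the observed allele counts on
    the stage-1 linear prediction, which maps any future linear prediction
    back into (0, 1).  Loci fixed across all populations are flagged and
    predicted at their current frequency.
    """
    import statsmodels.api as sm

    loci = loci or list(freqs.freq.columns)
    Y = freqs.freq[loci]
    if Y.isna().any().any():
        raise ValueError("frequency table has unavailable cells; drop or refill first")
    if Y.shape[0] < 3:
        raise ValueError("need >= 3 populations to calibrate")
    counts = freqs.n_alleles[loci]
    rda = rda_fit(Y, env.data)

    Xs = _standardized_env_raw(env, rda)
    linpred = rda.linear_predictions(Xs)  # pops x loci fitted frequencies
    rows = []
    for j, locus in enumerate(loci):
        p_obs = Y[locus].to_numpy(float)
        n_al = counts[locus].to_numpy(float)
        if np.allclose(p_obs, p_obs[0]):
            # no gradient to calibrate; predict the constant frequency
            const = float(np.clip(p_obs[0], 1e-6, 1 - 1e-6))
            rows.append({"locus": locus, "b0": logit(const), "b1": 0.0, "fixed": True})
            continue
        endog = np.column_stack([p_obs * n_al, (1 - p_obs) * n_al])
        exog = sm.add_constant(linpred[:, j])
        with np.errstate(all="ignore"):
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=100)
        rows.append(
            {"locus": locus, "b0": float(res.params[0]), "b1": float(res.params[1]), "fixed": False}
        )
    stage2 = pd.DataFrame(rows).set_index("locus")
    return AlleleEnvModel(rda=rda, stage2=stage2, variables=list(env.data.columns), loci=loci)


def _standardized_env_raw(env: EnvTable, rda: RdaModel) -> np.ndarray:
    X = env.data[rda.predictor_names].to_numpy(float)
    return (X - rda.x_mean) / rda.x_sd


def predict_future_frequencies(model: AlleleEnvModel, future_env: EnvTable) -> PopAlleleFreq:
    """Predict per-population allele frequencies under a future climate.

    The future environment is standardized with the CURRENT calibration
    constants, pushed through the stage-1 ordination, and mapped through
    the per-locus stage-2 inverse-logit; outputs are strictly inside (0, 1).
    """
    Xs = _standardized_env(model, future_env)
    linpred = model.rda.linear_predictions(Xs)
    b0 = model.stage2["b0"].to_numpy()
    b1 = model.stage2["b1"].to_numpy()
    pred = expit(b0[None, :] + b1[None, :] * linpred)
    freq = pd.DataFrame(pred, index=future_env.populations, columns=model.loci)
    n_alleles = pd.DataFrame(
        np.zeros_like(pred), index=future_env.populations, columns=model.loci
    )
    return PopAlleleFreq(freq=freq, n_alleles=n_alleles)


def rona_offset(current: PopAlleleFreq | pd.DataFrame, predicted: PopAlleleFreq | pd.DataFrame) -> pd.Series:
    """Risk of nonadaptedness: per-population mean |p_i - p_i*| over loci."""
    cur = current.freq if isinstance(current, PopAlleleFreq) else current
    pre = predicted.freq if isinstance(predicted, PopAlleleFreq) else predicted
    if cur.shape != pre.shape:
        raise ValueError("current and predicted frequency tables differ in shape")
    pre = pre.reindex(index=cur.index, columns=cur.columns)
    return (cur - pre).abs().mean(axis=1)


def adaptive_index_offset(
    model: RdaModel | AlleleEnvModel,
    env_now: EnvTable,
    env_future: EnvTable,
    axes: list[int] | None = None,
) -> pd.Series:
    """Euclidean distance between current and future adaptive indices.

    The adaptive index on axis k is the standardized environment projected
    through the predictor biplot scores; both climates are standardized
    with current constants, so the offset is zero when they coincide and
    invariant to axis sign flips.
    """
    rda = model.rda if isinstance(model, AlleleEnvModel) else model
    if axes is None:
        axes = list(range(1, rda.n_axes + 1))
    axes = [a for a in axes if 1 <= a <= rda.n_axes]
    if not axes:
        raise ValueError("no retained axes for the adaptive index")
    W = rda.biplot_scores.to_numpy()[:, [a - 1 for a in axes]]
    idx_now = _standardized_env(model, env_now) @ W
    idx_fut = _standardized_env(model, env_future) @ W
    d = np.sqrt(((idx_now - idx_fut) ** 2).sum(axis=1))
    return pd.Series(d, index=env_now.populations, name="rda_offset")


def offset_table(
    offsets: dict[tuple[str, str], pd.Series]
) -> pd.DataFrame:
    """Tidy table from {(method, scenario): per-population offsets}."""
    rows = []
    for (method, scenario), series in offsets.items():
        for pop, val in series.items():
            rows.append(
                {"population": pop, "scenario": scenario, "method": method, "offset": float(val)}
            )
    return pd.DataFrame(rows)


def decile_bins(values: pd.Series, n_classes: int = 10) -> pd.Series:
    """Quantile-binned index classes (1..n) for map visualisation."""
    return pd.Series(
        pd.qcut(values, q=n_classes, labels=False, duplicates="drop") + 1,
        index=values.index,
        name="class",
    )


def idw_surface(
    points: np.ndarray,
    values: np.ndarray,
    grid: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation of point values onto a grid.

    ``points`` is (k, 2) and ``grid`` (g, 2) in a shared planar coordinate
    system; a grid node coincident with a data point returns that point's
    value exactly.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    vals = np.asarray(values, float)
    gr = np.atleast_2d(np.asarray(grid, float))
    if pts.shape[0] == 0:
        raise ValueError("idw_surface needs >= 1 data point")
    d = np.sqrt(((gr[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(gr.shape[0])
    exact = d == 0
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    for i in range(gr.shape[0]):
        hit = np.flatnonzero(exact[i])
        if hit.size:
            out[i] = vals[hit[0]]
        else:
            out[i] = (w[i] * vals).sum() / w[i].sum()
    return out


def equirectangular_projection(coords: pd.DataFrame) -> np.ndarray:
    """Project lat/lon to planar meters (equirectangular at mean latitude)."""
    R = 6371000.0
    lat = np.radians(coords["lat"].to_numpy(float))
    lon = np.radians(coords["lon"].to_numpy(float))
    lat0 = lat.mean()
    return np.column_stack([R * lon * np.cos(lat0), R * lat])
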