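"""Genomic-offset estimation: bounded future frequencies, RONA, the
RDA adaptive-index offset and IDW projection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from landgea.environment import EnvTable
from landgea.genotypes import PopAlleleFreq
from landgea.offset import (
    adaptive_index_offset,
    decile_bins,
    equirectangular_projection,
    fit_allele_env_model,
    idw_surface,
    predict_future_frequencies,
    rona_offset,
)
from landgea.outliers import outflank_scan, pcadapt_scan
from landgea.rda import consensus_outliers, rda_fit, rda_outliers
from landgea.simulate import future_env_tables


@pytest.fixture(scope="module")
def calibrated(default_panel, qc_default):
    """Allele-environment model calibrated on the planted adaptive loci."""
    G, X, freq = qc_default
    pops = np.asarray(G.population_labels)
    counts = pd.DataFrame(
        [np.full(G.n_loci, 2 * (pops == p).sum()) for p in G.populations],
        index=G.populations, columns=G.locus_ids,
    )
    paf = PopAlleleFreq(freq=freq, n_alleles=counts)
    env = default_panel.env
    loci = [l for l in default_panel.adaptive_loci if l in G.locus_ids]
    model = fit_allele_env_model(paf, env, loci=loci)
    return model, paf, env, loci


def test_stage2_slopes_follow_cline_direction(calibrated, default_panel):
    model, paf, env, loci = calibrated
    temps = env.data["mean_temp"]
    agree = 0
    for locus in loci:
        dir_cline = np.sign(paf.freq[locus].corr(temps))
        # stage-1 linear prediction increases with the fitted gradient, so a
        # positive stage-2 slope means the locus tracks its own cline
        if model.stage2.loc[locus, "b1"] > 0:
            agree += 1
    assert agree >= 0.9 * len(loci)


def test_predictions_exact_in_sample_and_bounded(calibrated):
    model, paf, env, loci = calibrated
    same = predict_future_frequencies(model, env)
    again = predict_future_frequencies(model, env)
    assert np.allclose(same.freq.to_numpy(), again.freq.to_numpy(), atol=1e-12)
    # +/- 50 degC stress input stays strictly inside (0, 1)
    stress = env.data.copy()
    stress["mean_temp"] = stress["mean_temp"] + 50.0
    pred = predict_future_frequencies(model, EnvTable(stress))
    assert (pred.freq.to_numpy() > 0).all() and (pred.freq.to_numpy() < 1).all()
    stress["mean_temp"] = stress["mean_temp"] - 100.0
    pred = predict_future_frequencies(model, EnvTable(stress))
    assert (pred.freq.to_numpy() > 0).all() and (pred.freq.to_numpy() < 1).all()


def test_refit_on_fitted_values_is_self_consistent(calibrated):
    """Recalibrating on the model's own in-sample predictions reproduces
    them closely (the two-stage construction is near-idempotent)."""
    model, paf, env, loci = calibrated
    pred = predict_future_frequencies(model, env)
    paf2 = PopAlleleFreq(freq=pred.freq, n_alleles=paf.n_alleles[loci])
    model2 = fit_allele_env_model(paf2, env, loci=loci)
    pred2 = predict_future_frequencies(model2, env)
    diff = np.abs(pred2.freq.to_numpy() - pred.freq.to_numpy())
    assert diff.max() < 0.05 and diff.mean() < 0.01


def test_missing_variable_named(calibrated):
    model, _, env, _ = calibrated
    broken = EnvTable(env.data.drop(columns=["mean_temp"]))
    with pytest.raises(ValueError, match="mean_temp"):
        predict_future_frequencies(model, broken)


def test_constant_locus_flagged_and_predicted_flat(calibrated, default_panel):
    _, paf, env, loci = calibrated
    freq = paf.freq[loci].copy()
    freq[loci[0]] = 0.5
    paf2 = PopAlleleFreq(freq=freq, n_alleles=paf.n_alleles[loci])
    m = fit_allele_env_model(paf2, env, loci=loci)
    assert bool(m.stage2.loc[loci[0], "fixed"])
    pred = predict_future_frequencies(m, env)
    assert np.allclose(pred.freq[loci[0]], 0.5, atol=1e-9)


def test_rona_hand_arithmetic_and_zero():
    cur = pd.DataFrame([[0.2, 0.4]], index=["p1"], columns=["a", "b"])
    pre = pd.DataFrame([[0.3, 0.1]], index=["p1"], columns=["a", "b"])
    assert rona_offset(cur, pre)["p1"] == pytest.approx(0.2)
    assert rona_offset(cur, cur)["p1"] == 0.0
    with pytest.raises(ValueError, match="shape"):
        rona_offset(cur, pre.iloc[:, :1])


def test_rona_monotone_in_scenario_severity(calibrated, default_panel):
    model, paf, env, loci = calibrated
    futures = future_env_tables(env, default_panel.coords)
    cur = paf.freq[loci]
    offs = {
        name: rona_offset(cur, predict_future_frequencies(model, fut).freq)
        for name, fut in futures.items()
    }
    assert (offs["ssp126"] <= offs["ssp245"] + 1e-12).all()
    assert (offs["ssp245"] <= offs["ssp585"] + 1e-12).all()
    assert (offs["ssp585"] >= 0).all() and (offs["ssp585"] <= 1).all()


def test_adaptive_index_offset_properties(calibrated, default_panel):
    model, paf, env, loci = calibrated
    zero = adaptive_index_offset(model, env, env)
    assert np.allclose(zero.to_numpy(), 0.0)
    fut = future_env_tables(env, default_panel.coords)["ssp585"]
    one_axis = adaptive_index_offset(model, env, fut, axes=[1])
    # single axis: offset equals |delta index|
    W = model.rda.biplot_scores.to_numpy()[:, :1]
    Xn = (env.data[model.rda.predictor_names].to_numpy() - model.rda.x_mean) / model.rda.x_sd
    Xf = (fut.data[model.rda.predictor_names].to_numpy() - model.rda.x_mean) / model.rda.x_sd
    assert np.allclose(one_axis.to_numpy(), np.abs((Xn - Xf) @ W).ravel())
    # sign flip of the axis leaves the offset unchanged
    model.rda.biplot_scores.iloc[:, 0] *= -1
    flipped = adaptive_index_offset(model, env, fut, axes=[1])
    model.rda.biplot_scores.iloc[:, 0] *= -1
    assert np.allclose(one_axis.to_numpy(), flipped.to_numpy())


def test_rona_and_adaptive_index_rank_agree(calibrated, default_panel):
    """The two offsets are different statistics of the same calibration and
    should rank populations similarly (Spearman > 0.7)."""
    model, paf, env, loci = calibrated
    fut = future_env_tables(env, default_panel.coords)["ssp585"]
    rona = rona_offset(paf.freq[loci], predict_future_frequencies(model, fut).freq)
    rda_off = adaptive_index_offset(model, env, fut)
    rho = spearmanr(rona.to_numpy(), rda_off.to_numpy()).statistic
    assert rho > 0.7


def test_two_of_three_panel_preserves_offset_ranks(default_panel, qc_default):
    """Swapping the strict consensus panel for the two-of-three panel leaves
    the population ranking of adaptive-index offsets essentially unchanged."""
    G, X, freq = qc_default
    pops = np.asarray(G.population_labels)
    counts = pd.DataFrame(
        [np.full(G.n_loci, 2 * (pops == p).sum()) for p in G.populations],
        index=G.populations, columns=G.locus_ids,
    )
    paf = PopAlleleFreq(freq=freq, n_alleles=counts)
    env = default_panel.env
    of = outflank_scan(G)
    pc = pcadapt_scan(G)
    model_all = rda_fit(freq, env.data)
    ro = rda_outliers(model_all, axes=[1])
    cons = consensus_outliers(of.outliers, pc.outliers, list(ro.index))
    assert len(cons.pav) >= 2 and len(cons.two_of_three) >= len(cons.pav)
    fut = future_env_tables(env, default_panel.coords)["ssp585"]
    off_pav = adaptive_index_offset(
        fit_allele_env_model(paf, env, loci=cons.pav), env, fut
    )
    off_two = adaptive_index_offset(
        fit_allele_env_model(paf, env, loci=cons.two_of_three), env, fut
    )
    rho = spearmanr(off_pav.to_numpy(), off_two.to_numpy()).statistic
    assert rho > 0.9


def test_idw_exact_hit_midpoint_and_constant():
    pts = np.array([[0.0, 0.0], [2.0, 0.0]])
    vals = np.array([0.0, 1.0])
    grid = np.array([[0.0, 0.0], [1.0, 0.0]])
    out = idw_surface(pts, vals, grid)
    assert out[0] == 0.0  # coincident node returns the data value
    assert out[1] == pytest.approx(0.5)  # equidistant between 0 and 1
    const = idw_surface(pts, np.array([3.0, 3.0]), grid)
    assert np.allclose(const, 3.0)
    with pytest.raises(ValueError):
        idw_surface(np.empty((0, 2)), np.array([]), grid)


def test_idw_on_projected_transect(default_panel):
    xy = equirectangular_projection(default_panel.coords)
    vals = np.linspace(0, 1, len(xy))
    grid = xy[:5] + 1000.0
    out = idw_surface(xy, vals, grid)
    assert np.all((out >= 0) & (out <= 1))


def test_decile_bins_cover_range():
    s = pd.Series(np.linspace(0, 1, 40), index=[f"p{i}" for i in range(40)])
    b = decile_bins(s)
    assert b.min() == 1 and b.max() == 10
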