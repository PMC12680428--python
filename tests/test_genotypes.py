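"""Genotype loading, QC chain, LD pruning, imputation and frequencies."""

import numpy as np
import pandas as pd
import pytest

from landgea.genotypes import (
    MISSING,
    GenotypeIOError,
    GenotypeMatrix,
    QcConfig,
    apply_qc_filters,
    impute_within_population,
    ld_prune,
    load_genotypes,
    population_allele_frequencies,
)
from landgea.simulate import LandscapePanelSpec, simulate_landscape_panel, write_fixture


def _write_ped(tmp_path, ped_rows, locus_ids):
    ped = tmp_path / "toy.ped"
    ped.write_text("\n".join(" ".join(r) for r in ped_rows) + "\n")
    (tmp_path / "toy.map").write_text(
        "\n".join(f"0\t{lid}\t0\t{i + 1}" for i, lid in enumerate(locus_ids)) + "\n"
    )
    return ped


def test_ped_minor_allele_dosages(tmp_path):
    """'A A' / 'A G' gives dosages (0, 1) counting the rarer allele G."""
    ped = _write_ped(
        tmp_path,
        [["f", "i1", "0", "0", "0", "-9", "A", "A"], ["f", "i2", "0", "0", "0", "-9", "A", "G"]],
        ["L1"],
    )
    G = load_genotypes(ped, "ped", {"i1": "p1", "i2": "p1"})
    assert list(G.values[:, 0]) == [0, 1]
    assert G.alleles[0] == ("G", "A")


def test_ped_missing_sentinel_and_pop_map_errors(tmp_path):
    ped = _write_ped(
        tmp_path,
        [["f", "i1", "0", "0", "0", "-9", "0", "0"], ["f", "i2", "0", "0", "0", "-9", "A", "G"]],
        ["L1"],
    )
    G = load_genotypes(ped, "ped", {"i1": "p1", "i2": "p1"})
    assert G.values[0, 0] == MISSING
    with pytest.raises(GenotypeIOError, match="missing from population map"):
        load_genotypes(ped, "ped", {"i1": "p1"})


def test_ped_malformed_line_reports_number(tmp_path):
    ped = _write_ped(
        tmp_path,
        [["f", "i1", "0", "0", "0", "-9", "A", "A"], ["f", "i2", "0", "0", "0", "-9", "A"]],
        ["L1"],
    )
    with pytest.raises(GenotypeIOError, match="line 2"):
        load_genotypes(ped, "ped", {"i1": "p1", "i2": "p1"})


def test_vcf_multiallelic_skipped(tmp_path, caplog):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ti1\ti2\n"
        "1\t100\tL1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n"
        "1\t200\tL2\tA\tG,T\t.\t.\t.\tGT\t0/0\t1/2\n"
        "1\t300\tL3\tC\tT\t.\t.\t.\tGT\t./.\t1/1\n"
    )
    import logging

    with caplog.at_level(logging.WARNING):
        G = load_genotypes(vcf, "vcf", {"i1": "p1", "i2": "p1"})
    assert G.locus_ids == ["L1", "L3"]
    assert "multiallelic" in caplog.text
    assert G.values[0, 1] == MISSING


def _matrix(values, pops=None, n_pops=1):
    values = np.asarray(values)
    n, m = values.shape
    pops = pops or [f"p{(i * n_pops) // n}" for i in range(n)]
    return GenotypeMatrix(
        values=values,
        individual_ids=[f"i{i}" for i in range(n)],
        population_labels=pops,
        locus_ids=[f"L{j}" for j in range(m)],
        alleles=[("A", "G")] * m,
    )


def test_qc_maf_and_missingness_rules():
    """MAF 1/8 is retained at the 0.05 threshold; monomorphic and
    high-missingness loci are removed."""
    keep_col = [0, 0, 0, 1]  # MAF 0.125
    mono_col = [0, 0, 0, 0]
    vals = np.column_stack([keep_col, mono_col, keep_col])
    G = _matrix(vals)
    out, report = apply_qc_filters(G)
    assert out.locus_ids == ["L0", "L2"]
    assert report.loci_removed_maf == 1

    vals = np.tile([0, 1], (10, 1)).astype(np.int16)
    vals[:2, 0] = MISSING  # 20% missing > 10%
    G = _matrix(vals)
    out, report = apply_qc_filters(G)
    assert report.loci_removed_missing == 1 and "L0" in report.removed_locus_ids["missingness"]


def test_qc_idempotent_and_counts_consistent(default_panel):
    G1, r1 = apply_qc_filters(default_panel.genotypes)
    G2, r2 = apply_qc_filters(G1)
    assert G2.locus_ids == G1.locus_ids
    assert G2.individual_ids == G1.individual_ids
    r1.validate()
    assert r2.n_loci_in == r2.n_loci_out


def test_qc_all_removed_names_filter():
    G = _matrix(np.zeros((4, 2), dtype=int))
    with pytest.raises(ValueError, match="maf"):
        apply_qc_filters(G)


def test_ld_prune_drops_later_locus_of_correlated_pair():
    a = [0, 1, 2, 0, 1]
    b = [2, 1, 0, 2, 1]  # r^2 = 1 with a
    c = [0, 2, 0, 2, 2]
    G = _matrix(np.column_stack([a, b, c]))
    kept = ld_prune(G, r2_max=0.7, window_loci=10, step_loci=5)
    assert list(kept) == [0, 2]
    with pytest.raises(ValueError):
        ld_prune(G, window_loci=1)


def test_ld_prune_retains_independent_columns():
    rng = np.random.default_rng(3)
    G = _matrix(rng.integers(0, 3, size=(200, 2)))
    kept = ld_prune(G, r2_max=0.7, window_loci=10, step_loci=5)
    assert list(kept) == [0, 1]


def test_impute_within_population_mean_and_fallback():
    vals = np.array(
        [[0, MISSING], [2, MISSING], [MISSING, MISSING], [1, 1], [1, 0]], dtype=np.int16
    )
    G = _matrix(vals, pops=["a", "a", "a", "b", "b"])
    X = impute_within_population(G)
    assert X[2, 0] == pytest.approx(1.0)  # pop-a mean of (0, 2)
    assert X[0, 1] == pytest.approx(0.5)  # locus all-missing in pop a -> global mean
    assert not np.isnan(X).any()
    # no-missing matrix returned unchanged
    G2 = _matrix(np.array([[0, 1], [2, 1]]))
    assert np.array_equal(impute_within_population(G2), G2.values.astype(float))


def test_impute_all_missing_locus_errors():
    G = _matrix(np.full((3, 1), MISSING, dtype=np.int16))
    with pytest.raises(ValueError, match="no calls"):
        impute_within_population(G)


def test_population_allele_frequencies_counts():
    vals = np.array([[0], [1], [2], [1], [MISSING]], dtype=np.int16)
    G = _matrix(vals, pops=["a", "a", "a", "b", "b"])
    paf = population_allele_frequencies(G)
    assert paf.freq.loc["a", "L0"] == pytest.approx(0.5)
    assert paf.freq.loc["b", "L0"] == pytest.approx(0.5)
    assert paf.n_alleles.loc["b", "L0"] == 2  # missing excluded
    # frequencies in [0,1] and 2N * p recovers integer allele counts
    counts = paf.freq * paf.n_alleles
    assert np.allclose(counts, np.round(counts))


def test_fixture_round_trip(tmp_path):
    """write_fixture -> load_genotypes reproduces the dosage matrix exactly."""
    panel = simulate_landscape_panel(
        LandscapePanelSpec(n_pops=6, n_neutral=40, n_adaptive=4, seed=5)
    )
    paths = write_fixture(panel, tmp_path)
    G = load_genotypes(paths["ped"], "ped", paths["pop_map"])
    assert np.array_equal(G.values, panel.genotypes.values)
    assert G.locus_ids == panel.genotypes.locus_ids
    assert G.alleles == panel.genotypes.alleles
    coords = pd.read_csv(paths["coords"])
    assert len(coords) == 6
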