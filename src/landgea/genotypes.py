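"""Genotype containers, file readers and the SNP quality-control chain.

Genotypes are held as an individuals x loci integer dosage matrix counting
copies of the panel-wide minor allele (0, 1, 2), with ``MISSING`` (-9) as
the sentinel for no-calls.  Input dialects are whitespace-delimited PLINK
PED/MAP and biallelic VCF; individuals are assigned to populations through
a two-column TSV map.

The QC chain mirrors standard array workflows: locus filters (missingness,
minor-allele frequency) first, then individual missingness, then one MAF
re-pass, followed optionally by windowed LD pruning and within-population
mean imputation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for missing genotype calls in the integer dosage matrix.
MISSING: int = -9


class GenotypeIOError(ValueError):
    """Raised for malformed genotype input files."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic dosage matrix with population labels.

    Attributes
    ----------
    values
        ``(n_individuals, n_loci)`` int16 array; entries in {0, 1, 2} count
        the panel-wide minor allele, ``MISSING`` marks no-calls.
    individual_ids, population_labels, locus_ids
        Row and column annotations; ``population_labels`` has one entry per
        individual.
    alleles
        Per-locus ``(minor, major)`` character pair.  The minor allele is
        the panel-wide rarer allele; an exact 50/50 tie is broken toward
        the lexicographically smaller character so dosage signs are stable.
    """

    values: np.ndarray
    individual_ids: list[str]
    population_labels: list[str]
    locus_ids: list[str]
    alleles: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (individuals x loci)")
        n, m = self.values.shape
        if len(self.individual_ids) != n or len(self.population_labels) != n:
            raise ValueError("individual annotation length mismatch")
        if len(self.locus_ids) != m or len(self.alleles) != m:
            raise ValueError("locus annotation length mismatch")
        if len(set(self.locus_ids)) != m:
            raise ValueError("locus_ids must be unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        obs = self.values[self.values != MISSING]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("non-missing dosages must lie in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def populations(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        return list(dict.fromkeys(self.population_labels))

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "GenotypeMatrix":
        """Return a copy restricted to the given row/column index arrays."""
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_loci) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            values=self.values[np.ix_(rows, cols)].copy(),
            individual_ids=[self.individual_ids[i] for i in rows],
            population_labels=[self.population_labels[i] for i in rows],
            locus_ids=[self.locus_ids[j] for j in cols],
            alleles=[self.alleles[j] for j in cols],
        )


@dataclass
class QcConfig:
    """Thresholds for the SNP/individual quality-control chain."""

    maf_min: float = 0.05
    locus_missing_max: float = 0.10
    indiv_missing_max: float = 0.10
    ld_r2_max: float = 0.7

    def __post_init__(self) -> None:
        for name in ("maf_min", "locus_missing_max", "indiv_missing_max", "ld_r2_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QcReport:
    """Per-stage removal counts for a QC run; serializable to JSON."""

    n_individuals_in: int = 0
    n_loci_in: int = 0
    loci_removed_missing: int = 0
    loci_removed_maf: int = 0
    individuals_removed_missing: int = 0
    loci_removed_maf_repass: int = 0
    n_individuals_out: int = 0
    n_loci_out: int = 0
    removed_locus_ids: dict[str, list[str]] = field(default_factory=dict)
    removed_individual_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        loci_gone = self.loci_removed_missing + self.loci_removed_maf + self.loci_removed_maf_repass
        if loci_gone != self.n_loci_in - self.n_loci_out:
            raise AssertionError("locus stage counts do not sum to input - output")
        if self.individuals_removed_missing != self.n_individuals_in - self.n_individuals_out:
            raise AssertionError("individual stage counts do not sum to input - output")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, default=list)
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ---------------------------------------------------------------------------
# loading


def _read_pop_map(pop_map: str | Path | dict[str, str]) -> dict[str, str]:
    if isinstance(pop_map, dict):
        return dict(pop_map)
    df = pd.read_csv(pop_map, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "individual" not in cols or "population" not in cols:
        raise GenotypeIOError("population map must have columns 'individual' and 'population'")
    df.columns = cols
    return dict(zip(df["individual"], df["population"]))


def _orient_minor(raw: np.ndarray, allele_pairs: list[tuple[str, str]]) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Flip dosages so they count the panel-wide minor allele.

    ``raw`` counts ``allele_pairs[j][0]``; ties at frequency exactly 0.5 keep
    the lexicographically smaller character as minor.
    """
    values = raw.copy()
    out_alleles: list[tuple[str, str]] = []
    for j, (a1, a2) in enumerate(allele_pairs):
        col = values[:, j]
        obs = col[col != MISSING]
        freq = obs.sum() / (2 * obs.size) if obs.size else 0.0
        flip = freq > 0.5 or (freq == 0.5 and a2 < a1)
        if flip:
            col[col != MISSING] = 2 - col[col != MISSING]
            out_alleles.append((a2, a1))
        else:
            out_alleles.append((a1, a2))
    return values, out_alleles


def _load_ped(ped_path: Path, pop_lookup: dict[str, str]) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise GenotypeIOError(f"MAP file not found next to PED: {map_path}")
    locus_ids: list[str] = []
    for k, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise GenotypeIOError(f"{map_path}: malformed line {k}")
        locus_ids.append(parts[1])

    individual_ids: list[str] = []
    population_labels: list[str] = []
    allele_rows: list[list[str]] = []
    m = len(locus_ids)
    for k, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise GenotypeIOError(
                f"{ped_path}: line {k} has {len(parts)} fields, expected {6 + 2 * m}"
            )
        iid = parts[1]
        if iid not in pop_lookup:
            raise GenotypeIOError(f"individual {iid!r} missing from population map")
        individual_ids.append(iid)
        population_labels.append(pop_lookup[iid])
        allele_rows.append(parts[6:])

    n = len(individual_ids)
    raw = np.full((n, m), MISSING, dtype=np.int16)
    allele_pairs: list[tuple[str, str]] = []
    for j in range(m):
        a_calls = [row[2 * j] for row in allele_rows]
        b_calls = [row[2 * j + 1] for row in allele_rows]
        observed = sorted({c for c in a_calls + b_calls if c != "0"})
        if len(observed) > 2:
            raise GenotypeIOError(
                f"locus {locus_ids[j]!r} has >2 alleles in PED: {observed}"
            )
        if not observed:
            allele_pairs.append((".", "."))
            continue
        counted = observed[0]
        other = observed[1] if len(observed) == 2 else "."
        for i in range(n):
            a, b = a_calls[i], b_calls[i]
            if a == "0" or b == "0":
                continue
            raw[i, j] = int(a == counted) + int(b == counted)
        allele_pairs.append((counted, other))

    values, alleles = _orient_minor(raw, allele_pairs)
    return GenotypeMatrix(values, individual_ids, population_labels, locus_ids, alleles)


def _load_vcf(vcf_path: Path, pop_lookup: dict[str, str]) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: only needed for the VCF dialect

    vcf = VCF(str(vcf_path))
    individual_ids = list(vcf.samples)
    for iid in individual_ids:
        if iid not in pop_lookup:
            raise GenotypeIOError(f"individual {iid!r} missing from population map")
    population_labels = [pop_lookup[i] for i in individual_ids]

    cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    allele_pairs: list[tuple[str, str]] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s:%s (ALT=%s)", rec.CHROM, rec.POS, rec.ALT
            )
            continue
        gts = np.asarray(rec.genotypes, dtype=object)
        col = np.full(len(individual_ids), MISSING, dtype=np.int16)
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            col[i] = int(a) + int(b)  # counts ALT copies
        cols.append(col)
        locus_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}")
        allele_pairs.append((rec.ALT[0], rec.REF))
    if not cols:
        raise GenotypeIOError(f"{vcf_path}: no biallelic SNP records")
    raw = np.stack(cols, axis=1)
    values, alleles = _orient_minor(raw, allele_pairs)
    return GenotypeMatrix(values, individual_ids, population_labels, locus_ids, alleles)


def load_genotypes(
    path: str | Path,
    format: str = "ped",
    pop_map: str | Path | dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Load a genotype panel from PED/MAP or VCF into minor-allele dosages.

    Parameters
    ----------
    path
        PED file (with its MAP sibling) or a VCF.
    format
        ``"ped"`` or ``"vcf"``.
    pop_map
        TSV path (``individual<TAB>population``) or a dict; must cover every
        individual in the file.
    """
    if pop_map is None:
        raise GenotypeIOError("pop_map is required")
    pop_lookup = _read_pop_map(pop_map)
    path = Path(path)
    if format == "ped":
        return _load_ped(path, pop_lookup)
    if format == "vcf":
        return _load_vcf(path, pop_lookup)
    raise GenotypeIOError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC


def _locus_maf(values: np.ndarray) -> np.ndarray:
    """Per-locus minor-allele frequency among non-missing calls.

    Computed as min(p, 1-p) of the counted allele, so it stays correct after
    individual removal even without re-orienting dosages.
    """
    miss = values == MISSING
    calls = np.where(miss, 0, values).sum(axis=0)
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, calls / (2 * n_obs), 0.0)
    return np.minimum(p, 1.0 - p)


def apply_qc_filters(G: GenotypeMatrix, cfg: QcConfig | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Run the locus -> individual -> MAF-re-pass filter chain.

    Loci failing the missingness threshold are counted in that stage even if
    they also fail MAF; the MAF stage counts only loci that passed
    missingness.  After individual removal the MAF filter is applied once
    more, since removing individuals can push loci below the threshold.
    """
    cfg = cfg or QcConfig()
    if G.n_loci == 0 or G.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    report = QcReport(n_individuals_in=G.n_individuals, n_loci_in=G.n_loci)

    miss_frac = G.missing_mask().mean(axis=0)
    bad_missing = miss_frac > cfg.locus_missing_max
    maf = _locus_maf(G.values)
    bad_maf = (maf < cfg.maf_min) & ~bad_missing
    report.loci_removed_missing = int(bad_missing.sum())
    report.loci_removed_maf = int(bad_maf.sum())
    report.removed_locus_ids["missingness"] = [
        G.locus_ids[j] for j in np.flatnonzero(bad_missing)
    ]
    report.removed_locus_ids["maf"] = [G.locus_ids[j] for j in np.flatnonzero(bad_maf)]
    keep_loci = np.flatnonzero(~(bad_missing | bad_maf))
    if keep_loci.size == 0:
        binding = "missingness" if bad_missing.all() else "maf"
        raise ValueError(f"all loci removed by QC; binding filter: {binding}")
    G1 = G.subset(cols=keep_loci)

    ind_miss = G1.missing_mask().mean(axis=1)
    bad_ind = ind_miss > cfg.indiv_missing_max
    report.individuals_removed_missing = int(bad_ind.sum())
    report.removed_individual_ids = [G1.individual_ids[i] for i in np.flatnonzero(bad_ind)]
    G2 = G1.subset(rows=np.flatnonzero(~bad_ind))
    if G2.n_individuals == 0:
        raise ValueError("all individuals removed by QC; binding filter: individual missingness")

    maf2 = _locus_maf(G2.values)
    bad_maf2 = maf2 < cfg.maf_min
    report.loci_removed_maf_repass = int(bad_maf2.sum())
    report.removed_locus_ids["maf_repass"] = [
        G2.locus_ids[j] for j in np.flatnonzero(bad_maf2)
    ]
    G3 = G2.subset(cols=np.flatnonzero(~bad_maf2))
    if G3.n_loci == 0:
        raise ValueError("all loci removed by QC; binding filter: maf re-pass")

    report.n_individuals_out = G3.n_individuals
    report.n_loci_out = G3.n_loci
    report.validate()
    return G3, report


def ld_prune(
    G: GenotypeMatrix,
    r2_max: float = 0.7,
    window_loci: int = 200,
    step_loci: int = 50,
) -> np.ndarray:
    """Greedy windowed LD pruning on dosage correlations.

    Within each window, while any retained pair has squared Pearson
    correlation above ``r2_max`` (on pairwise-complete observations), the
    later-indexed locus of the worst pair is dropped.  Returns the retained
    locus indices in original order.
    """
    if window_loci < 2:
        raise ValueError("window_loci must be >= 2")
    m = G.n_loci
    X = G.values.astype(float)
    X[G.missing_mask()] = np.nan
    removed = np.zeros(m, dtype=bool)
    start = 0
    while start < m:
        idx = np.flatnonzero(~removed[start : start + window_loci]) + start
        if idx.size >= 2:
            sub = pd.DataFrame(X[:, idx])
            r2 = sub.corr().to_numpy() ** 2
            np.fill_diagonal(r2, 0.0)
            r2 = np.nan_to_num(r2, nan=0.0)
            alive = np.ones(idx.size, dtype=bool)
            while True:
                r2a = r2[np.ix_(alive, alive)]
                if r2a.size == 0 or np.nanmax(r2a) <= r2_max:
                    break
                local = np.flatnonzero(alive)
                i, j = np.unravel_index(np.argmax(r2a), r2a.shape)
                drop = max(local[i], local[j])  # later-indexed locus of worst pair
                alive[drop] = False
            removed[idx[~alive]] = True
        if start + window_loci >= m:
            break
        start += step_loci
    return np.flatnonzero(~removed)


def impute_within_population(G: GenotypeMatrix) -> np.ndarray:
    """Replace missing dosages by the within-population locus mean.

    Falls back to the global locus mean when a locus has no calls inside a
    population; a locus with no calls anywhere is an error.  Returns a float
    matrix with no missing cells.
    """
    import warnings

    X = G.values.astype(float)
    miss = G.missing_mask()
    X[miss] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        global_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    if np.isnan(global_mean).any():
        bad = [G.locus_ids[j] for j in np.flatnonzero(np.isnan(global_mean))]
        raise ValueError(f"loci with no calls anywhere: {bad[:5]}")
    pops = np.asarray(G.population_labels)
    out = X.copy()
    for pop in G.populations:
        rows = np.flatnonzero(pops == pop)
        block = X[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pop_mean = np.nanmean(block, axis=0)
        fill = np.where(np.isnan(pop_mean), global_mean, pop_mean)
        block_miss = np.isnan(block)
        out[np.ix_(rows, np.arange(G.n_loci))] = np.where(block_miss, fill, block)
    return out


@dataclass
class PopAlleleFreq:
    """Population x locus minor-allele frequencies with per-cell allele counts."""

    freq: pd.DataFrame  # populations x loci; NaN where no calls
    n_alleles: pd.DataFrame  # 2 x (non-missing individuals)

    def __post_init__(self) -> None:
        if self.freq.shape != self.n_alleles.shape:
            raise ValueError("freq and n_alleles shapes differ")


def population_allele_frequencies(G: GenotypeMatrix) -> PopAlleleFreq:
    """Minor-allele frequency per population and locus from dosage counts."""
    pops = np.asarray(G.population_labels)
    order = G.populations
    miss = G.missing_mask()
    freq_rows, n_rows = [], []
    for pop in order:
        rows = pops == pop
        vals = G.values[rows]
        pmiss = miss[rows]
        n_obs = (~pmiss).sum(axis=0)
        calls = np.where(pmiss, 0, vals).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_obs > 0, calls / (2 * n_obs), np.nan)
        freq_rows.append(p)
        n_rows.append(2 * n_obs)
    freq = pd.DataFrame(freq_rows, index=order, columns=G.locus_ids)
    n_alleles = pd.DataFrame(n_rows, index=order, columns=G.locus_ids)
    return PopAlleleFreq(freq=freq, n_alleles=n_alleles)
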