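"""Synthetic landscape-genomics panels.

Generates genotype matrices, environmental tables and coordinates with the
statistical structure the pipeline assumes: many clinally sampled
populations with weak neutral differentiation (Balding-Nichols model at a
target global F_ST), a small set of adaptive loci whose population allele
frequencies follow logistic clines in mean annual temperature, uniform
missingness, and a north-south transect where future warming is stronger
in the north.

Neutral loci draw an ancestral frequency pi ~ Uniform(0.05, 0.95) and
population frequencies from Beta(pi(1-F)/F, (1-pi)(1-F)/F); adaptive loci
set the population frequency to logistic(a_l + b * temperature).
Genotypes are Binomial(2, p) within populations (Hardy-Weinberg), so
realized F_IS is centered at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .environment import EnvTable, shift_climate
from .genotypes import MISSING, GenotypeMatrix, _orient_minor

#: Default north-weighted warming (degrees C on mean_temp) per scenario:
#: (delta at the northern end, delta at the southern end).
SCENARIO_TEMP_DELTAS: dict[str, tuple[float, float]] = {
    "ssp126": (1.8, 1.2),
    "ssp245": (2.8, 2.0),
    "ssp585": (4.5, 3.0),
}

CLIMATIC_VARS = ["mean_temp", "mean_dr", "temp_s", "perc_dry_m", "perc_wet_q", "wet"]
NON_CLIMATIC_VARS = ["ph", "carbon"]


@dataclass
class LandscapePanelSpec:
    """Parameters of the synthetic landscape panel.

    Defaults emulate a clinally sampled conifer survey: 39 populations of
    5-23 diploids (median 10) along a latitudinal temperature gradient,
    ~2000 neutral SNPs at global F_ST 0.017, 20 temperature-clined adaptive
    SNPs, and 3% uniformly missing genotypes.
    """

    n_pops: int = 39
    inds_per_pop: tuple[int, int] = (5, 23)
    inds_per_pop_median: int = 10
    n_neutral: int = 2000
    n_adaptive: int = 20
    target_fst: float = 0.017
    env_gradient: tuple[float, float] = (-2.0, 9.0)  # north -> south mean_temp, deg C
    cline_intercept: float | None = None  # None: centered at the gradient midpoint
    cline_intercept_sd: float = 0.6
    cline_slope: float = 0.25  # logit frequency per deg C
    missing_rate: float = 0.03
    lat_range: tuple[float, float] = (68.0, 50.0)  # north -> south
    lon: float = 24.0
    lon_jitter: float = 0.0
    ibd_strength: float = 0.0  # >0: spatially autocorrelated neutral frequencies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("n_pops must be >= 2")
        if not 0.0 < self.target_fst < 1.0:
            raise ValueError("target_fst must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.inds_per_pop
        if not (1 <= lo <= hi):
            raise ValueError("invalid inds_per_pop range")


@dataclass
class SimulatedPanel:
    """A generated panel plus its ground truth."""

    genotypes: GenotypeMatrix
    env: EnvTable
    coords: pd.DataFrame  # population, lat, lon (WGS84 decimal degrees)
    adaptive_loci: list[str] = field(default_factory=list)
    spec: LandscapePanelSpec | None = None


def _population_sizes(spec: LandscapePanelSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.inds_per_pop
    return np.clip(rng.poisson(spec.inds_per_pop_median, spec.n_pops), lo, hi)


def _environment(spec: LandscapePanelSpec, temps: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Eight predictors: temperature and correlates plus spatial noise."""
    n = spec.n_pops
    z = (temps - temps.mean()) / temps.std()
    env = pd.DataFrame(
        {
            "mean_temp": temps,
            "mean_dr": 8.0 + 1.2 * z + rng.normal(0, 0.8, n),
            "temp_s": 800.0 - 60.0 * z + rng.normal(0, 40.0, n),
            "perc_dry_m": rng.normal(30.0, 8.0, n),
            "perc_wet_q": rng.normal(220.0, 30.0, n),
            "wet": rng.normal(170.0, 15.0, n),
            "ph": rng.normal(5.5, 0.5, n),
            "carbon": rng.normal(12.0, 3.0, n),
        }
    )
    return env


def simulate_landscape_panel(spec: LandscapePanelSpec | None = None) -> SimulatedPanel:
    """Generate a reproducible genotype/environment/coordinate panel."""
    spec = spec or LandscapePanelSpec()
    rng = np.random.default_rng(spec.seed)
    n_pops = spec.n_pops
    pop_ids = [f"pop{i + 1:02d}" for i in range(n_pops)]
    sizes = _population_sizes(spec, rng)
    pop_labels = np.repeat(pop_ids, sizes)
    n_ind = int(sizes.sum())
    individual_ids = [f"{pop_labels[i]}_ind{i:04d}" for i in range(n_ind)]

    lats = np.linspace(*spec.lat_range, n_pops)
    lons = spec.lon + (rng.normal(0, spec.lon_jitter, n_pops) if spec.lon_jitter else 0.0)
    coords = pd.DataFrame({"population": pop_ids, "lat": lats, "lon": lons})
    temps = np.linspace(*spec.env_gradient, n_pops)
    env_data = _environment(spec, temps, rng)
    env_data.index = pd.Index(pop_ids, name="population")
    env = EnvTable(data=env_data, scenario="current", climatic_vars=list(CLIMATIC_VARS))

    F = spec.target_fst
    m_neutral, m_adaptive = spec.n_neutral, spec.n_adaptive

    # neutral: Balding-Nichols population frequencies around pi
    pi = rng.uniform(0.05, 0.95, m_neutral)
    if spec.ibd_strength > 0:
        # spatially autocorrelated deviations on the logit scale; the
        # stationary variance approximates the Balding-Nichols spread
        d = np.abs(lats[:, None] - lats[None, :])
        corr = np.exp(-d / (spec.ibd_strength * np.ptp(lats)))
        L = np.linalg.cholesky(corr + 1e-10 * np.eye(n_pops))
        z = L @ rng.standard_normal((n_pops, m_neutral))
        sigma = np.sqrt(F / (pi * (1 - pi)))
        p_neutral = expit(np.log(pi / (1 - pi))[None, :] + sigma[None, :] * z)
    else:
        a = pi * (1 - F) / F
        b = (1 - pi) * (1 - F) / F
        p_neutral = rng.beta(a[None, :], b[None, :], size=(n_pops, m_neutral))

    # adaptive: logistic clines in mean annual temperature
    intercept = (
        spec.cline_intercept
        if spec.cline_intercept is not None
        else -spec.cline_slope * temps.mean()
    )
    a_locus = intercept + rng.normal(0, spec.cline_intercept_sd, m_adaptive)
    p_adaptive = expit(a_locus[None, :] + spec.cline_slope * temps[:, None])

    p_all = np.concatenate([p_neutral, p_adaptive], axis=1)
    locus_ids = [f"snp_{j + 1:05d}" for j in range(m_neutral)] + [
        f"adaptive_{j + 1:03d}" for j in range(m_adaptive)
    ]
    order = rng.permutation(m_neutral + m_adaptive)
    p_all = p_all[:, order]
    locus_ids = [locus_ids[j] for j in order]
    adaptive_loci = [lid for lid in locus_ids if lid.startswith("adaptive_")]

    pop_index = np.repeat(np.arange(n_pops), sizes)
    raw = rng.binomial(2, p_all[pop_index, :]).astype(np.int16)
    if spec.missing_rate > 0:
        miss = rng.random(raw.shape) < spec.missing_rate
        raw[miss] = MISSING

    pairs = _random_allele_pairs(len(locus_ids), rng)
    values, alleles = _orient_minor(raw, pairs)
    G = GenotypeMatrix(
        values=values,
        individual_ids=individual_ids,
        population_labels=list(pop_labels),
        locus_ids=locus_ids,
        alleles=alleles,
    )
    return SimulatedPanel(genotypes=G, env=env, coords=coords, adaptive_loci=adaptive_loci, spec=spec)


def _random_allele_pairs(m: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    bases = np.array(list("ACGT"))
    first = rng.integers(0, 4, m)
    offset = rng.integers(1, 4, m)
    second = (first + offset) % 4
    return [(bases[i], bases[j]) for i, j in zip(first, second)]


def scenario_deltas(coords: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """North-weighted mean-temperature warming for a named scenario."""
    key = scenario.lower()
    if key not in SCENARIO_TEMP_DELTAS:
        raise ValueError(f"unknown scenario {scenario!r}; known: {sorted(SCENARIO_TEMP_DELTAS)}")
    north, south = SCENARIO_TEMP_DELTAS[key]
    lat = coords.set_index("population")["lat"]
    frac = (lat - lat.min()) / (lat.max() - lat.min()) if lat.max() > lat.min() else lat * 0
    delta = south + (north - south) * frac
    return pd.DataFrame({"mean_temp": delta})


def future_env_tables(env: EnvTable, coords: pd.DataFrame) -> dict[str, EnvTable]:
    """Future tables for all built-in scenarios via :func:`shift_climate`."""
    return {
        name: shift_climate(env, scenario_deltas(coords, name), scenario=name)
        for name in SCENARIO_TEMP_DELTAS
    }


def write_fixture(panel: SimulatedPanel, directory: str | Path) -> dict[str, Path]:
    """Write PED/MAP, population map, environment CSVs and coordinates.

    The PED dialect round-trips exactly through
    :func:`landgea.genotypes.load_genotypes`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    G = panel.genotypes
    paths: dict[str, Path] = {}

    map_lines = [f"0\t{lid}\t0\t{j + 1}" for j, lid in enumerate(G.locus_ids)]
    paths["map"] = directory / "panel.map"
    paths["map"].write_text("\n".join(map_lines) + "\n")

    ped_lines = []
    for i, iid in enumerate(G.individual_ids):
        fields = [G.population_labels[i], iid, "0", "0", "0", "-9"]
        for j in range(G.n_loci):
            d = G.values[i, j]
            minor, major = G.alleles[j]
            if d == MISSING:
                fields += ["0", "0"]
            elif d == 2:
                fields += [minor, minor]
            elif d == 1:
                fields += [minor, major]
            else:
                fields += [major, major]
        ped_lines.append(" ".join(fields))
    paths["ped"] = directory / "panel.ped"
    paths["ped"].write_text("\n".join(ped_lines) + "\n")

    paths["pop_map"] = directory / "popmap.tsv"
    pop_map = pd.DataFrame({"individual": G.individual_ids, "population": G.population_labels})
    pop_map.to_csv(paths["pop_map"], sep="\t", index=False)

    paths["env_current"] = directory / "env_current.csv"
    panel.env.to_csv(paths["env_current"])
    for name, table in future_env_tables(panel.env, panel.coords).items():
        paths[f"env_{name}"] = directory / f"env_{name}.csv"
        table.to_csv(paths[f"env_{name}"])

    paths["coords"] = directory / "coords.csv"
    panel.coords.to_csv(paths["coords"], index=False)
    return paths
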