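"""Configuration-driven orchestration of the full landscape-genomics run.

Stage order: panel acquisition (synthetic or files) -> QC -> diversity /
F_ST / Mantel -> PCA -> outlier scans -> consensus PAVs -> RDA variance
partitioning -> genomic offsets -> selection-time grid.  Every stage
writes its tables under the output directory and the run ends with a
JSON summary; any stage failure aborts with the stage named, retaining
partial artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .environment import EnvTable
from .genotypes import (
    GenotypeMatrix,
    QcConfig,
    apply_qc_filters,
    impute_within_population,
    ld_prune,
    load_genotypes,
    population_allele_frequencies,
    PopAlleleFreq,
)
from .offset import (
    adaptive_index_offset,
    fit_allele_env_model,
    offset_table,
    predict_future_frequencies,
    rona_offset,
)
from .outliers import outflank_scan, pcadapt_scan
from .popgen import (
    env_distances,
    fst_linearize,
    geodesic_distances,
    heterozygosity_stats,
    mantel_test,
    wc_fst,
)
from .rda import (
    anova_axes,
    consensus_outliers,
    dbmem_basis,
    forward_select,
    rda_fit,
    rda_outliers,
    variance_partition,
    vif_prune,
)
from .selection import simulate_selection_grid
from .simulate import LandscapePanelSpec, SimulatedPanel, future_env_tables, simulate_landscape_panel
from .structure import pca_genotypes

logger = logging.getLogger(__name__)

STAGES = [
    "panel",
    "qc",
    "diversity",
    "structure",
    "outliers",
    "rda",
    "offset",
    "selection",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated run configuration; exactly one of synthetic/inputs is set."""

    seed: int = 0
    synthetic: dict[str, Any] | None = None
    inputs: dict[str, Any] | None = None
    qc: dict[str, Any] = field(default_factory=dict)
    outliers: dict[str, Any] = field(default_factory=dict)
    rda: dict[str, Any] = field(default_factory=dict)
    offset: dict[str, Any] = field(default_factory=dict)
    selection: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be configured")
        scenarios = self.offset.get("scenarios")
        if self.inputs is not None and scenarios:
            futures = self.inputs.get("env_future") or {}
            missing = [s for s in scenarios if s not in futures]
            if missing:
                raise ValueError(f"offset scenarios without future env tables: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _load_panel(cfg: PipelineConfig) -> tuple[SimulatedPanel | None, GenotypeMatrix, EnvTable, dict[str, EnvTable], pd.DataFrame]:
    if cfg.synthetic is not None:
        spec = LandscapePanelSpec(**{**cfg.synthetic, "seed": cfg.seed})
        panel = simulate_landscape_panel(spec)
        futures = future_env_tables(panel.env, panel.coords)
        return panel, panel.genotypes, panel.env, futures, panel.coords
    inp = cfg.inputs
    G = load_genotypes(inp["genotypes"], format=inp.get("format", "ped"), pop_map=inp["pop_map"])
    climatic = inp.get("climatic_vars")
    env = EnvTable.from_csv(inp["env_current"], climatic_vars=climatic)
    futures = {
        name: EnvTable.from_csv(path, climatic_vars=climatic)
        for name, path in (inp.get("env_future") or {}).items()
    }
    coords = pd.read_csv(inp["coords"])
    return None, G, env, futures, coords


def _frequencies_from_imputed(X: np.ndarray, G: GenotypeMatrix) -> PopAlleleFreq:
    """Complete (no-NaN) population frequencies from imputed dosages."""
    pops = np.asarray(G.population_labels)
    order = G.populations
    freq = pd.DataFrame(
        [X[pops == p].mean(axis=0) / 2.0 for p in order], index=order, columns=G.locus_ids
    )
    counts = pd.DataFrame(
        [np.full(G.n_loci, 2 * (pops == p).sum()) for p in order],
        index=order,
        columns=G.locus_ids,
    )
    return PopAlleleFreq(freq=freq, n_alleles=counts)


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path,
    through_stage: str | None = None,
) -> Path:
    """Execute the pipeline, writing artifacts to ``out_dir``.

    ``through_stage`` truncates the run after the named stage (see
    ``STAGES``); the summary JSON is always written for completed stages.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stop_at = STAGES.index(through_stage) if through_stage else len(STAGES) - 1
    rng = np.random.default_rng(cfg.seed)
    summary: dict[str, Any] = {"seed": cfg.seed, "version": __version__}

    stage = "panel"
    try:
        panel, G, env, futures, coords = _load_panel(cfg)
        summary["panel"] = {
            "n_individuals": G.n_individuals,
            "n_loci": G.n_loci,
            "n_populations": len(G.populations),
        }
        if stop_at >= STAGES.index("qc"):
            stage = "qc"
            qc_cfg = QcConfig(**{k: v for k, v in cfg.qc.items() if k != "ld"})
            G, report = apply_qc_filters(G, qc_cfg)
            report.to_json(out / "qc_report.json")
            summary["qc"] = {"n_individuals": G.n_individuals, "n_loci": G.n_loci}
            X = impute_within_population(G)
            freqs = _frequencies_from_imputed(X, G)

        if stop_at >= STAGES.index("diversity"):
            stage = "diversity"
            div = heterozygosity_stats(G)
            div.per_population.to_csv(out / "diversity.csv")
            fst = wc_fst(G, mode="pairwise")
            fst.pairwise.to_csv(out / "fst_pairwise.csv")
            geo_d = geodesic_distances(coords)
            env_d = env_distances(env)
            lin = fst_linearize(fst.pairwise.to_numpy())
            np.fill_diagonal(lin, 0.0)
            r_ibd, p_ibd = mantel_test(lin, geo_d.to_numpy(), n_perm=999, rng=rng)
            r_ibe, p_ibe = mantel_test(lin, env_d.to_numpy(), n_perm=999, rng=rng)
            summary["diversity"] = {
                "overall_ho": div.overall["ho"],
                "overall_he": div.overall["he"],
                "overall_fis": div.overall["fis"],
                "global_fst": fst.global_fst,
                "mantel_ibd": {"r": r_ibd, "p": p_ibd},
                "mantel_ibe": {"r": r_ibe, "p": p_ibe},
            }

        if stop_at >= STAGES.index("structure"):
            stage = "structure"
            pruned = ld_prune(G, r2_max=QcConfig(**{k: v for k, v in cfg.qc.items() if k != "ld"}).ld_r2_max)
            pca = pca_genotypes(X[:, pruned])
            scores = pd.DataFrame(
                pca.scores[:, : min(10, pca.scores.shape[1])],
                index=G.individual_ids,
            )
            scores.insert(0, "population", G.population_labels)
            scores.to_csv(out / "pca_scores.csv")
            summary["structure"] = {
                "n_loci_ld_pruned": int(len(pruned)),
                "pc1_explained": float(pca.explained_ratio[0]),
            }

        if stop_at >= STAGES.index("outliers"):
            stage = "outliers"
            ocfg = cfg.outliers
            q_thr = ocfg.get("q_threshold", 0.05)
            of = outflank_scan(G, trim=ocfg.get("trim", 0.05), q_threshold=q_thr)
            pc = pcadapt_scan(G, K=ocfg.get("K"), q_threshold=q_thr)
            retained_vars, vif_dropped = vif_prune(env)
            env_sel = EnvTable(env.data[retained_vars], env.scenario,
                               [v for v in env.climatic_vars if v in retained_vars])
            model = rda_fit(freqs.freq, env_sel.data)
            n_perm_axes = ocfg.get("n_perm_axes", 199)
            axis_p = anova_axes(model, n_perm=n_perm_axes, rng=rng)
            sig_axes = [k + 1 for k, p in enumerate(axis_p) if p < 0.05] or [1]
            rda_out = rda_outliers(
                model, sd_mult=ocfg.get("sd_mult", 2.5), axes=sig_axes,
                freqs=freqs.freq, env=env_sel,
            )
            per_locus = of.per_locus.join(
                pc.per_locus, lsuffix="_fst", rsuffix="_pca"
            )
            per_locus.to_csv(out / "outlier_scans.tsv", sep="\t")
            rda_out.to_csv(out / "rda_outliers.tsv", sep="\t")
            cons = consensus_outliers(of.outliers, pc.outliers, list(rda_out.index))
            _dump_json(
                {"venn": cons.venn_counts, "pav": cons.pav, "two_of_three": cons.two_of_three},
                out / "consensus.json",
            )
            summary["outliers"] = {
                "n_fst": len(of.outliers),
                "n_pca": len(pc.outliers),
                "n_rda": len(rda_out.index),
                "n_pav": len(cons.pav),
                "significant_axes": sig_axes,
            }

        if stop_at >= STAGES.index("rda"):
            stage = "rda"
            mem = dbmem_basis(coords)
            sel_mems = forward_select(
                freqs.freq, mem.eigenvectors,
                alpha=cfg.rda.get("alpha", 0.05),
                n_perm=cfg.rda.get("n_perm", 199),
                rng=rng,
            )
            geo_X = mem.eigenvectors[sel_mems] if sel_mems else mem.eigenvectors.iloc[:, :1]
            part = variance_partition(freqs.freq, env_sel.data, geo_X)
            _dump_json(
                {
                    "n_dbmem_candidates": mem.n_candidates,
                    "n_dbmem_selected": len(sel_mems),
                    "env_exclusive": part.env_exclusive,
                    "confounded": part.confounded,
                    "geo_exclusive": part.geo_exclusive,
                    "unexplained": part.unexplained,
                    "adj_r2_combined": part.adj_r2_combined,
                },
                out / "variance_partition.json",
            )
            summary["rda"] = {
                "adj_r2_combined": part.adj_r2_combined,
                "env_exclusive": part.env_exclusive,
                "geo_exclusive": part.geo_exclusive,
                "confounded": part.confounded,
            }

        if stop_at >= STAGES.index("offset"):
            stage = "offset"
            if not futures:
                raise ValueError("offset requested but no future environment tables configured")
            pav_panel = cons.pav if len(cons.pav) >= 2 else cons.two_of_three
            if len(pav_panel) < 2:
                raise ValueError("fewer than 2 consensus loci; cannot calibrate offsets")
            aem = fit_allele_env_model(freqs, env_sel, loci=pav_panel)
            scenarios = cfg.offset.get("scenarios") or sorted(futures)
            offsets: dict[tuple[str, str], pd.Series] = {}
            cur = freqs.freq[pav_panel]
            for scen in scenarios:
                fut = futures[scen]
                fut_sel = EnvTable(fut.data[retained_vars], fut.scenario,
                                   [v for v in fut.climatic_vars if v in retained_vars])
                pred = predict_future_frequencies(aem, fut_sel)
                offsets[("rona_rda", scen)] = rona_offset(cur, pred.freq)
                offsets[("rda_index", scen)] = adaptive_index_offset(aem, env_sel, fut_sel)
            table = offset_table(offsets)
            table.to_csv(out / "offsets.csv", index=False)
            summary["offset"] = {
                f"{m}_{s}": {
                    "min": float(v.min()),
                    "max": float(v.max()),
                    "mean": float(v.mean()),
                }
                for (m, s), v in offsets.items()
            }

        if stop_at >= STAGES.index("selection"):
            stage = "selection"
            scfg = cfg.selection
            severest = scenarios[-1]
            rona = offsets[("rona_rda", severest)]
            targets = scfg.get("targets") or [float(rona.min()), float(rona.max())]
            s_grid = scfg.get("s_grid") or [round(s, 1) for s in np.arange(0.1, 1.0, 0.1)]
            p0_grid = scfg.get("p0_grid") or [0.4]
            res = simulate_selection_grid(p0_grid, s_grid, targets)
            res.grid.to_csv(out / "selection_grid.csv", index=False)
            summary["selection"] = res.summary
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        _dump_json(summary, out / "summary.json")
        raise PipelineError(stage, exc) from exc

    _dump_json(summary, out / "summary.json")
    logger.info("pipeline complete: %s", out / "summary.json")
    return out
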