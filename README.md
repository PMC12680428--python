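# landgea

Landscape genomics for clinally sampled SNP panels: from raw genotypes to
the number of generations a population would need to track its climate.

`landgea` is aimed at population geneticists studying local adaptation in
range-wide surveys of outcrossing species (the motivating case is a conifer
transect: dozens of populations of 5–23 diploids genotyped on a ~10⁴-SNP
array across a steep temperature gradient, with very weak background
differentiation, global F_ST ≈ 0.017). It implements the full analysis
chain as a tested, reusable Python library plus a thin CLI:

1. **QC** — PED/MAP and VCF readers; MAF < 0.05, locus/individual
   missingness > 10%, LD pruning at r² > 0.7, within-population mean
   imputation (`landgea.genotypes`).
2. **Diversity & structure** — H_o, Nei's unbiased H_e, F_IS;
   Weir–Cockerham F_ST (global and pairwise, ratio-of-sums); Mantel IBD/IBE
   with Vincenty geodesics and Mahalanobis environmental distances; SVD
   PCA and a permutation test of how much structure a SNP subset carries
   (`landgea.popgen`, `landgea.structure`).
3. **Outlier consensus** — a trimmed chi-square F_ST scan
   (F_ST ~ (F̄/df)·χ²_df fitted by truncated ML), a PC-regression
   Mahalanobis scan with genomic-inflation rescaling, an RDA loading scan
   at ±2.5 SD, Storey q-values, and their three-way intersection defining
   the potential adaptive variants, PAVs (`landgea.outliers`,
   `landgea.rda`).
4. **Variance partitioning** — partial RDA with VIF-pruned environmental
   predictors and forward-selected dbMEM spatial eigenvectors, splitting
   adjusted R² into environment-exclusive, geography-exclusive and
   confounded fractions (`landgea.rda`).
5. **Genomic offset** — RONA-RDA (a bounded two-stage allele-frequency
   predictor: constrained ordination followed by per-locus binomial logit
   calibration; offset = 1/n Σ|pᵢ − pᵢ*|) and the RDA adaptive-index
   offset (Euclidean distance between current and future adaptive
   indices), plus IDW surface projection (`landgea.offset`).
6. **Selection time** — deterministic iteration of
   Δp = s·p·q²/(1 − s·q²) (favored allele fully dominant) until the
   cumulative change matches an offset value, converted to years at a
   20–25-year generation time (`landgea.selection`).

A first-class synthetic-data generator (`landgea.simulate`) reproduces the
statistical structure the analysis assumes — Balding–Nichols neutral
background at a target F_ST, logistic temperature clines at a small set of
adaptive loci, uniform missingness, north-weighted future warming — so the
entire pipeline runs and is tested without any downloads.

## Worked example

```python
from landgea.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=1,
    synthetic={"n_neutral": 1000},       # 39 pops, 1000 neutral + 20 clinal SNPs
    outliers={"n_perm_axes": 99},
    rda={"n_perm": 99},
)
run_pipeline(cfg, "out/")
```

or equivalently `landgea run-all --config config.yaml --out out/`. The
summary JSON of this exact run reports, among others:

```
global_fst            0.0204      # weak background differentiation
overall_ho / he       0.361 / 0.362, F_IS = 0.002
outliers              n_fst=22, n_pca=21, n_rda=20 -> n_pav=20
rona_rda_ssp585       min 0.095, max 0.278         # per-population offsets
selection             target 0.095: 1-7 generations (<= 175 y at 25 y/gen)
                      target 0.278: 2-25 generations (<= 625 y)
```

Reading: the neutral background is nearly undifferentiated while all 20
planted clinal loci are recovered by the three-method consensus; under the
severest warming scenario the most exposed population would need its
adaptive allele frequencies to shift by 0.28 on average, which pure
selection of strength s ∈ [0.1, 0.9] would deliver in 2–25 generations.

Stage-wise subcommands (`landgea qc|diversity|structure|outliers|rda|offset|selection-time`)
run the pipeline through the named stage; `landgea simulate` writes a
synthetic panel as PED/MAP + CSV fixtures.

## Layout

```
src/landgea/
  genotypes.py    I/O + QC chain        popgen.py     diversity, F_ST, Mantel
  simulate.py     synthetic panels      structure.py  PCA + subset test
  outliers.py     F_ST & PC scans       rda.py        RDA, dbMEM, varpart, GLM
  offset.py       RONA & RDA offsets    selection.py  selection-time recursion
  environment.py  env tables            pipeline.py / cli.py   orchestration
```

See `docs/methods.md` for the statistical details and modeling choices.
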