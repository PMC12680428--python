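# Methods

This note documents the statistical models behind `landgea`, the defaults
and why, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer should know about.

## Genotype model and QC

Genotypes are diploid biallelic dosages counting the panel-wide minor
allele; the missing sentinel is a reserved integer (−9), never NaN, so the
integer matrix stays exact. Minor/major assignment uses panel-wide allele
counts with ties at frequency 0.5 broken toward the lexicographically
smaller allele character — this makes dosage signs reproducible under any
row permutation of individuals, which matters because every downstream
loading and GLM slope inherits the sign.

The QC chain is locus filters first (missingness > 10%, then MAF < 5%
among the survivors), then individual missingness > 10%, then a single MAF
re-pass, since removing individuals can push loci back under the MAF
threshold. One re-pass suffices for idempotence on realistic data and the
report records every removal, so the chain is auditable. LD pruning is
greedy and windowed (defaults: 200-locus windows, step 50, r² > 0.7,
pairwise-complete correlations): within a window the later-indexed locus
of the worst offending pair is dropped until no pair exceeds the
threshold. The wide window default reflects array designs with roughly one
SNP per gene, where long-range sorting of correlated loci is rare.
Missing dosages are mean-imputed within populations (global locus mean as
fallback) only for analyses that need complete matrices (PCA, RDA);
diversity and F_ST statistics use the observed calls.

## Diversity and differentiation

H_o is the heterozygote fraction among non-missing calls; H_e is Nei's
unbiased within-population gene diversity 2p(1−p)·2n/(2n−1) (the plain
2pq limit is recovered at large n); F_IS = 1 − H_o/H_e. Population values
are unweighted means over loci and overall values unweighted means over
populations — with unequal sample sizes a weighted convention would
differ slightly; the unweighted one is recorded here as the package's
choice.

F_ST uses the Weir–Cockerham (1984) variance components a (among
populations), b (among individuals within populations) and c (within
individuals), computed per locus from per-population sample sizes, allele
frequencies and heterozygote fractions, with the multilocus estimate as
the ratio of sums Σa/Σ(a+b+c) — not a mean of per-locus ratios, which
would be biased by low-information loci. Pairwise estimates re-run the
estimator on the two populations only and negative estimates are reported
as-is. The estimator recovers the generating F of Balding–Nichols
simulations within ±0.01 (30 populations × 20 diploids × 1000 loci).

Geographic distances are Vincenty inverse geodesics on the WGS84
ellipsoid (implemented in-package; the iteration aborts with the pair
named if a near-antipodal pair fails to converge, which cannot occur on
regional transects). Environmental distances standardize the predictor
table, project onto the first two principal components and take
Mahalanobis distances under the score covariance — invariant to affine
rescaling of any input variable. Mantel tests correlate off-diagonal
upper triangles with joint row/column permutations and the add-one
p-value convention; genetic distances are linearized as F_ST/(1−F_ST).

## Outlier scans and the consensus

**Trimmed chi-square F_ST scan.** Per-locus F_ST is computed without
finite-sample correction (s²/p̄(1−p̄) with frequency-weighted moments):
the finite-sample inflation is shared by all loci and is absorbed by the
fitted distribution, which is the point of fitting rather than assuming
the neutral spread. The model is F_ST ~ (F̄/df)·χ²_df. F̄ is profiled as
the two-sided 5%-trimmed mean and df maximizes the truncated chi-square
likelihood on the trimmed bulk (bounded scalar optimization, tolerance
1e−8). On draws from the generative model the fit recovers df and F̄
within a few percent (the trimmed-mean bias for a chi-square with df ≈ 20
is ~1%). Right-tail p-values from the fitted distribution are converted
to Storey q-values; loci with expected heterozygosity < 0.1 are excluded
from both fitting and calling because their F_ST estimates are erratic.
Fewer than 50 loci in the trimmed bulk is an error, not a warning.

**PC-regression Mahalanobis scan.** Dosages are scaled to unit binomial
variance (√(2p̂(1−p̂))), individuals projected onto the leading K
principal components (automated Cattell rule: keep axes while the
eigenvalue drop stays ≥ 5% of total variance; K is user-overridable), and
each locus is summarized by the K-vector of regression z-scores of its
scaled dosages on the component scores. The outlier statistic is the
Mahalanobis distance of that vector under the empirical mean and
covariance (minimum-covariance-determinant scatter available behind
`robust=True` with a seed; off by default so results are deterministic).
p-values come from χ²_K after dividing by the genomic inflation factor
λ = median(D²)/median(χ²_K); on neutral panels λ stays in [0.8, 1.2] and
the p-values are uniform.

**RDA loading scan.** Loci whose loadings on the significant constrained
axes (sequential permutation test, below) lie beyond ±2.5 SD of that
axis's loading distribution are flagged; the SD is computed on all loci
including prospective outliers — robust scale estimates would change the
nominal 2Φ(−2.5) ≈ 1.24% per-axis tail and are deliberately not used.
Each flagged locus is annotated with the predictor most correlated with
its population frequencies.

**Consensus.** The PAV panel is the exact three-way intersection; the
union of pairwise intersections ("two of three") is produced for
sensitivity analyses. On default synthetic panels the consensus recovers
≥ 70% of planted clinal loci with ≤ 1 false positive (median over 20
seeds); the intersection is what controls the false positives — each
individual scan admits a handful.

## RDA, dbMEM and variance partitioning

The ordination centers the response (population allele frequencies),
standardizes predictors, solves the multivariate least squares by SVD
projection, and decomposes the fitted values: eigenvalues are squared
singular values over n−1, site scores U·S, locus loadings the right
singular vectors, and predictor biplot scores the correlations between
standardized predictors and site scores. Singular values below an
absolute tolerance (10⁻⁸·√n, relative to the √n scale of standardized
columns) span nothing — this matters for partial models where
residualization can reduce predictors to numerical noise. R² is
trace(fitted)/trace(total) and adjusted R² uses Ezekiel's formula.
Partial RDA residualizes both response and predictors on the conditioning
matrix (the standard pCCA construction); its adjusted R² is the
semipartial difference adjR²(X∪Z) − adjR²(Z), which makes the variance
partition an exact identity: a + b + c equals the combined model's
adjusted R² to machine precision by construction, with
a = adjR²(env+geo) − adjR²(geo), c symmetric, b the remainder.

Axis significance uses a sequential permutation test: for axis k the
residuals around the first k−1 axes' reconstruction are row-permuted, the
ordination refitted and the axis-k eigenvalue compared (add-one
convention). Under pure noise the axis-1 p-value is uniform.

dbMEM spatial predictors truncate the geodesic distance matrix at the
longest minimum-spanning-tree edge t (entries beyond t set to 4t), apply
Gower centering to −D∘D/2 and keep positive-eigenvalue eigenvectors; a
transect of n sites yields n−1 nonzero candidate axes. Forward selection
follows the two-criterion rule: admit the candidate with the largest
additional adjusted R² if its marginal permutation pseudo-F has p < 0.05
and the cumulative adjusted R² does not exceed the global model's. A
consequence worth knowing: with exactly one informative candidate among
pure noise the global model's adjusted R² is, in expectation, no larger
than the true submodel's, so the guard binds roughly half the time — the
rule is designed for settings where several spatial scales carry signal.

Predictor collinearity is reduced before any RDA by iteratively dropping
the variable with the highest mean |r| among pairs with |r| ≥ 0.7, then
the highest-VIF variable while any VIF ≥ 10.

The per-locus genotype–temperature GLM treats each diploid as two
Bernoulli trials (dosage successes out of 2), fitted by IRLS; the odds
ratio is exp(β₁) per °C. A homozygote-contrast coding (minor vs major
homozygotes, heterozygotes dropped) is available via `coding="homozygote"`
since genotype-presence phrasings of this model are ambiguous between the
two; the dosage-binomial coding is the default. Perfect separation and
boundary fits are flagged, not raised.

## Genomic offset

RONA-RDA uses a two-stage bounded predictor. Stage 1 fits the ordination
of PAV frequencies on the (VIF-pruned) environment; stage 2 fits, per
locus, a binomial logistic regression of the observed allele counts on
the stage-1 linear prediction. A GLM rather than a GAM is used for stage
2: with ~39 calibration sites a smoother is under-constrained, and the
logit link already guarantees predictions strictly inside (0, 1), which
is the purpose of the second stage. Future environments are standardized
with the CURRENT means and SDs — the calibration frame must not move with
the scenario. Predictions are exactly reproducible in-sample; loci fixed
across all populations are flagged and predicted at their current
frequency. The offset is the per-population mean absolute difference
between current and predicted frequencies, so it lives on the allele-
frequency scale ([0, 1]) and is zero when the future equals the present.
Recalibrating the model on its own fitted values reproduces predictions
to within 0.05 (mean deviation < 0.01) rather than exactly: the stage-1
projection of a logit-transformed surface is not its own linear
predictor, so the two-stage construction is near- but not strictly
idempotent.

The RDA adaptive-index offset projects standardized environments through
the predictor biplot scores to a per-site index per retained axis; the
offset is the Euclidean distance between current and future index
vectors — sign-flip invariant and zero at identical climates. The two
offsets rank populations concordantly on synthetic panels (median
Spearman ≈ 0.8 across replicate panels) and the ranking is stable under
swapping the strict PAV panel for the two-of-three panel (Spearman >
0.9).

IDW projection operates on planar coordinates (equirectangular at the
mean latitude) with power-2 weights and exact values at coincident nodes;
a decile-binning helper supports indexed-class maps.

## Selection-time translation

The recursion Δp = s·p·q²/(1 − s·q²) (favored allele dominant, h = 0) is
iterated until the cumulative change first reaches the target; T counts
completed generations, T = 0 for a zero target, and targets beyond 1 − p₀
or the iteration cap are flagged unreachable rather than raised. Years
are T × generation time, with both 20 and 25 years evaluated and 25 used
for headline conversions. Drift, gene flow and finite population size are
deliberately excluded — each would lengthen the wait, so the result is a
lower bound. For weak selection, T·s approaches the continuous-time
integral ∫dp/(p q²) = [ln(p/(1−p)) + 1/(1−p)] between p₀ and p₀+target;
agreement is within 15% once trajectories exceed ~15 generations, while
very short trajectories are dominated by the integer-ceiling
discretization. The published range for these scenarios (3–29 generations
for a 0.27 shift from p₀ = 0.4) is slightly wider than direct iteration
of the printed recursion yields (2–24 here); the discrepancy evidently
lies in an unstated counting or parameterization convention of the
original implementation, so the recursion as printed is what this package
computes and the published figures are treated as upper bounds.

## Synthetic panels: what they emulate, and what not

The generator draws, per neutral locus, an ancestral frequency
π ~ U(0.05, 0.95) and population frequencies from the Balding–Nichols
Beta(π(1−F)/F, (1−π)(1−F)/F) at the target F_ST (default 0.017);
adaptive-locus frequencies are logistic(a_l + b·temperature) with slope
b = 0.25 logit/°C and per-locus intercepts spread with SD 0.6 around the
gradient midpoint — chosen so the per-locus frequency–temperature R²
falls in the 0.5–0.8 window typical of strong clines (realized mean
≈ 0.73), against ≈ 0.03 for neutral loci. Genotypes are Binomial(2, p)
within populations, so F_IS is centered at zero; missingness is uniform
at 3%; population sizes are Poisson(10) clipped to [5, 23] (median 10)
across 39 populations; temperatures span −2 to +9 °C north to south on a
single meridian from 68° to 50° latitude; built-in warming scenarios
shift mean temperature by +1.2…+4.5 °C with stronger warming in the
north. An optional mode (`ibd_strength > 0`) replaces the exchangeable
Balding–Nichols draws with spatially autocorrelated logit-frequencies so
that isolation by distance and a structured neutral background can be
exercised.

Not emulated: linkage (loci are independent, so LD pruning only ever
removes chance correlations), demographic history and range expansion,
selection during the simulation itself (the response is modeled
analytically), genotyping-intensity artifacts, and non-uniform
missingness. Consequently, passing tests demonstrate the statistical
machinery is correct and calibrated under the stated generative model —
they do not certify behaviour under strong LD, admixture clines or
informative missingness. One structural consequence is worth noting:
under the exchangeable default the only geographic axis in the data IS
the planted cline, so full-panel PCA is driven by the adaptive loci;
with a spatially structured neutral background (the realistic
postglacial scenario) the ordination is carried by the background and is
insensitive to removing the PAVs.

## Problem sizes used in tests

Test and acceptance runs use the default 39-population panel with 2000
neutral + 20 adaptive loci (calibration suites: 1000–1500 neutral loci,
6–20 replicate seeds), chosen as the smallest sizes at which the
calibration claims (F_ST recovery, λ bounds, consensus power) are stable
across seeds.
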