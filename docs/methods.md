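# Methods

This note documents the models, numerical choices and limitations of
`gxegrowth`. It is the package's own account of its science; every number
quoted here is computed by the test suite or by `scripts/acceptance.py`.

## Growth-curve parameterization

Individual plant height is modelled by the logistic function

y(t) = (K + y0) / (1 + (K/y0)·e^(−rt)) − y0,

chosen so that y(0) = 0 (a plant has zero height at sowing) and y → K as
t → ∞. Internally the algebraically equivalent form
y = y0·K·(1 − e^(−rt)) / (y0 + K·e^(−rt)) is evaluated, which makes the
t = 0 anchor exact in floating point. The shape constant y0 is fixed at
50 cm for every individual and K at the maximum observed height, so only
the rate r is free. The fit minimizes the squared error over
r ∈ (10⁻⁶, 2] per day via a 160-point log-spaced bracket scan followed by
bounded scalar minimization; the bracket makes the result robust when the
objective is nearly flat at extreme rates, and a test asserts the fit never
loses to a dense 10⁻⁵-step grid.

Two consequences of the K-fixing rule are worth knowing. First, if the
series is truncated before the curve saturates, K̂ = y_max < K and the
least-squares optimum of r shifts slightly away from the generative rate
(about 3×10⁻⁶ for a 12-week series at K = 100, r = 0.15); rate recovery is
therefore exact only on saturated series. Second, a day-0 observation is
harmless and included when present, because the curve passes through the
origin by construction.

Weekly increments are differences between consecutive observations,
labelled by the later observation's week; gaps simply span longer
intervals. Degenerate series (fewer than 3 points, or all-zero heights)
are excluded from trait extraction with a warning, and replicate averages
use the remaining individuals.

## Mixed-model association scans

Per environment, the replicate-averaged trait y is tested at each locus by
a likelihood-ratio test between

- null: y = 1μ + g + ε
- alternative: y = 1μ + x·β + g + ε

with g ~ N(0, σ²g·K) and ε ~ N(0, σ²e·I). K is the realized relationship
matrix K = ZZᵀ/m, where each non-constant genotype column is mean-centred
and divided by its population (divide-by-n) standard deviation; under this
standardization mean(diag K) = 1 exactly, which the code asserts. Constant
columns are dropped from m.

Both models are fitted by maximum likelihood (not REML), so the LRT between
them is valid. The fixed effects and the total variance are profiled out
analytically on the eigenbasis of K, leaving a 1-D problem in the variance
ratio δ = σ²e/σ²g. The profile can be multimodal in δ, so a 49-point grid
over log₁₀δ ∈ [−6, 6] locates the global basin before a bounded scalar
search refines it; a test compares the result against a dense brute-force
grid. The eigendecomposition is computed once per scan and reused across
loci. At δ → ∞ the model collapses to OLS, which serves as a boundary
check.

The statistic 2(llₐ − ll₀) is floored at 0 and referred to χ²₁. Loci with
fewer than 2 carriers or 2 non-carriers among the phenotyped cultivars are
skipped and reported with missing p (a constant dummy passed directly to
`lrt_pvalue` returns p = 1: zero contrast). Rows with missing phenotype are
dropped per scan and at least 10 phenotyped cultivars are required.
P-values are floored at the smallest positive double so −log₁₀ plots stay
finite. Benjamini–Hochberg q-values (statsmodels step-up) are attached per
scan. Under a null simulation with polygenic background (93 cultivars,
2,000 loci) the empirical type-I error at p < 0.05 is ≈ 0.05 (the
acceptance suite requires [0.035, 0.065]), and a planted common locus with
a 2.5-residual-SD effect ranks first in 50/50 seeded replicates. For rare
variants at n = 93 top-ranking is not guaranteed even for large effects —
the power simulation deliberately plants a common variant, the analogue of
the major maturity / stem-termination loci such scans are meant to find.

## Factor selection heuristics

Genetic factors. For each trait the per-environment scans are pooled by
taking the union of each environment's top N = 100 loci (ties broken by
chromosome, position). Each pooled locus is scored by the minimum of its
per-environment p-values; candidates are admitted greedily in min-P order
(same tie-break, so the list is invariant to input order) and discarded iff
an already-retained locus on the same chromosome lies strictly closer than
100 kb. The resulting priority list is then walked, keeping loci with at
least 2 carriers and 2 non-carriers whose genotype profile has |Pearson
r| < 0.5 against every factor already kept, until the requested number is
reached. Profiles are the cultivar dummies replicated over the training
environments; when every environment covers the same cultivars this equals
the plain cultivar-level correlation, and an explicit sample index can be
supplied for uneven coverage. The correlation cap is enforced among
genetic factors; environmental factors are selected independently
beforehand (see below), mirroring the fact that temperature windows are
chosen without reference to trait values.

Environmental factors. Daily temperatures from sowing are summarized as
T0…T90, the means of the ten consecutive 10-day windows (a series shorter
than 100 days is an error naming the missing windows). Windows are admitted
chronologically: T0 always enters; a later window enters only if its
absolute correlation across training environments with every admitted
window is below 0.5. Zero-variance windows are treated as blocked (they
carry no usable signal). Sowing day-of-year and field latitude are always
appended as day-length proxies. Which windows survive depends on the
realized weather; on the reference synthetic scenario two windows typically
survive, as the acceptance script reports.

All thresholds (N = 100, 100 kb, 0.5, carrier count 2) are keyword
arguments with these defaults.

## G×E regression models

The design matrix for samples (cultivar i, environment e) is
[1 | x₁..x_m | z₁..z_n | x_h·z_k for all pairs], restricted to the pattern
(G, E, G+E, G+E+G×E); interactions are products of the binary genotype
dummy with the raw numeric factor, so a non-carrier row has zero
interaction cells and a carrier row inherits z itself. Environmental
factors enter untransformed (°C, day-of-year, degrees latitude) so
coefficients stay on natural scales. Fitting is plain OLS via
`scipy.linalg.lstsq` (gelsd); rank deficiency triggers a warning and the
minimum-norm solution, which matters at desk scale where a full
interaction block can exceed the information in a handful of environments.
No regularization is applied. Evaluation reports Pearson R (NaN with a
warning when a vector is constant) and RMSE; the factor-count scan refits
each pattern at 1..100 genetic factors taken as prefixes of the priority
order and evaluates both the training environments and the held-out
environment set. In-sample, nesting guarantees R(G) ≤ R(G+E) ≤ R(G+E+G×E)
and monotonicity in the factor count, which the tests assert per seed.

The train/test split is by environment set (earlier-year environments
train, later-year plus novel-field environments test) and is configured,
never random.

## Synthetic-data generator

The generator emulates the structure of a two-field, multi-sowing trial:

- Genotypes: inbred lines carry binary homozygous dummies at loci spread
  evenly over 20 chromosomes (positions drawn without replacement,
  1-based); each locus draws a carrier frequency uniformly from the MAF
  range (default 0.1–0.5) and assigns round(freq·n) carriers. Heterozygotes
  are not simulated.
- Environments: daily temperature = annual mean (22 °C) + 8 °C seasonal
  cosine peaking around day 213 + 0.55 °C per degree latitude toward the
  35 °N reference + a per-(field, year) offset (sd 0.8 °C) + iid daily noise
  (sd 1.5 °C). The gradient reproduces the 3–4 °C warmth of the southern
  field and the year offset produces anomalies like a cold June, both of
  which the window-selection step needs to be non-trivial.
- Traits: FT, K and r are drawn from the linear G+E+G×E model with known
  coefficients (TruthModel) plus Gaussian replicate noise (defaults: 2 d,
  6 cm, 0.006 per day). Default effect sizes put G, E and G×E contributions
  on the same order as the noise; the three traits share part of their
  causal architecture, as real maturity loci do.
- Growth: each replicate's latent (K, r) generates a weekly logistic
  trajectory from day 0 with 2 cm height noise, truncated at 0; latent K is
  floored at 20 cm and r clipped to [0.02, 1] to keep curves biologically
  sensible. Downstream growth traits are re-estimated from these
  trajectories, so curve-fitting error propagates realistically into the
  K and r models.

The reference scenario is 93 cultivars × 2,000 loci, 8 training
environments (two fields, 2018 single sowing + 2019 three sowings) and 9
test environments (2020, three fields × three sowings) observed on a
32-cultivar subset. All randomness flows from one seed through a fixed
SeedSequence spawn order, so studies are bit-reproducible; the pipeline's
artifacts are byte-identical across reruns of the same config.

What the generator does not emulate: linkage disequilibrium and population
structure beyond what random sharing of causal loci induces (the GRM is
therefore close to diagonal), day-length physiology (latitude acts only
linearly), precipitation/soil covariates, missing data patterns, and
selection-induced correlations between loci. Passing tests demonstrate
correctness of the machinery and recoverability under the stated generative
model — not that real field data satisfy that model.

## Field statistics

The ANOVA partition of terminal height is the classical two-factor
decomposition with interaction, using sequential (Type-I) sums of squares
in the fixed order cultivar, environment, cultivar:environment, each tested
against the residual mean square. Because field designs are unbalanced and
may have empty cells, each term's df is the rank increase of the cumulative
one-hot design matrix (singular values below eps·max(n, p)·σmax are treated
as zero — the bare-eps default miscounts exactly-collinear factor blocks).
On a balanced design this reproduces statsmodels' `anova_lm(typ=1)`
exactly, which the tests use as an independent oracle; with a full
replicated design of 93 cultivars × 8 environments the cultivar df is 92
and the interaction df is 92×7, dropping by one per empty cell.

## Problem sizes used in the checks

The test suite and acceptance script run at the reference scale for the
structure-sensitive checks (93 × 2,000 null calibration; 93-cultivar ANOVA;
full-pipeline determinism) and at reduced scale elsewhere (e.g. 40
cultivars × 80 loci for coefficient-recovery replicates, 1,000 loci per
power replicate), sizes chosen so that repeated seeds still characterize
the sampling distributions being asserted.

## Known limitations

- The LMM uses a single GRM random effect; no additional structure
  covariates, no multi-trait or multi-environment joint models.
- Physical-distance pruning is not LD-aware; two distant loci in perfect
  correlation are handled by the correlation cap, not by clumping.
- OLS with up to 255 columns on ~744 samples is intentionally
  unregularized; coefficient variance at n_g = 100 is large, and the
  factor-count scan is the intended diagnostic.
- The gamma-family GLM variant of the ANOVA (for skewed height
  distributions) is not implemented; the Gaussian partition is the primary
  and only path.
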