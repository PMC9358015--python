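# gxegrowth

Genotype-by-environment (G×E) modelling of growth-related traits for
multi-environment crop trials.

Crop cultivars — soybean being the motivating case — are adapted to narrow
latitude bands: flowering time and vegetative growth respond strongly to
temperature, day length and sowing date, and the response differs by
genotype. Predicting how a panel of inbred cultivars will perform in a new
field therefore needs genetic factors (G), environmental factors (E) *and*
their interactions (G×E) in one model. `gxegrowth` implements that analysis
chain for trial designs of the form *cultivars × (field × year × sowing
time)*, together with a synthetic-data generator whose ground truth is fully
known, so every stage is testable without field data.

## What the package computes

**Growth parameterization.** Weekly plant heights of each individual are fit
by the logistic curve

    y(t) = (K + y0) / (1 + (K / y0) e^{-r t}) − y0

anchored at y(0) = 0, with the shape constant y0 fixed at 50 cm and K pinned
to the individual's maximum observed height, leaving a bounded 1-D
least-squares estimate of the growth rate r. The traits carried forward are
flowering time FT (days from sowing), K (cm) and r (per day),
replicate-averaged per cultivar × environment.

**Association scans.** Each binary locus dummy x (presence of a specific
homozygous variant genotype) is tested per environment with a linear mixed
model, y = Xβ + g + ε, g ~ N(0, σ²g·K) for the realized relationship matrix
K = ZZᵀ/m of standardized genotypes, by a likelihood-ratio χ²₁ test of the
locus term; Benjamini–Hochberg q-values are attached per scan.

**Factor selection.** The top-N loci of every environment are pooled, ranked
by min-P across environments, thinned to ≥ 100 kb spacing per chromosome,
and admitted greedily under carrier-count (≥ 2 both ways) and correlation
(|r| < 0.5) filters. Environmental factors are the mean temperatures of
10-day windows after sowing (T0…T90) admitted chronologically under the same
correlation cap, plus sowing day-of-year and field latitude.

**G×E regression.** For sample i (one cultivar in one environment),

    y_i = c + Σ_h α_h x_{h,i} + Σ_k β_k z_{k,i} + Σ_{h,k} γ_{h,k} x_{h,i} z_{k,i} + ε_i

fitted by OLS in four nested patterns P = G, E, G+E, G+E+G×E, with a
1..100-factor scan and Pearson-R / RMSE evaluation on training environments
and held-out (later-year, extra-field) environments.

**Field statistics.** Per-environment trait correlations and the sequential
two-factor ANOVA partition of terminal height into cultivar (G), environment
(E), interaction (G×E) and residual terms, with degrees of freedom taken from
the realized design rank so unbalanced designs with empty cells are handled.

## Worked example

`examples/fit_gxe_models.py` simulates a 40-cultivar trial (two training
fields × three sowings in 2019; a new field with two sowings in 2020 as the
test set), runs the whole pipeline for FT with 10 genetic factors, and
prints:

```
pattern     split  Pearson R   RMSE (days)
G           train      0.787      8.96
G           test       0.944      3.34
E           train      0.577     11.86
E           test       0.141     10.47
G+E         train      0.976      3.17
G+E         test       0.955      3.01
G+E+GxE     train      0.979      2.95
G+E+GxE     test       0.954      3.04
```

P=G assigns every cultivar one value regardless of environment and P=E
assigns every environment one value regardless of cultivar, so both are
ceilinged; G+E adds the environment baseline shift, and the G×E terms let
locus effects scale with temperature, sowing date and latitude. The other
scripts in `examples/` walk through each capability (simulation, curve
fitting, scans, selection, ANOVA) the same way.

A thin CLI mirrors the stages:

```bash
gxe simulate --out data/ --seed 1
gxe fit-growth --pheno data/phenotypes.csv --out traits.csv
gxe run --config config.yaml --out results/
```

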