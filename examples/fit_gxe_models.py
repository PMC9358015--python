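"""Fit the four model patterns and compare estimation vs prediction.

The trait is modelled as y = c + sum alpha_h x_h + sum beta_k z_k +
sum gamma_hk x_h z_k + eps. Patterns G, E, G+E and G+E+GxE are nested, so
in-sample fit can only improve left to right; held-out environments reveal
whether the interaction terms carry real signal.
"""
from gxegrowth import PipelineConfig, run_pipeline
from gxegrowth.simulate import FieldSite, SimScenario

scenario = SimScenario(
    n_cultivars=40,
    n_loci=400,
    n_chromosomes=8,
    fields=(
        FieldSite("MF", 31.8, {2019: (160, 190, 220)}),
        FieldSite("TF", 38.5, {2019: (155, 185, 215)}),
    ),
    test_fields=(FieldSite("KF", 35.3, {2020: (165, 205)}),),
    n_test_cultivars=20,
)
cfg = PipelineConfig(seed=3, trait="FT", n_factors=10, top_n=25, scenario=scenario)
results = run_pipeline(cfg, "scratch/example_run")

print("pattern     split  Pearson R   RMSE (days)")
for _, row in results["evaluation"].iterrows():
    print(f"{row['pattern']:<10}  {row['split']:<5}  {row['pearson_r']:9.3f}  {row['rmse']:8.2f}")
print()
print("P=G cannot separate environments and P=E cannot separate cultivars, so")
print("both plateau; adding E to G captures the additive environment shift, and")
print("the GxE terms let the genotype effect bend with temperature, sowing date")
print("and latitude, which is what transfers to the held-out 2020 environments.")
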