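"""Generate a synthetic multi-environment trial and look at its pieces.

The generator produces binary genotypes for inbred cultivars, daily
temperature series per field x year x sowing-time environment, replicate-level
trait values from a known G + E + GxE linear model, and weekly logistic
height trajectories realizing the latent (K, r) growth traits.
"""
from gxegrowth import simulate_study
from gxegrowth.simulate import FieldSite, SimScenario

scenario = SimScenario(
    n_cultivars=30,
    n_loci=200,
    n_chromosomes=5,
    fields=(
        FieldSite("MF", 31.8, {2019: (160, 200)}),
        FieldSite("TF", 38.5, {2019: (155, 195)}),
    ),
    test_fields=(FieldSite("KF", 35.3, {2020: (165,)}),),
    n_test_cultivars=15,
)
study = simulate_study(scenario, seed=7)

print(f"genotypes: {study.genotypes.n_cultivars} cultivars x {study.genotypes.n_loci} loci")
print(f"training environments: {study.train_envs}")
print(f"test environments:     {study.test_envs}")
print()
print("replicate-averaged flowering time (days from sowing), first rows:")
print(study.traits["FT"].averaged().head(6).to_string(index=False))
print()
env = study.environments[study.train_envs[0]]
print(
    f"environment {env.name}: latitude {env.latitude} N, sowing day {env.sowing_doy}, "
    f"mean temperature of the first 10 days {env.temperatures[:10].mean():.1f} C"
)
print()
print("Each trait value is intercept + locus effects + temperature/sowing/latitude")
print("effects + genotype-by-environment interactions + replicate noise, so every")
print("downstream estimate can be checked against the generating coefficients.")
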