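"""Partition terminal plant height into G, E and GxE variance components.

Sequential (Type-I) two-factor ANOVA in the order cultivar, environment,
interaction; with empty cultivar x environment cells the interaction df
comes from the realized design rank.
"""
from gxegrowth import anova_gxe, simulate_study, trait_correlation
from gxegrowth.simulate import FieldSite, SimScenario

scenario = SimScenario(
    n_cultivars=25,
    n_loci=150,
    n_chromosomes=5,
    fields=(
        FieldSite("MF", 31.8, {2019: (160, 200)}),
        FieldSite("TF", 38.5, {2019: (155, 195)}),
    ),
    test_fields=(),
    n_replicates=3,
)
study = simulate_study(scenario, seed=9)
pheno = study.pheno_wide()

table = anova_gxe(pheno, response="terminal_height")
print(table.round(3).to_string())
print()
print("'cultivar' carries the genetic (G) variance, 'environment' the field x")
print("sowing-time (E) variance, and the interaction row is the GxE component;")
print("its F-test against the residual mean square asks whether cultivars")
print("reorder across environments beyond replicate noise.")

ft_k = pheno[["cultivar", "environment", "FT", "terminal_height"]]
corr = trait_correlation(ft_k, "FT", "terminal_height")
print()
print("per-environment Pearson correlation of FT with terminal height:")
print(corr.round(3).to_string())
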