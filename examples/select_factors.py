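"""Pool per-environment scans into a priority list and pick model factors.

Genetic factors: top-N loci per environment are pooled, ranked by their
minimum p-value across environments, thinned to >= 100 kb spacing per
chromosome, then admitted greedily subject to carrier counts >= 2 and
pairwise |r| < 0.5. Environmental factors: 10-day temperature-window means
are admitted chronologically under the same correlation cap.
"""
from gxegrowth import (
    accumulate_top_n,
    build_priority_list,
    environment_factor_table,
    gwas_scan,
    relationship_matrix,
    select_env_factors,
    select_g_factors,
    simulate_study,
)
from gxegrowth.simulate import FieldSite, SimScenario

scenario = SimScenario(
    n_cultivars=40,
    n_loci=400,
    n_chromosomes=8,
    fields=(
        FieldSite("MF", 31.8, {2019: (160, 200)}),
        FieldSite("TF", 38.5, {2019: (155, 195)}),
    ),
    test_fields=(),
)
study = simulate_study(scenario, seed=3)
G = study.genotypes
K = relationship_matrix(G)

scans = {
    env: gwas_scan(study.traits["FT"].env_series(env), G, K)
    for env in study.train_envs
}
candidates = accumulate_top_n(scans, n=25)
priority = build_priority_list(scans, candidates, distance_bp=100_000)
print(f"candidate pool (top-25 union over {len(scans)} environments): {len(candidates)} loci")
print(f"priority list after 100 kb spacing: {len(priority)} loci; leaders:")
print(priority[["chrom", "pos", "min_p"]].head(5).to_string())

g_factors = select_g_factors(priority, G, max_n=10, n_environments=len(scans))
print(f"\nselected genetic factors ({len(g_factors)}): {g_factors[:5]} ...")
causal = set(study.truths["FT"].causal_loci)
print(f"true causal loci recovered among them: {sorted(set(g_factors) & causal)}")

envf = environment_factor_table([study.environments[e] for e in study.train_envs])
windows = select_env_factors(envf)
print(f"\ntemperature windows passing the |r| < 0.5 chronological filter: {windows}")
print("these plus sowing day-of-year and latitude form the environmental factors.")
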