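"""Ground-truth generator: determinism, forced contrasts, exact recovery."""
import numpy as np
import pandas as pd
import pytest

from gxegrowth import (
    ModelSpec,
    TruthModel,
    build_design_matrix,
    fit_ols,
    simulate_environment,
    simulate_genotypes,
    simulate_traits,
)
from gxegrowth.simulate import SimScenario, TempModel, default_scenario, simulate_study

from conftest import constant_temp_env


class TestSimulateGenotypes:
    def test_deterministic_under_seed(self, small_scenario):
        a = simulate_genotypes(small_scenario, seed=7)
        b = simulate_genotypes(small_scenario, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.loci, b.loci)

    def test_forced_carrier_frequency(self):
        scen = SimScenario(n_cultivars=20, n_loci=50, n_chromosomes=2,
                           chrom_length_bp=10**6, maf_range=(0.5, 0.5))
        G = simulate_genotypes(scen, seed=1)
        assert (G.values.sum(axis=0) == 10).all()  # exactly n/2 carriers

    def test_carrier_counts_within_maf_bounds(self):
        scen = SimScenario(n_cultivars=20, n_loci=200, n_chromosomes=4,
                           chrom_length_bp=10**7, maf_range=(0.2, 0.4))
        counts = simulate_genotypes(scen, seed=3).values.sum(axis=0)
        assert counts.min() >= round(0.2 * 20)
        assert counts.max() <= round(0.4 * 20)

    def test_positions_unique_and_in_range(self, small_scenario):
        G = simulate_genotypes(small_scenario, seed=5)
        assert not G.loci.duplicated(subset=["chrom", "pos"]).any()
        assert G.loci["pos"].min() >= 1
        assert G.loci["pos"].max() <= small_scenario.chrom_length_bp

    def test_too_many_loci_errors(self):
        scen = SimScenario(n_cultivars=5, n_loci=100, n_chromosomes=1, chrom_length_bp=50)
        with pytest.raises(ValueError, match="unique positions"):
            simulate_genotypes(scen, seed=0)


class TestSimulateEnvironment:
    def test_degenerate_model_is_exactly_constant(self):
        tm = TempModel(mean=20.0, amplitude=0.0, noise_sd=0.0, lat_gradient=0.0, year_sd=0.0)
        env = simulate_environment("MF", 31.8, 2019, 160, tm, seed=1)
        np.testing.assert_array_equal(env.temperatures, 20.0)
        assert env.n_days >= 100

    def test_deterministic_under_seed(self):
        tm = TempModel()
        a = simulate_environment("TF", 38.5, 2019, 155, tm, seed=9)
        b = simulate_environment("TF", 38.5, 2019, 155, tm, seed=9)
        np.testing.assert_array_equal(a.temperatures, b.temperatures)

    def test_later_sowing_after_peak_is_cooler(self):
        # pure sinusoid peaking at the solstice; both sowings on the cooling
        # flank, so the analytic window mean decreases with sowing day
        tm = TempModel(mean=22.0, amplitude=10.0, phase_doy=172, noise_sd=0.0,
                       lat_gradient=0.0, year_sd=0.0)
        early = simulate_environment("MF", 35.0, 2019, 200, tm, seed=0)
        late = simulate_environment("MF", 35.0, 2019, 230, tm, seed=0)
        m_early = early.temperatures[:100].mean()
        m_late = late.temperatures[:100].mean()
        assert m_late < m_early
        for env, sow in ((early, 200), (late, 230)):
            doy = sow + np.arange(100)
            analytic = 22.0 + 10.0 * np.cos(2 * np.pi * (doy - 172) / 365.25)
            assert env.temperatures[:100].mean() == pytest.approx(analytic.mean(), abs=1e-12)


class TestSimulateTraits:
    def _two_envs(self, t0_a=20.0, t0_b=30.0):
        return [
            constant_temp_env("A-2019-160", t0_a, sowing_doy=160),
            constant_temp_env("B-2019-170", t0_b, sowing_doy=170),
        ]

    def _geno(self, small_scenario):
        return simulate_genotypes(small_scenario, seed=2)

    def test_constant_model(self, small_scenario):
        G = self._geno(small_scenario)
        truth = TruthModel((), {}, {}, {}, intercept=40.0, noise_sd=0.0)
        tt = simulate_traits(G, self._two_envs(), truth, n_replicates=2)
        assert (tt.records["value"] == 40.0).all()

    def test_single_locus_contrast_exact(self, small_scenario):
        G = self._geno(small_scenario)
        locus = G.locus_ids[0]
        truth = TruthModel((locus,), {locus: 5.0}, {}, {}, intercept=10.0, noise_sd=0.0)
        wide = simulate_traits(G, self._two_envs(), truth).wide()
        x = pd.Series(G.column(locus), index=G.cultivars)
        for env in wide.columns:
            diff = wide.loc[x == 1, env].mean() - wide.loc[x == 0, env].mean()
            assert diff == pytest.approx(5.0, abs=1e-12)

    def test_interaction_shifts_contrast_between_environments(self, small_scenario):
        G = self._geno(small_scenario)
        locus = G.locus_ids[0]
        truth = TruthModel(
            (locus,), {}, {}, {(locus, "T0"): 0.2}, intercept=0.0, noise_sd=0.0
        )
        wide = simulate_traits(G, self._two_envs(20.0, 30.0), truth).wide()
        x = pd.Series(G.column(locus), index=G.cultivars)
        contrasts = {
            env: wide.loc[x == 1, env].mean() - wide.loc[x == 0, env].mean()
            for env in wide.columns
        }
        vals = sorted(contrasts.values())
        assert vals[1] - vals[0] == pytest.approx(0.2 * 10.0, abs=1e-12)

    def test_gamma_referencing_unknown_factor_errors(self, small_scenario):
        G = self._geno(small_scenario)
        locus = G.locus_ids[0]
        truth = TruthModel((locus,), {}, {}, {(locus, "T999"): 0.1}, 0.0, 0.0)
        with pytest.raises(KeyError, match="T999"):
            simulate_traits(G, self._two_envs(), truth)

    def test_deterministic_and_replicate_average_exact(self, small_scenario):
        G = self._geno(small_scenario)
        locus = G.locus_ids[3]
        truth = TruthModel((locus,), {locus: 2.0}, {"T0": 0.1}, {}, 30.0, 1.5, seed=77)
        t1 = simulate_traits(G, self._two_envs(), truth, n_replicates=3)
        t2 = simulate_traits(G, self._two_envs(), truth, n_replicates=3)
        pd.testing.assert_frame_equal(t1.records, t2.records)
        avg = t1.averaged().set_index(["cultivar", "environment"])["value"]
        by_hand = t1.records.groupby(["cultivar", "environment"])["value"].apply(
            lambda v: float(np.mean(v.to_numpy()))
        )
        np.testing.assert_allclose(avg.to_numpy(), by_hand.to_numpy(), rtol=0, atol=0)


class TestEndToEndRecovery:
    def test_noise_free_pipeline_recovers_truth_exactly(self, small_scenario):
        # zero-noise generative model + OLS restricted to the causal loci
        # must reproduce every planted coefficient
        G = simulate_genotypes(small_scenario, seed=4)
        causal = tuple(G.locus_ids[:3])
        e_factors = ("T0", "T30", "sowing_doy", "latitude")
        truth = TruthModel(
            causal,
            {causal[0]: 6.0, causal[1]: -3.5, causal[2]: 2.0},
            {"T0": -0.7, "T30": 0.4, "sowing_doy": -0.05, "latitude": 1.1},
            {(causal[0], "T0"): -0.3, (causal[1], "latitude"): 0.25},
            intercept=42.0,
            noise_sd=0.0,
        )
        tm = TempModel()
        envs = []
        rng_seeds = range(8)
        for i, s in enumerate(rng_seeds):
            envs.append(
                simulate_environment("MF" if i < 4 else "TF", 31.8 if i < 4 else 38.5,
                                     2019, 150 + 10 * i, tm, seed=100 + s)
            )
        tt = simulate_traits(G, envs, truth, n_replicates=2)
        from gxegrowth.selection import environment_factor_table

        envf = environment_factor_table(envs)
        samples = tt.averaged().rename(columns={"value": "value"})
        spec = ModelSpec("FT", "G+E+GxE", causal, e_factors)
        X, labels = build_design_matrix(spec, G, envf, samples)
        fit = fit_ols(X, samples["value"].to_numpy(), labels, spec)
        assert fit.intercept == pytest.approx(42.0, abs=1e-6)
        for locus, a in truth.alpha.items():
            assert fit.coef[locus] == pytest.approx(a, abs=1e-6)
        for e, b in truth.beta.items():
            assert fit.coef[e] == pytest.approx(b, abs=1e-6)
        for (g, e), c in truth.gamma.items():
            assert fit.coef[f"{g}:{e}"] == pytest.approx(c, abs=1e-6)
        planted = {f"{g}:{e}" for g, e in truth.gamma}
        other_gamma = [
            f"{g}:{e}" for g in causal for e in e_factors if f"{g}:{e}" not in planted
        ]
        assert max(abs(fit.coef[c]) for c in other_gamma) < 1e-6


class TestSimulateStudy:
    def test_reproducible_and_well_shaped(self, small_scenario):
        s1 = simulate_study(small_scenario, seed=42)
        s2 = simulate_study(small_scenario, seed=42)
        np.testing.assert_array_equal(s1.genotypes.values, s2.genotypes.values)
        pd.testing.assert_frame_equal(s1.growth, s2.growth)
        for t in ("FT", "K", "r"):
            pd.testing.assert_frame_equal(s1.traits[t].records, s2.traits[t].records)
        assert len(s1.train_envs) == 4 and len(s1.test_envs) == 2
        # test environments only observe the designated cultivar subset
        test_rec = s1.traits["FT"].records.query("environment in @s1.test_envs")
        assert set(test_rec["cultivar"]) <= set(s1.test_cultivars())

    def test_default_scenario_shape(self):
        scen = default_scenario()
        assert scen.n_cultivars == 93
        assert len(scen.environment_designs("train")) == 8
        assert len(scen.environment_designs("test")) == 9
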