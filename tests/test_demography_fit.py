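"""Model registry, composite likelihood, AIC bookkeeping and conversions."""

import math

import numpy as np
import pytest

from popsplit.demography_fit import (
    SECONDARY_CONTACT_BEST_FIT,
    DemographicInference,
    FitSettings,
    ModelSpec,
    ParameterSet,
    build_model,
    compare_models,
    composite_log_likelihood,
    generations_to_years,
    get_model_spec,
    max_obs_lhood,
    model_registry,
    simulate_counts_jsfs,
)
from popsplit.sfs import JointSFS


class TestRegistry:
    def test_seven_specs(self):
        reg = model_registry()
        assert [s.id for s in reg] == ["M1", "M2", "M3", "M4", "M5", "M6", "M6r"]

    def test_si_models_share_k_and_no_migration(self):
        si = [s for s in model_registry() if s.scenario == "SI"]
        assert len(si) == 3
        assert len({s.k for s in si}) == 1
        for s in si:
            pset, _ = s.params_from_vector(
                np.array([np.mean(b[1:3]) for b in s.free_params])
            )
            assert pset.M01 == pset.M12 == pset.M13 == 0.0

    def test_migration_models_build_on_m3_topology(self):
        m3 = get_model_spec("M3")
        for mid in ("M4", "M5", "M6", "M6r"):
            assert get_model_spec(mid).joins == m3.joins

    def test_vector_round_trip(self):
        spec = get_model_spec("M6")
        x = spec.vector_from(SECONDARY_CONTACT_BEST_FIT.scaled(10))
        pset, _ = spec.params_from_vector(x)
        truth = SECONDARY_CONTACT_BEST_FIT.scaled(10)
        assert pset.T1 == pytest.approx(truth.T1, rel=1e-9)
        assert pset.N3 == pytest.approx(truth.N3, rel=1e-9)
        assert pset.M01 == pytest.approx(truth.M01, rel=1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ParameterSet(
                N_anc=1, N_stem=1, N_pair=1, N0=1, N1=1, N2=1, N3=1,
                T0=5, T1=10, T2=1,  # T0 < T1
            )

    def test_sc_degenerates_to_si_when_contact_vanishes(self):
        """SC with a negligible contact window reproduces the SI spectrum."""
        from scipy.stats import chisquare
        from popsplit.sfs import expected_jsfs
        from popsplit.coalescent_sim import SampleConfig
        import dataclasses

        truth = SECONDARY_CONTACT_BEST_FIT.scaled(10)
        sc_off = dataclasses.replace(truth, T3=truth.T1 * 1e-6)
        m6 = build_model(get_model_spec("M6"), sc_off)
        si = build_model(
            get_model_spec("M3"),
            dataclasses.replace(truth, M01=0, M10=0, M12=0, M21=0, T3=None),
        )
        cfg = SampleConfig((6, 6, 0, 0))
        # compare pop0-pop1 spectra: SC-with-no-window still has 1<->2 flow,
        # so give both models the same non-contact migration switched off
        m6_no12 = build_model(
            get_model_spec("M6"),
            dataclasses.replace(sc_off, M12=0, M21=0),
        )
        a = expected_jsfs(m6_no12, cfg, n_sims=3000, seed=4, pops=(0, 1))
        b = expected_jsfs(si, cfg, n_sims=3000, seed=11, pops=(0, 1))
        obs = a.cells[a.mask] * 3000
        exp = b.cells[b.mask] * 3000
        keep = exp > 5
        res = chisquare(obs[keep] / obs[keep].sum() * 100, exp[keep] / exp[keep].sum() * 100)
        assert res.pvalue > 0.01


def toy_sfs(cells, folded=False):
    return JointSFS(np.asarray(cells, dtype=float), folded=folded, kind="counts")


class TestCompositeLikelihood:
    def test_hand_arithmetic(self):
        # counts (3, 1) against probabilities (0.75, 0.25)
        obs = toy_sfs([[0.0, 3.0], [1.0, 0.0]])
        exp = JointSFS(
            np.array([[0.0, 0.75], [0.25, 0.0]]), folded=False, kind="proportions"
        )
        ll = composite_log_likelihood([obs], [exp])
        assert ll == pytest.approx(3 * math.log10(0.75) + math.log10(0.25), abs=1e-9)
        assert ll == pytest.approx(-0.976876, abs=1e-5)

    def test_max_obs_same_arithmetic(self):
        obs = toy_sfs([[0.0, 3.0], [1.0, 0.0]])
        assert max_obs_lhood([obs]) == pytest.approx(-0.976876, abs=1e-5)

    def test_saturated_fit_attains_bound(self):
        obs = toy_sfs([[0.0, 3.0], [1.0, 0.0]])
        exp = JointSFS(
            np.array([[0.0, 0.75], [0.25, 0.0]]), folded=False, kind="proportions"
        )
        assert composite_log_likelihood([obs], [exp]) == pytest.approx(
            max_obs_lhood([obs])
        )

    def test_gibbs_inequality(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 20, size=(4, 4)).astype(float)
            obs = toy_sfs(counts)
            p = rng.random((4, 4))
            mask = obs.mask
            p[~mask] = 0
            p[mask] /= p[mask].sum()
            exp = JointSFS(p, folded=False, kind="proportions")
            assert composite_log_likelihood([obs], [exp]) <= max_obs_lhood([obs]) + 1e-9

    def test_single_cell_mass_scores_zero(self):
        obs = toy_sfs([[0.0, 5.0], [0.0, 0.0]])
        assert max_obs_lhood([obs]) == 0.0

    def test_permutation_invariance(self):
        obs = toy_sfs([[0.0, 3.0], [1.0, 0.0]])
        swapped = toy_sfs([[0.0, 1.0], [3.0, 0.0]])
        assert max_obs_lhood([obs]) == pytest.approx(max_obs_lhood([swapped]))

    def test_empty_spectrum_rejected(self):
        obs = toy_sfs([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            max_obs_lhood([obs])

    def test_dimension_mismatch_rejected(self):
        obs = toy_sfs([[0.0, 3.0], [1.0, 0.0]])
        exp = JointSFS(np.full((3, 3), 1 / 7.0), folded=False, kind="proportions")
        with pytest.raises(ValueError):
            composite_log_likelihood([obs], [exp])


class TestCompareModels:
    def _result(self, model_id, k_override, ll):
        # minimal stand-in results via real fits would be slow; build the
        # frame through compare_models on lightweight namespace objects
        class R:
            def __init__(self, spec, ll):
                self.spec = spec
                self.max_est_lhood = ll
                self.max_obs_lhood = -5.0
                self.delta_l = self.max_obs_lhood - ll
                self.k = spec.k
                self.aic = 2 * spec.k - 2 * math.log(10) * ll

        return R(get_model_spec(model_id), ll)

    def test_tie_broken_by_fewer_parameters(self):
        a = self._result("M3", None, -100.0)  # k = 10
        b = self._result("M6", None, -100.0)  # k = 17
        table = compare_models([a, b])
        assert table["model"].iloc[0] == "M3"

    def test_aic_formula(self):
        r = self._result("M6", None, -1000.0)
        k = get_model_spec("M6").k
        assert r.aic == pytest.approx(2 * k + 2 * math.log(10) * 1000.0)

    def test_single_fit_table(self):
        table = compare_models([self._result("M3", None, -10.0)])
        assert len(table) == 1

    def test_mixed_observations_rejected(self):
        a = self._result("M3", None, -100.0)
        b = self._result("M6", None, -100.0)
        b.max_obs_lhood = -7.0
        with pytest.raises(ValueError):
            compare_models([a, b])


class TestFitMachinery:
    def test_split_time_recovery_by_likelihood_scan(self):
        """One-parameter self-consistency: scanning the pop0/pop1 divergence
        time recovers the generating value within a factor of two.

        (A panmictic size-only scan would be flat: with monomorphic cells
        masked, the polymorphism-conditioned SFS shape does not depend on N —
        divergence time is the natural identifiable one-parameter check.)
        """
        import dataclasses

        spec = get_model_spec("M3")
        N = 10_000.0
        base = ParameterSet(
            N_anc=N, N_stem=N, N_pair=N, N0=N, N1=N, N2=N, N3=N,
            T0=30_000.0, T1=5_000.0, T2=10.0,
        )
        sizes = (6, 6, 0, 0)
        obs = simulate_counts_jsfs(spec, base, sizes, n_snps=1000, seed=8)
        mdl = DemographicInference(obs, spec, sizes)
        grid = 10 ** np.linspace(2.7, 4.3, 9)  # stays below T0
        lls = []
        for t1 in grid:
            p = dataclasses.replace(base, T1=t1, T2=min(10.0, t1 / 2))
            lls.append(mdl.loglike(p, n_sims=1500, seed=3))
        best = grid[int(np.argmax(lls))]
        assert 2_500 <= best <= 10_000

    def test_fit_respects_gibbs_and_reports_runs(self):
        spec = get_model_spec("M3")
        pset = SECONDARY_CONTACT_BEST_FIT.scaled(10)
        sizes = (6, 6, 6, 6)
        obs = simulate_counts_jsfs(spec, pset, sizes, n_snps=400, seed=2)
        res = DemographicInference(obs, spec, sizes).fit(
            seed=5,
            settings=FitSettings(
                n_runs=2, sims_per_eval=120, ecm_cycles=1, line_evals=3
            ),
        )
        assert res.max_est_lhood <= res.max_obs_lhood
        assert len(res.runs) == 2
        assert res.aic == pytest.approx(
            2 * spec.k - 2 * math.log(10) * res.max_est_lhood
        )
        assert "T1" in res.free_values
        assert "MaxEstLhood" in res.summary()


class TestConversions:
    @pytest.mark.parametrize(
        "gens,kyr",
        [(23_802, 59.5), (9_120, 22.8), (4_213, 10.5), (3_214, 8.0), (0, 0.0)],
    )
    def test_generation_to_kyr(self, gens, kyr):
        years, got = generations_to_years(gens)
        assert got == kyr
        assert years == gens * 2.5

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            generations_to_years(-1)

    def test_scaling_preserves_drift_and_flow(self):
        p = SECONDARY_CONTACT_BEST_FIT
        s = p.scaled(10)
        assert s.T1 / s.N1 == pytest.approx(p.T1 / p.N1)
        assert s.N1 * s.M12 == pytest.approx(p.N1 * p.M12)
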