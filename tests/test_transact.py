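"""Trans-complementation forward model and hypothesis discrimination."""

import numpy as np
import pytest

from ire1_rnase import synthetic_data as sd
from ire1_rnase import transact as tr
from ire1_rnase.transact import (
    H1061N,
    H1061N_R1039A,
    WT,
    TransModelParams,
    TransTitrationData,
)


@pytest.fixture
def params():
    return TransModelParams()


class TestOrientations:
    def test_wild_type_dimer_both_productive(self, params):
        oris = tr.enumerate_orientations(WT, WT, "per_monomer", params)
        assert len(oris) == 2
        assert all(o.productive for o in oris)
        assert all(o.K == params.K_orient for o in oris)

    def test_dead_dimer_nothing_productive(self, params):
        oris = tr.enumerate_orientations(H1061N, H1061N, "per_monomer",
                                         params)
        assert not any(o.productive for o in oris)

    def test_heterodimer_single_productive_orientation(self, params):
        oris = tr.enumerate_orientations(WT, H1061N, "per_monomer", params)
        assert sum(o.productive for o in oris) == 1
        assert next(o for o in oris if o.productive).cleaving is WT

    def test_composite_kills_heterodimer(self, params):
        oris = tr.enumerate_orientations(WT, H1061N, "composite", params)
        assert not any(o.productive for o in oris)

    def test_trans_hle_penalty_on_productive_orientation(self, params):
        # the double mutant supplies a crippled HLE in trans to the
        # wild-type active site
        oris = tr.enumerate_orientations(WT, H1061N_R1039A, "per_monomer",
                                         params)
        prod = [o for o in oris if o.productive]
        assert len(prod) == 1
        assert prod[0].K == pytest.approx(params.K_orient * params.f_hle)

    def test_unknown_hypothesis_rejected(self, params):
        with pytest.raises(ValueError, match="unknown hypothesis"):
            tr.enumerate_orientations(WT, WT, "telepathic", params)


class TestForwardModel:
    def test_bounded_by_k2(self, params):
        grid = np.geomspace(0.01, 50.0, 30)
        for hyp in tr.HYPOTHESES:
            k = tr.simulate_titration(1.5, grid, H1061N, hyp,
                                      params).k_obs_values
            assert np.all(k >= 0.0) and np.all(k <= params.k2)

    def test_hypothesis_free_limit(self, params):
        values = {tr.predict_kobs(1.5, 0.0, hypothesis=h, params=params)
                  for h in tr.HYPOTHESES}
        assert len(values) == 1

    def test_interior_maximum_two_phase_shape(self, params):
        """Activation then inhibition: the published qualitative signature."""
        grid = np.geomspace(0.1, 15.0, 12)
        k = tr.simulate_titration(1.5, grid, H1061N, "per_monomer",
                                  params).k_obs_values
        peak = int(np.argmax(k))
        assert 0 < peak < k.size - 1
        assert k[peak] > tr.predict_kobs(1.5, 0.0, params=params)

    def test_dilute_wt_scaling_ratio(self):
        """Productive share scales as x (per-monomer) vs x^2 (composite)."""
        p = TransModelParams(beta=0.0)
        for x in (0.05, 0.01, 0.002):
            W = 1.0
            M = W * (1 - x) / x
            ratio = (tr.predict_kobs(W, M, hypothesis="per_monomer", params=p)
                     / tr.predict_kobs(W, M, hypothesis="composite", params=p))
            assert ratio == pytest.approx(1.0 / x, rel=0.01)

    def test_sequestration_monotonicity(self, params):
        """Extra non-productive binders strictly decrease the rate."""
        k_ref = tr.predict_kobs(1.5, 5.0, H1061N, "per_monomer", params)
        k_more = tr.predict_kobs(1.5, 10.0, H1061N, "per_monomer", params)
        assert k_more < k_ref

    def test_double_mutant_curve_below_single_mutant(self, params):
        # subsaturating wild-type anchor concentration (0.06 Km regime)
        grid = np.geomspace(0.1, 15.0, 12)
        single = tr.simulate_titration(0.3, grid, H1061N,
                                       "per_monomer_trans_hle", params)
        double = tr.simulate_titration(0.3, grid, H1061N_R1039A,
                                       "per_monomer_trans_hle", params)
        assert np.all(double.k_obs_values < single.k_obs_values)

    def test_penalty_free_limit_curves_identical(self):
        p = TransModelParams(f_hle=1.0)
        grid = np.geomspace(0.1, 15.0, 12)
        single = tr.simulate_titration(0.3, grid, H1061N,
                                       "per_monomer_trans_hle", p)
        double = tr.simulate_titration(0.3, grid, H1061N_R1039A,
                                       "per_monomer_trans_hle", p)
        np.testing.assert_allclose(single.k_obs_values,
                                   double.k_obs_values, rtol=1e-12)

    def test_grid_length_preserved(self, params):
        grid = np.linspace(0.0, 10.0, 7)
        out = tr.simulate_titration(1.5, grid, H1061N, "per_monomer", params)
        assert out.k_obs_values.size == 7


class TestStochasticOracle:
    @pytest.mark.parametrize("mut_conc", [0.5, 1.5, 3.0, 7.0, 15.0])
    def test_matches_closed_form_within_3_sigma(self, params, mut_conc):
        """Explicit pairing + tracer partitioning reproduces the rate law."""
        mean, se = tr.simulate_kobs_stochastic(
            1.5, mut_conc, H1061N, "per_monomer", params,
            n_monomers=1000, n_trials=100_000, seed=7)
        closed = tr.predict_kobs(1.5, mut_conc, H1061N, "per_monomer",
                                 params)
        assert abs(mean - closed) <= 3 * se


class TestDiscrimination:
    def test_recovers_generating_hypothesis_noiseless(self, params):
        for gen in ("per_monomer", "composite"):
            data, _ = sd.gen_trans_titration(
                gen, params=params, mutant_grid=tr.STUDY_GRID,
                noise=sd.NoiseModel(0.0, 0))
            res = tr.discriminate(data, base_params=params)
            assert res.verdict == gen

    def test_flat_noise_is_indeterminate(self, params):
        rng = np.random.default_rng(12)
        flat = TransTitrationData(
            1.5, tr.STUDY_GRID,
            np.abs(rng.normal(0.0, 0.02, tr.STUDY_GRID.size)))
        assert tr.discriminate(flat, base_params=params).verdict == \
            "indeterminate"

    def test_too_few_points_rejected(self, params):
        data = TransTitrationData(1.5, np.arange(1.0, 5.0),
                                  np.full(4, 0.01))
        with pytest.raises(ValueError, match="at least 6"):
            tr.discriminate(data, base_params=params)

    def test_reports_delta_aicc_for_all_candidates(self, params):
        data, _ = sd.gen_trans_titration(
            "per_monomer", params=params, mutant_grid=tr.STUDY_GRID,
            noise=sd.NoiseModel(0.02, 3))
        res = tr.discriminate(
            data, hypotheses=("per_monomer", "composite",
                              "per_monomer_trans_hle"),
            base_params=params)
        assert set(res.delta_aicc) == {"per_monomer", "composite",
                                       "per_monomer_trans_hle",
                                       "null_constant"}
        assert min(res.delta_aicc.values()) == 0.0

    @pytest.mark.parametrize("gen", ["per_monomer", "composite"])
    def test_recovery_rate_under_noise(self, gen):
        """Seeded 100-run study: the generating architecture is called
        back in at least 95 runs at the default noise level."""
        counts = tr.recovery_study(gen, n_seeds=100, sd=0.02, seed0=0)
        assert counts.get(gen, 0) >= 95
        wrong = sum(v for k, v in counts.items()
                    if k not in (gen, "indeterminate"))
        assert wrong == 0
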