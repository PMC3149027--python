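"""Curve-family fits: exponential, saturation, inhibition, Michaelis-Menten."""

import numpy as np
import pytest

from ire1_rnase import kinetics as kn
from ire1_rnase import synthetic_data as sd


class TestExponential:
    def test_noiseless_round_trip(self, design, noiseless):
        course, _ = sd.gen_time_course(0.10, 0.9, design, noiseless)
        fit = kn.fit_exponential(course)
        assert fit.converged
        assert fit.k_obs == pytest.approx(0.10, rel=1e-6)
        assert fit.endpoint == pytest.approx(0.9, rel=1e-6)

    def test_all_zero_signal_flagged(self):
        course = kn.TimeCourse(np.arange(5.0), np.zeros(5))
        fit = kn.fit_exponential(course)
        assert not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kn.fit_exponential(kn.TimeCourse([0.0, 1.0, 2.0],
                                             [0.0, 0.1, 0.2]))

    def test_time_unit_rescaling(self, design, noiseless):
        """Rates transform reciprocally with the time unit."""
        course, _ = sd.gen_time_course(0.10, 0.9, design, noiseless)
        k_s = kn.fit_exponential(course).k_obs
        in_minutes = kn.TimeCourse(course.times / 60.0, course.fractions)
        k_min = kn.fit_exponential(in_minutes).k_obs
        assert k_min == pytest.approx(60.0 * k_s, rel=1e-6)

    def test_monte_carlo_recovery_wild_type_rate(self, design):
        """Rate recovery at the wild-type plateau rate under gel noise."""
        k_hats = []
        for seed in range(100):
            course, _ = sd.gen_time_course(
                0.25, 0.9, design, sd.NoiseModel(0.02, seed))
            k_hats.append(kn.fit_exponential(course).k_obs)
        k_hats = np.asarray(k_hats)
        assert abs(np.median(k_hats) / 0.25 - 1.0) < 0.05
        assert np.sum(np.abs(k_hats / 0.25 - 1.0) < 0.15) >= 95


class TestTitration:
    def test_noiseless_round_trip(self, design, noiseless):
        prof, _ = sd.gen_titration(0.25, 1.0, design, noiseless)
        fit = kn.fit_titration(prof)
        assert fit.k2 == pytest.approx(0.25, rel=1e-6)
        assert fit.K_half == pytest.approx(1.0, rel=1e-6)
        assert fit.K_half_identifiable

    def test_plateau_only_design_flags_K_half(self, noiseless):
        # all enzyme concentrations at >= 50x K_half: only k2 is learnable
        design = sd.AssayDesign(enzyme_grid=np.linspace(50.0, 200.0, 8))
        prof, _ = sd.gen_titration(0.25, 1.0, design, sd.NoiseModel(0.01, 3))
        fit = kn.fit_titration(prof)
        assert fit.k2 == pytest.approx(0.25, rel=0.05)
        assert not fit.K_half_identifiable

    def test_point_order_invariance(self, design, noiseless):
        prof, _ = sd.gen_titration(0.25, 1.0, design, sd.NoiseModel(0.01, 7))
        fit = kn.fit_titration(prof)
        perm = np.random.default_rng(0).permutation(prof.enzyme_concs.size)
        shuffled = kn.TitrationProfile(prof.enzyme_concs[perm],
                                       prof.k_obs_values[perm])
        fit2 = kn.fit_titration(shuffled)
        assert fit2.k2 == pytest.approx(fit.k2, rel=1e-6)
        assert fit2.K_half == pytest.approx(fit.K_half, rel=1e-6)

    def test_monte_carlo_recovery_mutant_plateau(self, design):
        """k2 of the slow tyrosine-mutant regime recovered under noise."""
        k2_hats = []
        for seed in range(100):
            prof, _ = sd.gen_titration(0.022, 1.0, design,
                                       sd.NoiseModel(0.002, seed))
            k2_hats.append(kn.fit_titration(prof).k2)
        assert abs(np.median(k2_hats) / 0.022 - 1.0) < 0.10


class TestInhibition:
    @pytest.mark.parametrize("K_true", [5.0, 200.0])
    def test_noiseless_round_trip(self, design, noiseless, K_true):
        series, _ = sd.gen_inhibition(0.25, K_true, design, noiseless)
        fit = kn.fit_inhibition(series)
        assert fit.k0 == pytest.approx(0.25, rel=1e-6)
        assert fit.K == pytest.approx(K_true, rel=1e-6)

    def test_half_inhibition_identity(self, noiseless):
        series, _ = sd.gen_inhibition(
            0.2, 200.0,
            sd.AssayDesign(competitor_grid=np.array([0.0, 50.0, 200.0, 800.0])),
            noiseless)
        at_K = series.k_obs_values[series.competitor_concs == 200.0]
        assert at_K == pytest.approx(0.1)

    def test_weak_vs_cognate_binding_ratio(self, design, noiseless):
        """Single-stranded mimic binds ~40-fold weaker than the stem-loop."""
        cognate, _ = sd.gen_inhibition(0.25, 5.0, design, noiseless)
        mimic, _ = sd.gen_inhibition(0.25, 200.0, design, noiseless)
        ratio = kn.fit_inhibition(mimic).K / kn.fit_inhibition(cognate).K
        assert ratio == pytest.approx(40.0, rel=1e-6)

    def test_flat_series_gives_lower_bound(self, design, noiseless):
        flat = kn.InhibitionSeries(design.competitor_grid,
                                   np.full(design.competitor_grid.size, 0.25))
        fit = kn.fit_inhibition(flat)
        assert fit.K_is_lower_bound
        assert fit.K >= design.competitor_grid.max()

    def test_missing_zero_anchor_rejected(self):
        with pytest.raises(ValueError):
            kn.fit_inhibition(kn.InhibitionSeries(
                [50.0, 100.0, 200.0, 400.0], [0.2, 0.15, 0.1, 0.05]))


class TestMichaelis:
    def test_noiseless_round_trip(self):
        S = np.geomspace(0.5, 50.0, 10)
        v = kn.michaelis_menten(S, kcat_E0=1.0 * 3.0, Km=5.0)
        fit = kn.fit_michaelis(S, v, enzyme_conc=3.0)
        assert fit.kcat == pytest.approx(1.0, rel=1e-6)
        assert fit.Km_mt == pytest.approx(5.0, rel=1e-6)

    def test_half_saturation_identity(self):
        v = kn.michaelis_menten(np.array([5.0]), kcat_E0=2.0, Km=5.0)
        assert v[0] == pytest.approx(1.0)

    def test_sigma_interval_coverage(self, rng):
        """Asymptotic 1-sigma intervals cover the truth at a ~68% rate."""
        S = np.geomspace(0.5, 50.0, 12)
        covered = 0
        for _ in range(100):
            v = kn.michaelis_menten(S, 3.0, 5.0) + rng.normal(0, 0.05, S.size)
            fit = kn.fit_michaelis(S, v, enzyme_conc=3.0)
            err = fit.standard_errors.get("Km_mt")
            if err and abs(fit.Km_mt - 5.0) <= err:
                covered += 1
        assert 58 <= covered <= 78


class TestBiasInvariant:
    @pytest.mark.parametrize(
        "gen, fit, true, attr, sd_noise",
        [
            ("time_course", kn.fit_exponential, 0.25, "k_obs", 0.01),
            ("titration", kn.fit_titration, 0.25, "k2", 0.01),
            ("inhibition", kn.fit_inhibition, 5.0, "K", 0.01),
        ],
    )
    def test_small_noise_bias_below_2_percent(self, gen, fit, true, attr,
                                              sd_noise):
        design = sd.AssayDesign(
            time_grid=np.linspace(0.0, 60.0, 12),
            enzyme_grid=np.geomspace(0.1, 15.0, 12),
            competitor_grid=np.concatenate(([0.0],
                                            np.geomspace(0.5, 1000.0, 11))),
        )
        estimates = []
        for seed in range(100):
            noise = sd.NoiseModel(sd_noise, seed)
            if gen == "time_course":
                data, _ = sd.gen_time_course(true, 0.9, design, noise)
            elif gen == "titration":
                data, _ = sd.gen_titration(true, 1.0, design, noise)
            else:
                data, _ = sd.gen_inhibition(0.25, true, design, noise)
            estimates.append(getattr(fit(data), attr))
        assert abs(np.median(estimates) / true - 1.0) < 0.02
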