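"""Maxwell moduli, gel-point extraction, relaxation fits, stress simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from gelstrain import (
    DataError,
    DegenerateRelaxation,
    FrequencySweep,
    MaxwellMode,
    MaxwellSpectrum,
    MultipleCrossovers,
    NoCrossover,
    RelaxationCurve,
    complex_moduli,
    cycles_to_convergence,
    find_gel_point,
    fit_relaxation,
    generate_relaxation_curve,
    relaxation_modulus,
    sample_sweep,
    simulate_stress,
)


def brute_moduli(weights, taus, f):
    """Independent term-by-term evaluation of the Maxwell frequency response."""
    gp = gpp = 0.0
    for g, tau in zip(weights, taus):
        x = 2.0 * np.pi * f * tau
        gp += g * x * x / (1.0 + x * x)
        gpp += g * x / (1.0 + x * x)
    return gp, gpp


class TestComplexModuli:
    def test_single_mode_crossover_symmetry(self):
        spec = MaxwellSpectrum([MaxwellMode(1000.0, 1.0)])
        gp, gpp = complex_moduli(spec, [1.0 / (2.0 * np.pi)])
        assert gp[0] == pytest.approx(500.0, rel=1e-12)
        assert gpp[0] == pytest.approx(500.0, rel=1e-12)

    def test_high_frequency_limit(self):
        spec = MaxwellSpectrum([MaxwellMode(1000.0, 1.0)])
        gp, gpp = complex_moduli(spec, [1e6])
        assert gp[0] == pytest.approx(1000.0, rel=1e-6)
        assert gpp[0] == pytest.approx(0.0, abs=1e-2)

    def test_two_mode_against_term_sum(self, two_mode):
        gp, gpp = complex_moduli(two_mode, [0.1])
        egp, egpp = brute_moduli([600, 400], [1.0, 0.01], 0.1)
        assert gp[0] == pytest.approx(egp, rel=1e-12)
        assert gpp[0] == pytest.approx(egpp, rel=1e-12)

    def test_storage_increases_and_loss_tangent_decreases(self, single_mode):
        f = np.geomspace(0.01, 100, 200)
        gp, gpp = complex_moduli(single_mode, f)
        assert np.all(np.diff(gp) > 0)
        assert np.all(np.diff(gpp / gp) < 0)

    def test_nonpositive_frequency_rejected(self, single_mode):
        with pytest.raises(DataError):
            complex_moduli(single_mode, [0.0])


class TestRelaxationModulus:
    def test_initial_value_is_total_stiffness(self, two_mode):
        assert relaxation_modulus(two_mode, 0.0) == pytest.approx(1000.0, rel=1e-12)

    def test_single_mode_closed_form(self):
        spec = MaxwellSpectrum([MaxwellMode(800.0, 2.0)])
        assert relaxation_modulus(spec, 2.0) == pytest.approx(800.0 * np.exp(-1), rel=1e-12)

    def test_two_mode_against_term_sum(self, two_mode):
        expected = 600 * np.exp(-5.0 / 1.0) + 400 * np.exp(-5.0 / 0.01)
        assert relaxation_modulus(two_mode, 5.0) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing(self, two_mode):
        t = np.linspace(0, 10, 500)
        assert np.all(np.diff(relaxation_modulus(two_mode, t)) < 0)

    def test_negative_time_rejected(self, two_mode):
        with pytest.raises(DataError):
            relaxation_modulus(two_mode, -0.1)


class TestFindGelPoint:
    def test_single_mode_sampled_sweep(self, single_mode):
        sweep = sample_sweep(single_mode, 0.05, 20.0, 40)
        gp = find_gel_point(sweep)
        assert gp.frequency == pytest.approx(1.0, rel=1e-12)
        assert gp.modulus == pytest.approx(1000.0, rel=5e-3)

    def test_single_mode_dense_sweep_is_exact(self, single_mode):
        gp = find_gel_point(sample_sweep(single_mode, 0.05, 20.0, 5000))
        assert gp.frequency == pytest.approx(1.0, rel=1e-9)
        assert gp.modulus == pytest.approx(1000.0, rel=1e-6)

    def test_no_crossover_raises(self, single_mode):
        sweep = sample_sweep(single_mode, 2.0, 50.0, 20)  # G' > G'' throughout
        with pytest.raises(NoCrossover):
            find_gel_point(sweep)

    def test_multiple_crossovers_report_brackets(self):
        f = np.geomspace(0.01, 100, 400)
        # weights chosen so the fast loss hump re-crosses the slow plateau
        spec = MaxwellSpectrum([MaxwellMode(180.0, 0.5305), MaxwellMode(820.0, 0.0265)])
        gp, gpp = complex_moduli(spec, f)
        with pytest.raises(MultipleCrossovers) as err:
            find_gel_point(FrequencySweep(f, gp, gpp))
        assert len(err.value.brackets) == 3
        for lo, hi in err.value.brackets:
            assert lo < hi

    def test_two_mode_matches_dense_grid_oracle(self, two_mode):
        sweep = sample_sweep(two_mode, 0.01, 100.0, 3000)
        gp = find_gel_point(sweep)
        # brute force: sign change of G'-G'' on a 10^6-point grid
        f = np.geomspace(0.01, 100.0, 10**6)
        g1, g2 = complex_moduli(two_mode, f)
        i = int(np.flatnonzero(np.sign(g1 - g2)[:-1] != np.sign(g1 - g2)[1:])[0])
        assert gp.frequency == pytest.approx(f[i], rel=1e-5)
        assert gp.modulus == pytest.approx(g1[i], rel=1e-4)

    @pytest.mark.parametrize("seed", range(20))
    def test_randomized_agreement_with_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        tau = 10 ** rng.uniform(-2, 0.5)
        g0 = 10 ** rng.uniform(2, 4)
        spec = MaxwellSpectrum([MaxwellMode(g0, tau)])
        f_gp = 1.0 / (2 * np.pi * tau)
        gp = find_gel_point(sample_sweep(spec, f_gp / 20, f_gp * 20, 4000))
        assert gp.frequency == pytest.approx(f_gp, rel=1e-6)
        assert gp.modulus == pytest.approx(g0 / 2, rel=1e-6)


class TestFitRelaxation:
    def test_noiseless_two_mode_roundtrip(self, relax_spectrum):
        curve = generate_relaxation_curve(relax_spectrum, 50.0, 500, 0.0, 0)
        fit = fit_relaxation(curve, n_modes=2)
        assert fit.spectrum.times == pytest.approx([10.0, 0.5], rel=1e-6)
        assert fit.spectrum.weights == pytest.approx([800.0, 200.0], rel=1e-6)
        expected_char = (800 * 10 + 200 * 0.5) / 1000
        assert fit.characteristic_time == pytest.approx(expected_char, rel=1e-6)

    def test_roundtrip_rms_below_1e6_of_g0(self, relax_spectrum):
        curve = generate_relaxation_curve(relax_spectrum, 50.0, 500, 0.0, 0)
        fit = fit_relaxation(curve, n_modes=2)
        model = relaxation_modulus(fit.spectrum, curve.times)
        rms = np.sqrt(np.mean((model - curve.values) ** 2))
        assert rms < 1e-6 * relax_spectrum.total_stiffness

    def test_constant_curve_is_degenerate(self):
        curve = RelaxationCurve(np.linspace(0, 10, 50), np.full(50, 1000.0))
        with pytest.raises(DegenerateRelaxation):
            fit_relaxation(curve)

    def test_increasing_curve_is_degenerate(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(DegenerateRelaxation):
            fit_relaxation(RelaxationCurve(t, 100.0 + 10.0 * t))

    def test_one_percent_noise_recovers_times_within_5pct(self, relax_spectrum):
        curve = generate_relaxation_curve(relax_spectrum, 50.0, 500, 0.01, seed=42)
        fit = fit_relaxation(curve, n_modes=2)
        assert fit.spectrum.times == pytest.approx([10.0, 0.5], rel=0.05)

    def test_too_few_samples_rejected(self):
        t = np.linspace(0, 1, 4)
        with pytest.raises(DataError):
            fit_relaxation(RelaxationCurve(t, np.exp(-t) + 1e-3), n_modes=2)


class TestSimulateStress:
    def test_step_strain_reproduces_relaxation(self):
        spec = MaxwellSpectrum([MaxwellMode(1000.0, 1.0)])
        sigma = simulate_stress(spec, [0.0, 1.0], [0.1, 0.1])
        assert sigma[0] == pytest.approx(100.0, rel=1e-12)
        assert sigma[1] == pytest.approx(100.0 * np.exp(-1), rel=1e-9)

    def test_zero_strain_zero_stress(self, two_mode):
        t = np.linspace(0, 5, 100)
        assert np.all(simulate_stress(two_mode, t, np.zeros_like(t)) == 0.0)

    def test_linearity_in_amplitude(self, two_mode):
        t = np.linspace(0, 2, 400)
        eps = 0.05 * np.sin(2 * np.pi * 3 * t)
        s1 = simulate_stress(two_mode, t, eps)
        s2 = simulate_stress(two_mode, t, 2.0 * eps)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-9, abs=1e-9)

    def test_ramp_against_closed_form(self, two_mode):
        rate = 0.02
        t = np.linspace(0, 3, 3001)  # 10^3 samples per second
        sigma = simulate_stress(two_mode, t, rate * t)
        expected = rate * sum(
            g * tau * (1 - np.exp(-t / tau))
            for g, tau in zip([600, 400], [1.0, 0.01])
        )
        assert sigma[1:] == pytest.approx(expected[1:], rel=1e-4)

    @pytest.mark.parametrize("seed", range(20))
    def test_randomized_agreement_with_quadrature(self, seed):
        rng = np.random.default_rng(100 + seed)
        taus = 10 ** rng.uniform(-1.5, 0.5, 2)
        taus[1] = taus[0] * 10 ** rng.uniform(0.5, 1.5)  # keep them distinct
        weights = 10 ** rng.uniform(2, 3, 2)
        spec = MaxwellSpectrum([MaxwellMode(w, t) for w, t in zip(weights, taus)])
        freq = rng.uniform(0.5, 3.0)
        amp = rng.uniform(0.01, 0.3)
        t = np.linspace(0, 1.5, 1501)
        eps = amp * np.sin(2 * np.pi * freq * t)
        sigma = simulate_stress(spec, t, eps)

        def eps_rate(s):
            return amp * 2 * np.pi * freq * np.cos(2 * np.pi * freq * s)

        for t_check in (0.4, 1.1):
            expected = sum(
                quad(
                    lambda s, g=g, tau=tau: g * np.exp(-(t_check - s) / tau) * eps_rate(s),
                    0.0,
                    t_check,
                    limit=400,
                )[0]
                for g, tau in zip(weights, taus)
            )
            k = int(round(t_check * 1000))
            assert sigma[k] == pytest.approx(expected, rel=5e-4, abs=1e-6 * weights.sum())

    def test_unordered_times_rejected(self, two_mode):
        with pytest.raises(DataError):
            simulate_stress(two_mode, [0.0, 2.0, 1.0], [0.0, 0.1, 0.1])


class TestCyclesToConvergence:
    @staticmethod
    def _cyclic_stress(spec, freq, n_cycles, spc=200, amp=0.25, pre=0.75):
        t = np.arange(n_cycles * spc + 1) / (spc * freq)
        eps = pre + amp * 0.5 * (1 - np.cos(2 * np.pi * freq * t))
        return simulate_stress(spec, t, eps)[1:]

    def test_quasi_elastic_converges_at_cycle_two(self):
        spec = MaxwellSpectrum([MaxwellMode(1000.0, 1e9)])
        s = self._cyclic_stress(spec, 1.0, 5)
        res = cycles_to_convergence(s, 200, 1e-6)
        assert res.converged and res.cycle == 2

    def test_matches_independent_peak_extraction(self):
        spec = MaxwellSpectrum([MaxwellMode(1000.0, 1.0)])
        s = self._cyclic_stress(spec, 1.0, 40)
        res = cycles_to_convergence(s, 200, 0.01)
        # oracle: explicit per-cycle peak loop
        peaks = [np.abs(s[i * 200:(i + 1) * 200]).max() for i in range(40)]
        k = None
        for c in range(1, 40):
            if all(
                abs(peaks[j] - peaks[j - 1]) < 0.01 * peaks[j - 1] for j in range(c, 40)
            ):
                k = c + 1
                break
        assert res.converged and res.cycle == k

    def test_single_cycle_rejected(self):
        with pytest.raises(DataError):
            cycles_to_convergence(np.ones(150), 100, 0.01)

    def test_never_converged_flags_series_length(self):
        s = np.concatenate([np.full(10, p) for p in [1, 2, 4, 8, 16.0]])
        res = cycles_to_convergence(s, 10, 0.01)
        assert not res.converged and res.cycle == 5


class TestSpectrumValidation:
    def test_modes_sorted_slowest_first(self):
        spec = MaxwellSpectrum([MaxwellMode(1.0, 0.1), MaxwellMode(2.0, 5.0)])
        assert spec.times[0] == 5.0

    def test_duplicate_times_rejected(self):
        with pytest.raises(DataError):
            MaxwellSpectrum([MaxwellMode(1.0, 1.0), MaxwellMode(2.0, 1.0 + 1e-12)])

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(DataError):
            MaxwellMode(-1.0, 1.0)
        with pytest.raises(DataError):
            MaxwellMode(1.0, 0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    g0=st.floats(10.0, 1e5),
    tau=st.floats(1e-3, 1e2),
)
def test_single_mode_gel_point_property(g0, tau):
    """Any single-mode sweep crosses at (1/(2 pi tau), G0/2)."""
    spec = MaxwellSpectrum([MaxwellMode(g0, tau)])
    f_gp = 1.0 / (2 * np.pi * tau)
    gp = find_gel_point(sample_sweep(spec, f_gp / 20, f_gp * 20, 4000))
    assert gp.frequency == pytest.approx(f_gp, rel=1e-9)
    assert gp.modulus == pytest.approx(g0 / 2, rel=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 10**6))
def test_stress_homogeneity_property(scale, seed):
    """Stress is homogeneous of degree 1 in the strain history."""
    rng = np.random.default_rng(seed)
    spec = MaxwellSpectrum([MaxwellMode(500.0, 0.3), MaxwellMode(700.0, 2.0)])
    t = np.sort(rng.uniform(0, 4, 50))
    t = np.unique(t)
    eps = rng.normal(0, 0.1, len(t))
    s1 = simulate_stress(spec, t, eps)
    s2 = simulate_stress(spec, t, scale * eps)
    np.testing.assert_allclose(s2, scale * s1, rtol=1e-9, atol=1e-9)
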