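import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcoat import (
    binarize_phase,
    build_pattern_sequence,
    demodulate,
    make_transmission_matrix,
    precompute_segment_responses,
    plan_dither,
    run_exhaustive_oracle,
    run_fcoat,
    run_greedy_oracle,
)
from fcoat.fcoat_core import _sign_matrix, square_wave
from fcoat.forward_optics import linear_layout


class TestPlanDither:
    def test_n32_frequency_plan(self, layout32):
        plan = plan_dither(layout32)
        h1, h2 = plan.halves
        assert len(h1) == 406 and len(h2) == 406
        assert plan.samples_per_half == 1624
        assert plan.total_patterns == 3248
        for bins in plan.bins:
            assert bins.min() == 1624 // 4
            assert bins.max() == 811
            assert len(np.unique(bins)) == len(bins)

    def test_minimal_two_segments(self):
        plan = plan_dither(linear_layout(2))
        assert plan.samples_per_half == 4
        assert list(plan.bins[0]) == [1]
        assert list(plan.bins[1]) == [1]

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError):
            plan_dither(linear_layout(1))

    def test_random_scheme_partitions(self):
        plan = plan_dither(linear_layout(101), scheme="random", seed=3)
        h1, h2 = plan.halves
        assert abs(len(h1) - len(h2)) <= 1
        assert sorted(np.concatenate([h1, h2])) == list(range(101))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(m=st.integers(2, 300))
    def test_band_occupies_upper_octave(self, m):
        # the lowest modulation frequency is half the highest: bins fill
        # [T/4, T/4 + H) inside [T/4, T/2)
        plan = plan_dither(linear_layout(m))
        t = plan.samples_per_half
        h = max(len(plan.halves[0]), len(plan.halves[1]))
        assert t == 4 * h
        for half, bins in zip(plan.halves, plan.bins):
            assert len(bins) == len(half)
            assert bins.min() >= t // 4
            assert bins.max() < t // 2
        assert plan.total_patterns <= 4 * m + 4


class TestSquareWave:
    @pytest.mark.parametrize("k,t_n", [(1, 4), (7, 28), (101, 404), (203, 812)])
    def test_sign_change_count(self, k, t_n):
        s = square_wave(k, t_n)
        assert s[0] == 1.0  # start at base value
        changes = np.sum(s[1:] != s[:-1])
        # 2k zero crossings of cos over the record; sampling can merge the
        # final one with the wrap-around
        assert changes in (2 * k - 1, 2 * k)

    def test_fundamental_dominates_dft(self):
        t_n = 812
        for k in (203, 300, 405):
            s = square_wave(k, t_n)
            d = np.abs(np.fft.fft(s))
            assert d[k] >= 0.9 * t_n / np.pi  # square-wave fundamental 2T/pi


class TestPatternSequence:
    def test_sequence_start_and_holds(self):
        layout = linear_layout(10)
        plan = plan_dither(layout)
        base = np.where(np.arange(10) % 3 == 0, np.pi, 0.0)
        seq = build_pattern_sequence(plan, 0, base)
        assert seq.shape == (plan.samples_per_half, 10)
        np.testing.assert_array_equal(seq[0], base)  # t=0: all at base
        # unmodulated half holds the base phase throughout
        np.testing.assert_array_equal(
            seq[:, plan.halves[1]], np.tile(base[plan.halves[1]], (len(seq), 1)))
        assert set(np.unique(seq)) <= {0.0, np.pi}

    def test_modulated_segment_follows_its_square_wave(self):
        layout = linear_layout(8)
        plan = plan_dither(layout)
        seq = build_pattern_sequence(plan, 0, np.zeros(8))
        for j, seg in enumerate(plan.halves[0]):
            wave = square_wave(plan.bins[0][j], plan.samples_per_half)
            np.testing.assert_array_equal(
                seq[:, seg], np.where(wave > 0, 0.0, np.pi))


class TestBinarize:
    @pytest.mark.parametrize("phi,expected", [
        (0.3, 0.0), (1.6, np.pi), (5.5, 0.0),
        (0.0, 0.0), (np.pi, np.pi),
        (np.pi / 2, np.pi), (3 * np.pi / 2, 0.0),  # half-open boundaries
        (-0.3, 0.0), (7.0, 0.0),
    ])
    def test_stated_intervals(self, phi, expected):
        assert binarize_phase(phi) == expected

    def test_idempotent_on_binary_set(self):
        assert binarize_phase(binarize_phase(1.6)) == np.pi
        assert binarize_phase(binarize_phase(0.3)) == 0.0

    def test_even_symmetry_off_boundaries(self):
        phi = np.linspace(0.01, np.pi - 0.01, 10_000)
        np.testing.assert_array_equal(binarize_phase(phi), binarize_phase(-phi))


class TestDemodulate:
    def test_constant_input_no_signal(self):
        plan = plan_dither(linear_layout(8))
        dem = demodulate(np.ones(plan.samples_per_half), plan, 0)
        np.testing.assert_array_equal(dem.bits, 0.0)
        np.testing.assert_array_equal(dem.phases, 0.0)

    def test_ramp_mode_recovers_injected_phase(self):
        plan = plan_dither(linear_layout(8))
        t_n = plan.samples_per_half
        k = int(plan.bins[0][2])
        t = np.arange(t_n)
        intensity = 1.0 + np.cos(2 * np.pi * k * t / t_n + 0.3)
        dem = demodulate(intensity, plan, 0, mode="ramp")
        assert dem.phases[2] == pytest.approx(0.3, abs=1e-6)

    def test_length_mismatch_rejected(self):
        plan = plan_dither(linear_layout(8))
        with pytest.raises(ValueError):
            demodulate(np.ones(5), plan, 0)

    def test_sign_of_coefficient_tracks_cos_of_medium_phase(self):
        # one modulated segment against a fixed reference: the real part of
        # c * exp(-j psi) must carry sign(cos(delta_phi))
        plan = plan_dither(linear_layout(2))
        t_n = plan.samples_per_half
        wave = _sign_matrix(plan, 0)[:, 0]
        for dphi in np.linspace(-3.0, 3.0, 25):
            if abs(abs(dphi) - np.pi / 2) < 1e-6:
                continue
            a_i, a_r = 0.7 * np.exp(1j * dphi), 1.3
            intensity = np.abs(a_r + wave * a_i) ** 2
            dem = demodulate(intensity, plan, 0)
            val = np.real(dem.coeffs[0] * np.exp(-1j * dem.ref_phases[0]))
            assert np.sign(val) == np.sign(np.cos(dphi))

    def test_ramp_mode_full_phase_recovery_through_medium(self, config, pinhole):
        # continuous-dither validation: the recovered phase matches the true
        # medium-induced phase arg(E_i conj(E_ref)) before binarisation
        layout = linear_layout(208)
        medium = make_transmission_matrix(1024, 208, seed=5)
        basis = precompute_segment_responses(layout, medium, config, pinhole)
        plan = plan_dither(layout)
        t = np.arange(plan.samples_per_half)
        for half in (0, 1):
            idx, other = plan.halves[half], plan.halves[1 - half]
            e_ref = basis.e_static[0] + basis.e_seg[other, 0].sum()
            ramp = np.exp(2j * np.pi * np.outer(t, plan.bins[half])
                          / plan.samples_per_half)
            intensity = np.abs(e_ref + ramp @ basis.e_seg[idx, 0]) ** 2
            dem = demodulate(intensity, plan, half, mode="ramp")
            true = np.angle(basis.e_seg[idx, 0] * np.conj(e_ref))
            err = np.angle(np.exp(1j * (dem.phases - true)))
            assert np.sqrt(np.mean(err ** 2)) < 0.2


class TestRunFcoat:
    def test_toy_two_segments_reaches_global_optimum(self, config, pinhole):
        # medium with segment phases (0, pi-0.1): enumeration of all four
        # binary masks gives the optimum; fCOAT must reach its intensity
        layout = linear_layout(2)
        medium = make_transmission_matrix(1, 2, seed=0)
        medium.values[:] = [[np.exp(0j), np.exp(1j * (np.pi - 0.1))]]
        basis = precompute_segment_responses(layout, medium, config, pinhole)
        best = run_exhaustive_oracle(basis)
        res = run_fcoat(medium, layout, config, pinhole,
                        render=False, compute_pbr=False)
        assert res.intensity_after == pytest.approx(basis.detect(best), rel=1e-6)
        # (0, pi) and (pi, 0) are exactly degenerate (global pi offset)
        assert sorted(res.mask) == [0.0, np.pi]

    def test_identity_medium_needs_no_correction(self, config, pinhole):
        layout = linear_layout(64)
        medium = make_transmission_matrix(1, 64, seed=0)
        medium.values[:] = 1.0
        res = run_fcoat(medium, layout, config, pinhole,
                        render=False, compute_pbr=False)
        assert np.mean(res.mask == np.pi) < 0.05

    def test_measurement_count_equals_plan_budget(self, config, pinhole):
        layout = linear_layout(50)
        medium = make_transmission_matrix(64, 50, seed=1)
        res = run_fcoat(medium, layout, config, pinhole,
                        render=False, compute_pbr=False)
        plan = plan_dither(layout)
        assert res.n_measurements == plan.total_patterns

    def test_intensity_increases_on_every_static_seed(self, config, pinhole):
        layout = linear_layout(100)
        for seed in range(20):
            medium = make_transmission_matrix(256, 100, seed=seed)
            res = run_fcoat(medium, layout, config, pinhole,
                            render=False, compute_pbr=False)
            assert res.intensity_after > res.intensity_before

    def test_enhancement_scales_linearly_with_segments(self, config, pinhole):
        # binary-phase theory: corrected PBR ~ M/pi; crosstalk shaves a bit
        means = []
        m_values = [64, 256, 812]
        for m in m_values:
            vals = []
            for seed in range(10):
                medium = make_transmission_matrix(4096, m, seed=100 + seed)
                res = run_fcoat(medium, linear_layout(m), config, pinhole)
                vals.append(res.pbr_after)
            means.append(np.mean(vals))
        slope = np.polyfit(m_values, means, 1)[0]
        assert 0.25 <= slope <= 0.40

    def test_fcoat_reaches_most_of_greedy_intensity(self, config, layout32, pinhole):
        for seed in range(1, 6):
            medium = make_transmission_matrix(4096, layout32.m_active, seed=seed)
            basis = precompute_segment_responses(layout32, medium, config, pinhole)
            res = run_fcoat(medium, layout32, config, pinhole,
                            render=False, compute_pbr=False)
            greedy = basis.detect(run_greedy_oracle(basis))
            assert res.intensity_after >= 0.70 * greedy

    def test_dynamic_medium_decays_and_warns(self, config, pinhole):
        layout = linear_layout(40)
        medium = make_transmission_matrix(256, 40, seed=3, tau=1e-4)
        with pytest.warns(RuntimeWarning):
            run_fcoat(medium, layout, config, pinhole,
                      render=False, compute_pbr=False)

    def test_continuous_working_mode_recovers_decayed_focus(self, config, pinhole):
        layout = linear_layout(100)
        medium = make_transmission_matrix(256, 100, seed=11, tau=1e9)
        res = run_fcoat(medium, layout, config, pinhole,
                        render=False, compute_pbr=False)
        # medium partially decorrelates after the correction
        evolved = medium.copy()
        evolved.tau = 10.0
        from fcoat import evolve_medium
        evolved = evolve_medium(evolved, 5.0)
        basis = precompute_segment_responses(layout, evolved, config, pinhole)
        decayed = basis.detect(res.mask)
        assert decayed < res.intensity_after
        evolved.tau = 1e9  # hold still during the re-run
        res2 = run_fcoat(evolved, layout, config, pinhole,
                         initial_mask=res.mask, render=False, compute_pbr=False)
        assert res2.intensity_after >= decayed

    def test_initial_mask_validated(self, config, pinhole):
        layout = linear_layout(10)
        medium = make_transmission_matrix(16, 10, seed=0)
        with pytest.raises(ValueError):
            run_fcoat(medium, layout, config, pinhole,
                      initial_mask=np.full(10, 0.5))


class TestOracles:
    def test_greedy_within_one_percent_of_exhaustive(self, config, pinhole):
        for seed in range(5):
            layout = linear_layout(12)
            medium = make_transmission_matrix(64, 12, seed=seed)
            basis = precompute_segment_responses(layout, medium, config, pinhole)
            greedy = basis.detect(run_greedy_oracle(basis))
            best = basis.detect(run_exhaustive_oracle(basis))
            assert greedy >= 0.99 * best

    def test_greedy_on_identity_returns_zeros(self, config, pinhole):
        layout = linear_layout(8)
        medium = make_transmission_matrix(1, 8, seed=0)
        medium.values[:] = 1.0
        basis = precompute_segment_responses(layout, medium, config, pinhole)
        np.testing.assert_array_equal(run_greedy_oracle(basis), np.zeros(8))

    def test_exhaustive_rejects_large_m(self, config, pinhole):
        layout = linear_layout(20)
        medium = make_transmission_matrix(16, 20, seed=0)
        basis = precompute_segment_responses(layout, medium, config, pinhole)
        with pytest.raises(ValueError):
            run_exhaustive_oracle(basis)
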