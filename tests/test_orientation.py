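"""Length-weighted axial statistics and the von Mises fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filatrace import (DISPERSION_MAX_DEG, ParameterError, angle_histogram,
                       compute_orientation_stats, fit_axial_von_mises,
                       orientation_dispersion)

parts_strategy = st.lists(
    st.tuples(st.floats(-360, 360), st.floats(0.01, 100)),
    min_size=1, max_size=30)


class TestHistogram:
    def test_single_part_all_weight_in_first_bin(self):
        hist, edges = angle_histogram([0.0], [10.0], n_bins=18)
        assert hist[0] == pytest.approx(10.0)
        assert hist.sum() == pytest.approx(10.0)

    def test_axial_identification_mod_180(self):
        h1, _ = angle_histogram([10.0], [1.0], n_bins=18)
        h2, _ = angle_histogram([190.0], [1.0], n_bins=18)
        assert np.allclose(h1, h2)

    def test_four_equal_parts_uniform(self):
        hist, _ = angle_histogram([0, 45, 90, 135], [2, 2, 2, 2], n_bins=4)
        assert np.allclose(hist, 2.0)

    def test_weights_sum_to_total_length(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(0, 180, 50)
        lengths = rng.uniform(0.1, 5, 50)
        hist, _ = angle_histogram(angles, lengths)
        assert hist.sum() == pytest.approx(lengths.sum())

    def test_no_parts_all_zero(self):
        hist, _ = angle_histogram([], [], n_bins=10)
        assert hist.shape == (10,)
        assert hist.sum() == 0

    def test_too_few_bins_rejected(self):
        with pytest.raises(ParameterError):
            angle_histogram([0.0], [1.0], n_bins=1)


class TestVonMises:
    def test_perfect_alignment(self):
        mu, kappa, r = fit_axial_von_mises([30.0] * 10, [5.0] * 10)
        assert r == pytest.approx(1.0)
        assert mu == pytest.approx(30.0)
        assert kappa == 500.0  # capped sentinel for a degenerate resultant

    def test_uniform_four_angles_cancel(self):
        """0/45/90/135 double to 0/90/180/270: the resultant vanishes and
        the fit degenerates to the uniform density (kappa -> 0)."""
        mu, kappa, r = fit_axial_von_mises([0, 45, 90, 135], [1, 1, 1, 1])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert kappa == pytest.approx(0.0, abs=1e-11)

    def test_perpendicular_pair_cancels(self):
        _, _, r = fit_axial_von_mises([0.0, 90.0], [3.0, 3.0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_length_weighting_shifts_mu(self):
        mu, _, r = fit_axial_von_mises([0.0, 90.0], [10.0, 1e-9])
        assert mu == pytest.approx(0.0, abs=1e-6)
        assert r == pytest.approx(1.0, rel=1e-6)

    def test_zero_total_length_rejected(self):
        with pytest.raises(ParameterError):
            fit_axial_von_mises([10.0], [0.0])

    def test_kappa_consistent_with_scipy_a1(self):
        """A1(kappa_est) must map back to R, using scipy's Bessel
        functions as the independent reference for A1 = I1/I0."""
        from scipy.special import i0, i1
        for w in (0.1, 0.3, 0.8, 2.0, 6.0, 20.0):
            # parts at 0 and 45 deg double to orthogonal vectors, giving
            # a resultant R = sqrt(1 + w^2) / (1 + w) spanning (0.7, 1)
            _, kappa, r = fit_axial_von_mises([0.0, 45.0], [1.0, w])
            a1 = i1(kappa) / i0(kappa) if kappa > 0 else 0.0
            assert r == pytest.approx(np.hypot(1, w) / (1 + w), abs=1e-9)
            assert a1 == pytest.approx(r, abs=0.03)


class TestDispersion:
    def test_endpoints_match_printed_range(self):
        assert orientation_dispersion(1.0) == pytest.approx(0.0)
        assert round(orientation_dispersion(0.0), 2) == 28.65
        assert DISPERSION_MAX_DEG == pytest.approx(np.degrees(0.5))

    def test_midpoint_of_linear_map(self):
        assert round(orientation_dispersion(0.5), 2) == 14.32

    def test_strictly_decreasing_in_r(self):
        rs = np.linspace(0, 1, 11)
        ds = [orientation_dispersion(r) for r in rs]
        assert all(a > b for a, b in zip(ds[:-1], ds[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            orientation_dispersion(-0.01)
        with pytest.raises(ParameterError):
            orientation_dispersion(1.01)


class TestInvariances:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(parts=parts_strategy)
    def test_axial_invariance_add_180(self, parts):
        angles = np.array([a for a, _ in parts])
        lengths = np.array([w for _, w in parts])
        s1 = compute_orientation_stats(angles, lengths)
        s2 = compute_orientation_stats(angles + 180.0, lengths)
        dmu = (s1.mu_deg - s2.mu_deg) % 180.0
        assert min(dmu, 180.0 - dmu) == pytest.approx(0.0, abs=1e-6)
        assert s1.R == pytest.approx(s2.R, abs=1e-9)
        assert s1.dispersion_deg == pytest.approx(s2.dispersion_deg, abs=1e-6)
        assert np.allclose(s1.histogram, s2.histogram)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(parts=parts_strategy, delta=st.floats(-180, 180))
    def test_rotation_covariance(self, parts, delta):
        angles = np.array([a for a, _ in parts])
        lengths = np.array([w for _, w in parts])
        s1 = compute_orientation_stats(angles, lengths)
        s2 = compute_orientation_stats(angles + delta, lengths)
        assert s2.R == pytest.approx(s1.R, abs=1e-9)
        assert s2.kappa == pytest.approx(s1.kappa, rel=1e-6, abs=1e-9)
        assert s2.dispersion_deg == pytest.approx(s1.dispersion_deg, abs=1e-6)
        if s1.R > 1e-6:  # mu undefined at zero resultant
            diff = (s2.mu_deg - s1.mu_deg - delta) % 180.0
            assert min(diff, 180.0 - diff) == pytest.approx(0.0, abs=1e-5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(parts=parts_strategy)
    def test_weight_invariance_duplication(self, parts):
        angles = np.array([a for a, _ in parts])
        lengths = np.array([w for _, w in parts])
        s1 = compute_orientation_stats(angles, lengths)
        s2 = compute_orientation_stats(np.concatenate([angles, angles]),
                                       np.concatenate([lengths, lengths]) / 2)
        assert s2.mu_deg == pytest.approx(s1.mu_deg, abs=1e-6)
        assert s2.R == pytest.approx(s1.R, abs=1e-9)
        assert s2.kappa == pytest.approx(s1.kappa, rel=1e-6, abs=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(parts=parts_strategy)
    def test_dispersion_bounds(self, parts):
        angles = [a for a, _ in parts]
        lengths = [w for _, w in parts]
        _, _, r = fit_axial_von_mises(angles, lengths)
        d = orientation_dispersion(r)
        assert 0.0 <= d <= 28.6479 + 1e-9
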