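import numpy as np
import pytest
from scipy.stats import norm, spearmanr

import cortiq as cq
from cortiq.quantify import (_shift_profile, fit_and_subtract_reference,
                             integrate_cortical_signal, max_slope_position)
from cortiq.straighten import StraightenedCortex

from conftest import mean_cortex_profile, uniform_density, zero_density


def make_straightened(values, closed=True):
    return StraightenedCortex(np.asarray(values, float), 1.0, 1.0, closed)


def sigmoid_profile(center=24.5, width=2.0, lo=10.0, hi=100.0, n=50):
    j = np.arange(n, dtype=float)
    return lo + (hi - lo) * norm.cdf((j - center) / width)


# -- rolling average ------------------------------------------------------

def brute_force_rolling(values, window):
    """Direct circular-window mean over rows i-floor(w/2) .. i+ceil(w/2)-1."""
    n = len(values)
    out = np.empty_like(values)
    lo, hi = window // 2, window - window // 2
    for i in range(n):
        idx = np.arange(i - lo, i + hi) % n
        out[i] = values[idx].mean(axis=0)
    return out


class TestRollingAverage:
    def test_constant_matrix_unchanged(self):
        st = make_straightened(np.full((20, 50), 3.0))
        out = cq.rolling_average_along_cortex(st, 5)
        assert np.allclose(out.values, 3.0)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        st = make_straightened(rng.normal(size=(15, 50)))
        out = cq.rolling_average_along_cortex(st, 1)
        assert np.array_equal(out.values, st.values)

    def test_circular_impulse(self):
        values = np.zeros((10, 50))
        values[3] = 1.0
        out = cq.rolling_average_along_cortex(make_straightened(values), 5)
        hit = np.where(out.values[:, 0] > 0)[0]
        assert len(hit) == 5
        assert np.allclose(out.values[hit], 0.2)

    @pytest.mark.parametrize("window", [2, 5, 8, 13])
    def test_matches_brute_force_circular(self, window):
        rng = np.random.default_rng(window)
        values = rng.normal(size=(17, 12))
        out = cq.rolling_average_along_cortex(make_straightened(values), window)
        assert np.allclose(out.values, brute_force_rolling(values, window),
                           atol=1e-9)

    def test_open_arc_window_too_large(self):
        st = make_straightened(np.zeros((5, 50)), closed=False)
        with pytest.raises(ValueError, match="exceeds"):
            cq.rolling_average_along_cortex(st, 10)


# -- Savitzky-Golay -------------------------------------------------------

def brute_force_savgol(profile, window, order):
    """Fit a polynomial in each window, evaluate at the center point."""
    half = window // 2
    n = len(profile)
    out = np.empty(n)
    x = np.arange(window) - half
    for i in range(n):
        if i < half or i >= n - half:
            continue
        coeffs = np.polyfit(x, profile[i - half:i + half + 1], order)
        out[i] = np.polyval(coeffs, 0.0)
    return out


class TestSmoothProfile:
    def test_reproduces_cubic_polynomial(self):
        j = np.arange(50, dtype=float)
        cubic = 0.002 * j ** 3 - 0.1 * j ** 2 + j + 5
        out = cq.smooth_profile(cubic, 11, 3)
        assert np.allclose(out[5:-5], cubic[5:-5], atol=1e-9)

    def test_constant_unchanged(self):
        out = cq.smooth_profile(np.full(50, 4.2))
        assert np.allclose(out, 4.2)

    def test_noise_suppression_on_sigmoid(self):
        clean = sigmoid_profile()
        rng = np.random.default_rng(3)
        noisy = clean + rng.normal(0, 0.05 * 90, size=50)
        out = cq.smooth_profile(noisy)
        rms_in = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_out = np.sqrt(np.mean((out - clean) ** 2))
        assert rms_out <= 0.6 * rms_in

    @pytest.mark.parametrize("window,order", [(5, 2), (11, 3), (17, 4)])
    def test_matches_brute_force(self, window, order):
        rng = np.random.default_rng(window * order)
        profile = rng.normal(size=60)
        out = cq.smooth_profile(profile, window, order)
        ref = brute_force_savgol(profile, window, order)
        half = window // 2
        assert np.allclose(out[half:-half], ref[half:-half], atol=1e-9)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            cq.smooth_profile(np.zeros(50), sg_window=10, sg_order=3)
        with pytest.raises(ValueError):
            cq.smooth_profile(np.zeros(50), sg_window=3, sg_order=3)


# -- max-slope alignment --------------------------------------------------

def brute_force_best_integer_shift(profile, target):
    """Integer shift that brings the max forward difference closest to target."""
    best, best_dist = 0, np.inf
    for s in range(-10, 11):
        shifted = _shift_profile(profile, s)
        pos = np.argmax(np.diff(shifted)) + 0.5
        if abs(pos - target) < best_dist:
            best, best_dist = s, abs(pos - target)
    return best


class TestAlignToMaxSlope:
    def test_already_aligned_profile_untouched(self):
        p = sigmoid_profile(center=24.5)
        aligned, shift, flags = cq.align_to_max_slope(p)
        assert abs(shift) < 0.05
        assert np.allclose(aligned, p, atol=1e-6 * p.max())

    def test_integer_shift_family_collapses(self):
        """Sigmoids pre-shifted by integers collapse onto one curve."""
        family = np.array([sigmoid_profile(center=24.5 + k)
                           for k in range(-3, 4)])
        aligned, shifts, _ = cq.align_to_max_slope(family)
        expected = [brute_force_best_integer_shift(p, 24.5) for p in family]
        assert np.allclose(shifts, expected, atol=0.05)
        assert np.allclose(expected, [-k for k in range(-3, 4)])
        interior = aligned[:, 10:40]
        assert interior.std(axis=0).max() < 1e-3

    def test_half_pixel_shift_recovered(self):
        p = sigmoid_profile(center=25.0)  # 0.5 px interior of band center
        _, shift, _ = cq.align_to_max_slope(p)
        assert shift == pytest.approx(-0.5, abs=0.25)

    def test_flat_profile_flagged_and_passed_through(self):
        p = np.full(50, 2.0)
        aligned, shift, flags = cq.align_to_max_slope(p)
        assert flags == ["flat"]
        assert shift == 0.0
        assert np.array_equal(aligned, p)

    def test_max_slope_position_subpixel(self):
        p = sigmoid_profile(center=20.25, width=2.0)
        assert max_slope_position(p) == pytest.approx(20.25, abs=0.1)


# -- reference derivation and fitting ------------------------------------

class TestDeriveReference:
    def test_scale_invariance(self):
        p = sigmoid_profile()
        ref1 = cq.derive_reference_profile(np.array([p, 3 * p]))
        ref2 = cq.derive_reference_profile(p[None, :])
        assert np.allclose(ref1.intensities, ref2.intensities, atol=1e-9)

    def test_single_profile_normalized_copy(self):
        p = sigmoid_profile()
        ref = cq.derive_reference_profile(p[None, :])
        assert ref.intensities[-10:].mean() == pytest.approx(1.0, abs=1e-9)

    def test_noisy_copies_collapse(self):
        clean = sigmoid_profile()
        rng = np.random.default_rng(8)
        profiles = np.array([
            s * (clean + rng.normal(0, 0.05 * 90, 50))
            for s in rng.uniform(0.5, 2.0, size=20)])
        ref = cq.derive_reference_profile(profiles)
        target = clean / clean[-10:].mean()
        rms = np.sqrt(np.mean((ref.intensities - target) ** 2))
        assert rms < 0.02 * target.max()

    def test_flat_profiles_rejected(self):
        with pytest.raises(ValueError, match="rising edge"):
            cq.derive_reference_profile(np.full((2, 50), 5.0))


class TestFitAndSubtract:
    def test_pure_scaled_reference(self, analytic_reference):
        p = 2.0 * analytic_reference.intensities
        fit = fit_and_subtract_reference(p, analytic_reference)
        assert fit.scale == pytest.approx(2.0, abs=1e-3)
        assert abs(fit.shift) < 0.05
        assert np.abs(fit.residual).max() < 1e-3

    def test_zero_profile(self, analytic_reference):
        fit = fit_and_subtract_reference(np.zeros(50), analytic_reference)
        assert fit.scale == 0.0
        assert np.allclose(fit.residual, 0.0)

    def test_shifted_reference_plus_bump_recovered(self, analytic_reference):
        """Scale, shift and the residual bump all recovered from a composite."""
        j = np.arange(50, dtype=float)
        shifted = _shift_profile(analytic_reference.intensities, 1.2)
        bump = 0.3 * np.exp(-0.5 * ((j - 24.5) / 2.0) ** 2)
        p = 1.5 * shifted + bump
        fit = fit_and_subtract_reference(p, analytic_reference)
        assert fit.scale == pytest.approx(1.5, rel=0.02)
        assert fit.shift == pytest.approx(1.2, abs=0.2)
        mass = bump.sum()
        assert integrate_cortical_signal(fit, 10) == pytest.approx(mass, rel=0.05)

    def test_fixed_shift_skips_search(self, analytic_reference):
        p = 1.5 * _shift_profile(analytic_reference.intensities, 0.7)
        fit = fit_and_subtract_reference(p, analytic_reference, fixed_shift=0.7)
        assert fit.shift == 0.7
        assert fit.scale == pytest.approx(1.5, abs=1e-3)


class TestIntegrate:
    def test_zero_residual(self, analytic_reference):
        fit = fit_and_subtract_reference(np.zeros(50), analytic_reference)
        assert integrate_cortical_signal(fit) == 0.0

    def test_gaussian_bump_mass(self):
        j = np.arange(50, dtype=float)
        mass = 500.0
        bump = mass / (2 * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((j - 24.5) / 2.0) ** 2)
        fit = cq.ReferenceFit(scale=0, shift=0, residual=bump, sse=0)
        assert integrate_cortical_signal(fit, 10) == pytest.approx(mass, rel=0.01)

    def test_linearity_in_amplitude(self):
        j = np.arange(50, dtype=float)
        bump = np.exp(-0.5 * ((j - 24.5) / 2.0) ** 2)
        f1 = cq.ReferenceFit(scale=0, shift=0, residual=bump, sse=0)
        f2 = cq.ReferenceFit(scale=0, shift=0, residual=2 * bump, sse=0)
        i1, i2 = integrate_cortical_signal(f1), integrate_cortical_signal(f2)
        assert i2 == pytest.approx(2 * i1, rel=1e-6)

    def test_window_exceeding_band_rejected(self):
        fit = cq.ReferenceFit(scale=0, shift=0, residual=np.zeros(50), sse=0)
        with pytest.raises(ValueError, match="exceeds"):
            integrate_cortical_signal(fit, 30)


class TestNormalizeTrace:
    def test_identity_and_zero(self):
        out = cq.normalize_trace(np.array([5.0, 0.0]), 5.0)
        assert out[0] == 1.0 and out[1] == 0.0

    def test_scale_invariance(self):
        v = np.array([2.0, 4.0, 8.0])
        assert np.allclose(cq.normalize_trace(v, 4.0),
                           cq.normalize_trace(v / 2, 2.0))

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError):
            cq.normalize_trace(np.array([1.0]), 0.0)


# -- end-to-end movie quantification --------------------------------------

class TestQuantifyTimecourse:
    def test_accumulation_recovered(self, small_geometry, reference):
        tmpl = cq.KineticTemplate("accumulation",
                                  {"level": 200.0, "onset": 3.0, "offset": 12.0})
        base = cq.SyntheticGroundTruth(membrane_density=zero_density, seed=17)
        stack, contours, series = cq.generate_timecourse(
            small_geometry, tmpl, base, 12, 1.5, image_shape=(256, 256))
        trace = cq.quantify_timecourse(stack, contours, reference)
        truth = np.array([r["mean_density"] for r in series])
        rho, _ = spearmanr(trace.values[truth > 0], truth[truth > 0])
        assert rho > 0.95
        # maintenance-normalized plateau sits at 1
        assert trace.values[-1] == pytest.approx(1.0, abs=0.1)

    def test_cytoplasm_only_movie_rejected_signal(self, small_geometry,
                                                  reference):
        base = cq.SyntheticGroundTruth(membrane_density=zero_density, seed=19)
        stack, contours, _ = cq.generate_timecourse(
            small_geometry, cq.KineticTemplate("uniform", {"level": 0.0}),
            base, 4, 1.5, image_shape=(256, 256))
        # reference signal level: a uniform membrane at density 200
        img, c, _ = cq.generate_frame(
            small_geometry,
            cq.SyntheticGroundTruth(membrane_density=uniform_density(200),
                                    seed=20), (256, 256))
        ref_value, _, _ = cq.quantify_frame(img, c, reference)
        trace = cq.quantify_timecourse(stack, contours, reference,
                                       maintenance_measurement=ref_value)
        # the floor on a short small-geometry movie is set by registration
        # noise (few tenths of a pixel on the shared shift), far below any
        # real cortical signal
        assert np.nanmax(np.abs(trace.values)) < 0.12

    def test_contour_count_mismatch(self, reference):
        with pytest.raises(ValueError, match="one contour per frame"):
            cq.quantify_timecourse(np.zeros((3, 64, 64)), [None, None],
                                   reference)
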