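"""NPS estimator: ROI handling, 2D estimate, radial average, summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ctiq import (
    BlurModel,
    ImageStack,
    NoiseModel,
    PhantomGeometry,
    RoiLayout,
    Spectrum2D,
    cardinal_roi_layout,
    compute_nps_2d,
    extract_rois,
    generate_phantom_stack,
    noise_magnitude,
    noise_magnitude_reduction,
    nps_peak_frequency,
    peak_frequency_shift,
    radial_average,
)
from ctiq.nps import RadialSpectrum
from ctiq.errors import InputError, LayoutError, UndefinedPeakError

PIXEL = 200.0 / 512.0


class TestRoiExtraction:
    def test_roi_accounting_214_slices(self):
        """Four 100x100 ROIs per slice over 214 slices give 856 patches."""
        geo = PhantomGeometry(n_slices=214)
        stack = generate_phantom_stack(geo, BlurModel(sigma=0.4), NoiseModel(variance=25.0, seed=0))
        patches = extract_rois(stack, cardinal_roi_layout(geo))
        assert patches.shape == (856, 100, 100)

    def test_single_roi_is_the_subimage(self):
        data = np.arange(64 * 64, dtype=float).reshape(1, 64, 64)
        stack = ImageStack(data, PIXEL)
        layout = RoiLayout(roi_size=16, positions=((8, 4),))
        patches = extract_rois(stack, layout)
        assert patches.shape == (1, 16, 16)
        assert np.array_equal(patches[0], data[0, 4:20, 8:24])

    def test_roi_past_image_edge_rejected(self):
        stack = ImageStack(np.zeros((1, 64, 64)), PIXEL)
        layout = RoiLayout(roi_size=32, positions=((40, 40),))
        with pytest.raises(LayoutError):
            extract_rois(stack, layout)

    def test_roi_overlapping_insert_rejected(self):
        geo = PhantomGeometry(n_slices=1)
        stack = generate_phantom_stack(geo, BlurModel(sigma=0.4), NoiseModel(variance=0.0))
        layout = RoiLayout(roi_size=32, positions=((240, 240),))  # on the insert
        with pytest.raises(LayoutError):
            extract_rois(stack, layout)


class TestNps2d:
    def test_constant_patches_give_zero_spectrum(self):
        patches = [np.full((32, 32), 17.0)] * 4
        spectrum = compute_nps_2d(patches, PIXEL)
        assert np.allclose(spectrum.values, 0.0, atol=1e-18)

    def test_white_noise_level(self):
        """Flat spectrum at sigma^2 * dx * dy for white noise (Parseval)."""
        rng = np.random.default_rng(0)
        patches = rng.normal(0.0, 10.0, size=(400, 100, 100))
        spectrum = compute_nps_2d(patches, PIXEL)
        expected = 100.0 * PIXEL**2  # ~15.26 HU^2 mm^2
        assert spectrum.values.mean() == pytest.approx(expected, rel=0.03)

    def test_impulse_patch_parseval_identity(self):
        """2D integral equals the patch variance for a centered unit
        impulse (odd patch size puts it at the detrend basis center, where
        the plane fit removes exactly the mean)."""
        patch = np.zeros((99, 99))
        patch[49, 49] = 1.0
        spectrum = compute_nps_2d([patch], PIXEL)
        assert spectrum.integral() == pytest.approx(np.var(patch), rel=1e-10)

    def test_mixed_sizes_rejected(self):
        with pytest.raises(InputError):
            compute_nps_2d([np.zeros((16, 16)), np.zeros((32, 32))], PIXEL)

    def test_point_symmetry(self):
        rng = np.random.default_rng(1)
        spectrum = compute_nps_2d(rng.normal(size=(8, 32, 32)), PIXEL)
        v = spectrum.values[1:, 1:]  # drop the unpaired negative-Nyquist row/col
        assert np.allclose(v, v[::-1, ::-1], rtol=1e-10)

    def test_brute_force_dft_equivalence(self):
        """On 8x8 patches the FFT-based estimate equals a double-loop DFT."""
        rng = np.random.default_rng(2)
        patches = rng.normal(size=(3, 8, 8))
        spectrum = compute_nps_2d(patches, PIXEL)

        from ctiq.nps import _plane_detrend

        detrended = _plane_detrend(patches.copy())
        n = 8
        brute = np.zeros((n, n), dtype=complex)
        acc = np.zeros((n, n))
        for p in detrended:
            for u in range(n):
                for v in range(n):
                    s = 0.0j
                    for i in range(n):
                        for j in range(n):
                            s += p[i, j] * np.exp(-2j * np.pi * (u * i + v * j) / n)
                    brute[u, v] = s
            acc += np.abs(brute) ** 2
        expected = np.fft.fftshift(acc / len(patches)) * PIXEL**2 / n**2
        assert np.allclose(spectrum.values, expected, rtol=1e-9, atol=1e-12)

    def test_scale_equivariance(self):
        """Scaling images by k scales NPS by k^2 and keeps the peak."""
        geo = PhantomGeometry(image_size=96, insert_radius=8.0)
        noise = NoiseModel(kind="ramp_bandpass", variance=100.0, peak_frequency=0.35)
        rng = np.random.default_rng(3)
        from ctiq import shape_noise_field

        fields = np.stack([shape_noise_field(geo, noise, rng) for _ in range(100)])
        s1 = compute_nps_2d(fields, PIXEL)
        s2 = compute_nps_2d(3.0 * fields, PIXEL)
        assert np.allclose(s2.values, 9.0 * s1.values, rtol=1e-9)
        assert nps_peak_frequency(radial_average(s1)) == nps_peak_frequency(radial_average(s2))

    def test_rotation_invariance_of_radial_average(self):
        """Rotating the patch ensemble by 90 deg leaves the 1D NPS unchanged."""
        rng = np.random.default_rng(4)
        patches = rng.normal(size=(50, 64, 64))
        r1 = radial_average(compute_nps_2d(patches, PIXEL))
        r2 = radial_average(compute_nps_2d(np.rot90(patches, axes=(1, 2)), PIXEL))
        assert np.allclose(r1.values, r2.values, rtol=1e-9)


class TestRadialAverage:
    def test_isotropic_power_law_against_brute_force(self):
        """Radial average of |f|^2 equals a brute-force per-point binning
        oracle exactly, and tracks bin-center^2 away from the origin (the
        innermost annuli are lattice-sparse, so the agreement with the
        continuous value is only a few percent there)."""
        freqs = np.fft.fftshift(np.fft.fftfreq(100, d=PIXEL))
        fx, fy = np.meshgrid(freqs, freqs)
        spectrum = Spectrum2D(values=fx**2 + fy**2, freq_x=freqs, freq_y=freqs.copy())
        radial = radial_average(spectrum)
        bw = 1.0 / (100 * PIXEL)

        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for gx in freqs:
            for gy in freqs:
                k = round(float(np.hypot(gx, gy)) / bw)
                sums[k] = sums.get(k, 0.0) + gx * gx + gy * gy
                counts[k] = counts.get(k, 0) + 1
        oracle = np.array([sums[k] / counts[k] for k in sorted(counts)])
        assert np.allclose(radial.values, oracle, rtol=1e-12, atol=1e-15)

        sel = (radial.frequencies >= 4 * bw) & (radial.frequencies <= 1.28)
        assert np.allclose(radial.values[sel], radial.frequencies[sel] ** 2, rtol=0.06)

    def test_all_zero_input(self):
        freqs = np.fft.fftshift(np.fft.fftfreq(32, d=PIXEL))
        radial = radial_average(Spectrum2D(np.zeros((32, 32)), freqs, freqs.copy()))
        assert np.all(radial.values == 0.0)

    def test_bad_bin_width_rejected(self):
        freqs = np.fft.fftshift(np.fft.fftfreq(32, d=PIXEL))
        with pytest.raises(InputError):
            radial_average(Spectrum2D(np.zeros((32, 32)), freqs, freqs.copy()), bin_width=0.0)


class TestScalarSummaries:
    def _spectrum(self, values):
        values = np.asarray(values, dtype=float)
        return RadialSpectrum(frequencies=np.arange(len(values)) * 0.05, values=values)

    def test_peak_of_single_maximum(self):
        values = np.exp(-0.5 * ((np.arange(20) * 0.05 - 0.30) / 0.1) ** 2)
        assert nps_peak_frequency(self._spectrum(values)) == pytest.approx(0.30)

    def test_monotone_decreasing_peaks_at_first_nondc_bin(self):
        assert nps_peak_frequency(self._spectrum([10, 8, 6, 4, 2, 1])) == pytest.approx(0.05)

    def test_all_zero_spectrum_undefined(self):
        with pytest.raises(UndefinedPeakError):
            nps_peak_frequency(self._spectrum(np.zeros(8)))

    def test_magnitude_of_constant_spectrum(self):
        radial = self._spectrum(np.full(21, 5.0))  # constant 5 over [0, 1.0]
        assert noise_magnitude(radial) == pytest.approx(5.0 * 1.0)

    def test_magnitude_zero_for_zero_spectrum(self):
        assert noise_magnitude(self._spectrum(np.zeros(8))) == 0.0

    def test_magnitude_linear_in_variance(self):
        """Doubling simulator variance doubles the NPS magnitude."""
        geo = PhantomGeometry(image_size=96, insert_radius=8.0)
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(6)
        from ctiq import shape_noise_field

        def magnitude(var, rng):
            noise = NoiseModel(kind="ramp_bandpass", variance=var, peak_frequency=0.3)
            fields = [shape_noise_field(geo, noise, rng) for _ in range(150)]
            return noise_magnitude(radial_average(compute_nps_2d(fields, PIXEL)))

        m1 = magnitude(100.0, rng1)
        m2 = magnitude(200.0, rng2)
        assert m2 / m1 == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize(
        "f_a, f_b, expected",
        [(0.3, 0.3, 0.0), (0.441, 0.30, 47.0), (0.15, 0.30, -50.0)],
    )
    def test_peak_shift_arithmetic(self, f_a, f_b, expected):
        assert peak_frequency_shift(f_a, f_b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "m_a, m_b, expected",
        [(10.0, 10.0, 0.0), (9.1, 10.0, -9.0), (6.2, 10.0, -38.0)],
    )
    def test_magnitude_reduction_arithmetic(self, m_a, m_b, expected):
        assert noise_magnitude_reduction(m_a, m_b) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            peak_frequency_shift(0.3, 0.0)
        with pytest.raises(ZeroDivisionError):
            noise_magnitude_reduction(1.0, 0.0)

    @given(
        a=st.floats(min_value=1e-3, max_value=1e3),
        b=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_shift_is_relative_change(self, a, b):
        """shift(a, b) = 100*(a/b - 1); sign follows a - b, and the relation
        is generally asymmetric under argument swap."""
        s = peak_frequency_shift(a, b)
        assert s == pytest.approx(100.0 * (a / b - 1.0))
        assert (s > 0) == (a > b) or a == b
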