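"""Noise power spectrum estimation.

2D NPS is estimated from square background ROIs the standard way for CT:
each ROI is detrended with a least-squares plane (removing the slow
background inhomogeneity that would otherwise dominate the low frequencies),
discrete-Fourier-transformed, modulus-squared, and scaled by
(pixel area / pixel count); the ensemble average over ROIs is the estimate.
No apodization window is applied — after detrending this is standard CT-NPS
practice, and a window would bias the magnitude integral.

The 1D NPS is the radial average of the 2D estimate.  Two scalar summaries
are derived from it: the peak frequency (noise "texture") and the integral
under the curve (noise "magnitude"), plus the two relative comparison
statistics used to contrast a photon-counting against an energy-integrating
system:

    peak frequency shift      = 100 * (f_a - f_b) / f_b        [%]
    noise magnitude reduction = 100 * (m_a - m_b) / m_b        [%]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError, LayoutError, UndefinedPeakError
from .phantom import PhantomGeometry
from .stack import ImageStack

__all__ = [
    "RoiLayout",
    "Spectrum2D",
    "RadialSpectrum",
    "cardinal_roi_layout",
    "extract_rois",
    "compute_nps_2d",
    "radial_average",
    "nps_peak_frequency",
    "noise_magnitude",
    "peak_frequency_shift",
    "noise_magnitude_reduction",
]


@dataclass(frozen=True)
class RoiLayout:
    """Square ROI grid applied identically to every slice.

    ``positions`` are (x, y) top-left pixel coordinates.  ROIs must lie fully
    inside the image and, when the stack's metadata records an insert, fully
    outside it.
    """

    roi_size: int
    positions: tuple

    def __post_init__(self) -> None:
        if self.roi_size < 16:
            raise LayoutError("roi_size must be >= 16 pixels")
        if len(self.positions) == 0:
            raise LayoutError("layout needs at least one ROI position")
        object.__setattr__(self, "positions", tuple((int(x), int(y)) for x, y in self.positions))

    def validate(self, stack: ImageStack) -> None:
        ny, nx = stack.data.shape[1:]
        s = self.roi_size
        for x, y in self.positions:
            if x < 0 or y < 0 or x + s > nx or y + s > ny:
                raise LayoutError(f"ROI at ({x}, {y}) size {s} exceeds image bounds {nx}x{ny}")
        truth = stack.metadata.get("ground_truth", {})
        geo = truth.get("geometry")
        if geo:
            cx, cy = geo["insert_center"]
            r_px = geo["insert_radius"] / geo["pixel_spacing"]
            for x, y in self.positions:
                # distance from insert center to nearest point of the ROI box
                dx = max(x - cx, 0.0, cx - (x + s - 1))
                dy = max(y - cy, 0.0, cy - (y + s - 1))
                if np.hypot(dx, dy) <= r_px:
                    raise LayoutError(
                        f"ROI at ({x}, {y}) overlaps the insert (background ROIs only)"
                    )


def cardinal_roi_layout(geometry: PhantomGeometry, roi_size: int = 100) -> RoiLayout:
    """Four ROIs at the cardinal positions between insert and image edge."""
    cx, cy = geometry.insert_center
    r_px = geometry.insert_radius / geometry.pixel_spacing
    # midway between the insert edge and the image edge along each axis
    offset = (r_px + geometry.image_size / 2.0) / 2.0
    half = roi_size / 2.0
    centers = [
        (cx, cy - offset),
        (cx + offset, cy),
        (cx, cy + offset),
        (cx - offset, cy),
    ]
    positions = [(int(round(x - half)), int(round(y - half))) for x, y in centers]
    return RoiLayout(roi_size=roi_size, positions=tuple(positions))


def extract_rois(stack: ImageStack, layout: RoiLayout) -> np.ndarray:
    """All background patches, shape (n_slices * n_positions, s, s).

    Patches are ordered slice-major: all positions of slice 0, then slice 1...
    """
    layout.validate(stack)
    s = layout.roi_size
    patches = [
        stack.data[k, y : y + s, x : x + s]
        for k in range(stack.n_slices)
        for x, y in layout.positions
    ]
    return np.stack(patches)


@dataclass(frozen=True)
class Spectrum2D:
    """Ensemble-averaged 2D NPS on a zero-centered frequency grid.

    ``values`` are in HU^2 mm^2; ``freq_x``/``freq_y`` are the fftshifted
    frequency axes in mm^-1.
    """

    values: np.ndarray
    freq_x: np.ndarray
    freq_y: np.ndarray
    n_samples: int = 1

    @property
    def grid_spacing(self) -> float:
        return float(self.freq_x[1] - self.freq_x[0])

    def integral(self) -> float:
        """Riemann sum over the full frequency plane, in HU^2.

        For stationary noise this equals the pixel variance (Parseval).
        """
        return float(self.values.sum() * self.grid_spacing**2)


def _plane_detrend(patches: np.ndarray) -> np.ndarray:
    """Subtract the least-squares first-order 2D polynomial from each patch."""
    m, s, _ = patches.shape
    y, x = np.mgrid[0:s, 0:s]
    design = np.column_stack([np.ones(s * s), x.ravel() - (s - 1) / 2, y.ravel() - (s - 1) / 2])
    pinv = np.linalg.pinv(design)  # (3, s*s)
    flat = patches.reshape(m, s * s)
    coeffs = flat @ pinv.T
    return (flat - coeffs @ design.T).reshape(m, s, s)


def compute_nps_2d(patches: Sequence[np.ndarray] | np.ndarray, pixel_spacing: float) -> Spectrum2D:
    """ICRU-style 2D NPS: detrend, DFT, modulus-squared, scale by
    (pixel area / pixel count), average over the patch ensemble."""
    patches = list(np.asarray(p, dtype=float) for p in patches)
    if len(patches) == 0:
        raise InputError("need at least one patch")
    shape0 = patches[0].shape
    if any(p.shape != shape0 for p in patches) or len(shape0) != 2 or shape0[0] != shape0[1]:
        raise InputError("all patches must be square and of identical size")
    if pixel_spacing <= 0:
        raise InputError("pixel_spacing must be positive")
    arr = _plane_detrend(np.stack(patches))
    s = shape0[0]
    power = np.abs(np.fft.fft2(arr)) ** 2
    scale = pixel_spacing**2 / (s * s)
    values = np.fft.fftshift(power.mean(axis=0)) * scale
    freqs = np.fft.fftshift(np.fft.fftfreq(s, d=pixel_spacing))
    return Spectrum2D(values=values, freq_x=freqs, freq_y=freqs.copy(), n_samples=len(patches))


@dataclass(frozen=True)
class RadialSpectrum:
    """1D radially averaged spectrum: frequency (mm^-1) -> power (HU^2 mm^2)."""

    frequencies: np.ndarray
    values: np.ndarray
    n_samples: int = 1

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if f.shape != v.shape or f.ndim != 1:
            raise InputError("frequencies and values must be matching 1D arrays")
        if len(f) > 1 and np.any(np.diff(f) <= 0):
            raise InputError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)


def radial_average(spectrum: Spectrum2D, bin_width: float | None = None) -> RadialSpectrum:
    """Average 2D samples in annular frequency bins.

    Bin k is centered at k * bin_width (edges at (k +/- 0.5) * bin_width), so
    the DC sample falls in the bin centered at zero.  Empty bins are dropped.
    ``bin_width`` defaults to the 2D grid's frequency sample spacing.
    """
    if bin_width is None:
        bin_width = spectrum.grid_spacing
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    fx, fy = np.meshgrid(spectrum.freq_x, spectrum.freq_y, indexing="xy")
    fmag = np.hypot(fx, fy).ravel()
    idx = np.round(fmag / bin_width).astype(int)
    counts = np.bincount(idx)
    sums = np.bincount(idx, weights=spectrum.values.ravel())
    nonempty = counts > 0
    centers = np.arange(len(counts)) * bin_width
    return RadialSpectrum(
        frequencies=centers[nonempty],
        values=sums[nonempty] / counts[nonempty],
        n_samples=spectrum.n_samples,
    )


def nps_peak_frequency(nps: RadialSpectrum, smooth_bins: int = 3) -> float:
    """Frequency of maximum smoothed amplitude, excluding the DC bin.

    A short moving-average smoother suppresses per-bin estimator noise; ties
    break toward the lower frequency.  Near-zero frequency content (large-
    scale inhomogeneity) is excluded from the search.
    """
    if len(nps.frequencies) < 5:
        raise InputError("need at least 5 radial bins")
    values = np.asarray(nps.values, dtype=float)
    if np.all(values == 0):
        raise UndefinedPeakError("peak frequency undefined for all-zero spectrum")
    kernel = np.ones(smooth_bins)
    smoothed = np.convolve(values, kernel, mode="same") / np.convolve(
        np.ones_like(values), kernel, mode="same"
    )
    keep = nps.frequencies > 0
    freqs = nps.frequencies[keep]
    smoothed = smoothed[keep]
    return float(freqs[int(np.argmax(smoothed))])


def noise_magnitude(nps: RadialSpectrum) -> float:
    """Trapezoidal integral of the 1D radial NPS from first to last bin."""
    if len(nps.frequencies) < 2:
        raise InputError("need at least 2 bins to integrate")
    return float(np.trapezoid(nps.values, nps.frequencies))


def peak_frequency_shift(f_pcd: float, f_eid: float) -> float:
    """Signed NPS-peak shift of system a relative to system b, in percent.

    Positive means the first system's noise texture peaks at a higher
    frequency (finer noise grain).
    """
    if f_eid <= 0:
        raise ZeroDivisionError("reference peak frequency must be > 0")
    return 100.0 * (f_pcd - f_eid) / f_eid


def noise_magnitude_reduction(m_pcd: float, m_eid: float) -> float:
    """Signed relative noise-magnitude difference in percent; negative means
    the first system is less noisy."""
    if m_eid <= 0:
        raise ZeroDivisionError("reference noise magnitude must be > 0")
    return 100.0 * (m_pcd - m_eid) / m_eid
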