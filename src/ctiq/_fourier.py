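"""Shared Fourier-domain primitives.

Radial disk transform and frequency-domain noise coloring are needed by both
the phantom simulator and the model-observer Monte-Carlo oracle, so they live
here rather than in either module.
"""

from __future__ import annotations

import numpy as np
from scipy.special import j1

__all__ = ["disk_ft", "freq_magnitude_grid", "colored_noise", "nps_filter_gain"]


def disk_ft(radius: float, f):
    """2D Fourier magnitude of a uniform disk of ``radius`` mm at radial
    frequency ``f`` (mm^-1): (r/f) * J1(2*pi*r*f), with the analytic limit
    pi*r^2 at f = 0.  Units: mm^2.
    """
    f = np.asarray(f, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    small = np.abs(f) < 1e-12
    fs = np.where(small, 1.0, f)
    out = np.where(small, np.pi * radius**2, (radius / fs) * j1(2.0 * np.pi * radius * fs))
    return float(out[0]) if scalar else out


def freq_magnitude_grid(n: int, pixel_spacing: float) -> np.ndarray:
    """|f| on the unshifted n x n DFT grid, in mm^-1."""
    f = np.fft.fftfreq(n, d=pixel_spacing)
    fx, fy = np.meshgrid(f, f, indexing="xy")
    return np.hypot(fx, fy)


def nps_filter_gain(power: np.ndarray, pixel_spacing: float) -> np.ndarray:
    """DFT filter gain |H| whose output noise has the given 2D NPS.

    With unit-variance white input w, the field ifft2(fft2(w) * H) has
    NPS = dx*dy*|H|^2, so |H| = sqrt(P / (dx*dy)).
    """
    return np.sqrt(np.clip(power, 0.0, None) / pixel_spacing**2)


def colored_noise(rng: np.random.Generator, shape, filter_gain: np.ndarray) -> np.ndarray:
    """Stationary Gaussian field(s) with NPS dx*dy*|filter_gain|^2.

    ``shape`` may be (n, n) or (batch, n, n); the filter acts on the last two
    axes.  The output is exactly real (circular convolution of real white
    noise with a real, point-symmetric kernel).
    """
    w = rng.standard_normal(shape)
    return np.real(np.fft.ifft2(np.fft.fft2(w) * filter_gain))
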