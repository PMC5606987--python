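"""Image-quality and pattern-frequency metrics.

Two metrics drive the autofocus: the mean squared error between the
measured and commanded modulation frequency of the patterned sheet
(cheap, robust to defocus direction), and the Shannon entropy of the
discrete cosine transform (SE-DCT) of the uniform image, which is
maximal at best focus and is used for the fine search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import dctn, rfft, rfftfreq
from scipy.ndimage import median_filter


class NoModulationError(ValueError):
    """The image contains no detectable periodic modulation."""


@dataclass(frozen=True)
class ModulationEstimate:
    """Dominant spatial frequency of a structured image.

    ``prominence`` is the peak magnitude over the median non-DC
    magnitude — a dimensionless line-to-background ratio that separates
    a genuine pattern lock from a random noise peak."""

    frequency_cyc_per_px: float
    power: float
    mse_vs_known: float | None = None
    prominence: float = np.inf

    def __post_init__(self) -> None:
        if not 0.0 < self.frequency_cyc_per_px <= 0.5:
            raise ValueError("frequency must lie in (0, 0.5] cycles/pixel")


def estimate_modulation_frequency(structured_image: np.ndarray, axis: int = 1,
                                  known_frequency: float | None = None,
                                  band: tuple[float, float] | None = None
                                  ) -> ModulationEstimate:
    """Estimate the modulation frequency of a patterned image.

    The image is summed along the non-modulated axis into a 1-D profile,
    the mean is removed and the dominant non-DC bin of its discrete
    Fourier transform is located.  Three-point parabolic interpolation
    of the log-magnitude around the peak gives sub-bin precision.

    ``band`` optionally restricts the peak search to a frequency window
    (cycles/pixel) — used when the commanded pattern frequency is known
    and strong specimen structure could otherwise dominate the spectrum.
    The prominence is always referenced to the full non-DC spectrum.

    Raises :class:`NoModulationError` if no non-DC component rises above
    the numerical floor (an all-constant image).
    """
    img = np.asarray(structured_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if img.shape[axis] < 8:
        raise ValueError("need at least 8 pixels along the modulated axis")
    profile = img.sum(axis=1 - axis)
    profile = profile - profile.mean()
    n = profile.size
    if np.allclose(profile, 0.0, atol=1e-9 * max(1.0, float(np.abs(img).max())) * n):
        raise NoModulationError("no modulation detected: constant profile")
    spec = np.abs(rfft(profile))
    freqs = rfftfreq(n)
    spec[0] = 0.0
    searchable = spec.copy()
    if band is not None:
        searchable[(freqs < band[0]) | (freqs > band[1])] = 0.0
    p = int(np.argmax(searchable))
    if searchable[p] <= 0.0:
        raise NoModulationError("no modulation detected: empty spectrum")
    # Parabolic refinement on log magnitude (exact for a Gaussian-shaped peak).
    if 1 <= p - 1 and p + 1 < spec.size and spec[p - 1] > 0 and spec[p + 1] > 0:
        lm, l0, lp = np.log(spec[p - 1]), np.log(spec[p]), np.log(spec[p + 1])
        denom = lm - 2.0 * l0 + lp
        delta = 0.0 if denom == 0 else 0.5 * (lm - lp) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    freq = float((p + delta) / n)
    freq = min(max(freq, freqs[1] * 0.5), 0.5)
    mse = None if known_frequency is None else (freq - known_frequency) ** 2
    med = float(np.median(spec[1:]))
    prom = float(spec[p] / med) if med > 0 else np.inf
    return ModulationEstimate(frequency_cyc_per_px=freq,
                              power=float(spec[p]), mse_vs_known=mse,
                              prominence=prom)


def modulation_mse(estimate: ModulationEstimate | float,
                   known_frequency: float) -> float:
    """Squared error of the estimated frequency against the commanded one."""
    f_hat = (estimate.frequency_cyc_per_px
             if isinstance(estimate, ModulationEstimate) else float(estimate))
    for f in (f_hat, known_frequency):
        if not 0.0 < f <= 0.5:
            raise ValueError("frequencies must lie in (0, 0.5] cycles/pixel")
    return (f_hat - known_frequency) ** 2


def se_dct(image: np.ndarray, median_size: int = 3,
           lowpass_radius_frac: float | None = None) -> float:
    """Shannon entropy (bits) of the normalized DCT magnitude spectrum.

    A minimal median filter (default 3x3) suppresses shot noise, then the
    orthonormal type-II DCT is taken and its absolute coefficients are
    normalized to a probability vector whose entropy is returned.  Sharp
    images spread energy over many coefficients and score higher;
    defocused images concentrate energy near DC and score lower.  An
    optional radial cutoff (``lowpass_radius_frac`` of ``min(shape)`` in
    coefficient index) discards the highest frequencies first.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValueError("expected a 2D image of at least 8x8 pixels")
    if median_size and median_size > 1:
        img = median_filter(img, size=median_size, mode="reflect")
    coeffs = dctn(img, type=2, norm="ortho")
    if lowpass_radius_frac is not None:
        i = np.arange(coeffs.shape[0])[:, None]
        j = np.arange(coeffs.shape[1])[None, :]
        keep = np.hypot(i, j) <= lowpass_radius_frac * min(coeffs.shape)
        mags = np.abs(coeffs[keep])
    else:
        mags = np.abs(coeffs).ravel()
    total = mags.sum()
    if total <= 0.0:
        return 0.0
    p = mags / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def brightness(image: np.ndarray) -> float:
    """Mean pixel intensity."""
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    return float(img.mean())


@dataclass
class FocusMetricSeries:
    """Metric values over an ordered sweep of candidate focus offsets."""

    offsets_um: np.ndarray
    mse_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    sedct_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    brightness_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.offsets_um = np.asarray(self.offsets_um, dtype=float)
        if np.any(np.diff(self.offsets_um) <= 0):
            raise ValueError("candidate offsets must be strictly increasing")
        n = self.offsets_um.size
        for name in ("mse_values", "sedct_values", "brightness_values"):
            v = getattr(self, name)
            if v is None:
                setattr(self, name, np.full(n, np.nan))
            else:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset_um": self.offsets_um,
            "mse": self.mse_values,
            "sedct": self.sedct_values,
            "brightness": self.brightness_values,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
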