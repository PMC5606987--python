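"""HiLo structured-illumination reconstruction.

HiLo combines two exposures of the same plane — one with uniform
illumination (U) and one with a sinusoidal pattern (S) — into an
optically sectioned image.  A partially demodulated image

    D(x) = |U(x) - 2 S(x)|

isolates in-focus content (only in-focus emission retains the pattern;
out-of-focus haze averages it out), and the reconstruction fuses its
low-frequency part with the high-frequency part of the uniform image:

    I_HiLo = eta * LP(D) + HP(U)

where LP is a Gaussian low-pass, HP its exact complement
(HP = identity - LP, same kernel) and eta the fusion weight, theoretically
pi / (2 M) for modulation depth M (the mean of |cos| being 2/pi).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from cdslm.metrics import brightness, estimate_modulation_frequency, se_dct
from cdslm.scope import DomainError


@dataclass
class ReconstructionPair:
    """Co-registered uniform image U and structured image S for one plane."""

    uniform: np.ndarray
    structured: np.ndarray
    modulation_frequency: float  # cycles/pixel along x

    def __post_init__(self) -> None:
        self.uniform = np.asarray(self.uniform, dtype=np.float64)
        self.structured = np.asarray(self.structured, dtype=np.float64)
        if self.uniform.shape != self.structured.shape:
            raise DomainError("uniform and structured images must share a shape")
        if not 0.0 < self.modulation_frequency <= 0.5:
            raise DomainError("modulation frequency must lie in (0, 0.5]")


@dataclass(frozen=True)
class HiLoParams:
    """Fusion parameters: eta weight, LP/HP crossover, modulation depth."""

    eta: float
    cutoff_frequency: float      # cycles/pixel; half-power point of LP
    modulation_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise DomainError("eta must be non-negative")
        if not 0.0 < self.cutoff_frequency <= 0.5:
            raise DomainError("cutoff frequency must lie in (0, 0.5]")
        if not 0.0 < self.modulation_amplitude <= 1.0:
            raise DomainError("modulation amplitude must lie in (0, 1]")

    @classmethod
    def for_pair(cls, pair: ReconstructionPair, eta: float | None = None,
                 modulation_amplitude: float = 1.0) -> "HiLoParams":
        """Standard defaults: cutoff at half the pattern frequency and,
        unless given, the theoretical eta = pi / (2 M)."""
        if eta is None:
            eta = eta_theoretical(modulation_amplitude)
        return cls(eta=eta, cutoff_frequency=0.5 * pair.modulation_frequency,
                   modulation_amplitude=modulation_amplitude)


def lp_sigma_px(cutoff_frequency: float) -> float:
    """Gaussian sigma (pixels) whose transfer function is 1/2 at the cutoff:
    sigma = sqrt(2 ln 2) / (2 pi f_c)."""
    return math.sqrt(2.0 * math.log(2.0)) / (2.0 * math.pi * cutoff_frequency)


def demodulate(pair: ReconstructionPair) -> np.ndarray:
    """Partially demodulated image D = |U - 2 S|, pixelwise non-negative."""
    return np.abs(pair.uniform - 2.0 * pair.structured)


def hilo_reconstruct(pair: ReconstructionPair,
                     params: HiLoParams) -> np.ndarray:
    """Fuse one uniform/structured pair into an optically sectioned image.

    Returns the unclamped float image
    ``eta * LP(D) + (U - LP(U))`` with reflective border handling.
    """
    if params.cutoff_frequency >= pair.modulation_frequency:
        warnings.warn("LP cutoff at or above the modulation frequency: "
                      "demodulated signal leaks into the HP band",
                      RuntimeWarning, stacklevel=2)
    sigma = lp_sigma_px(params.cutoff_frequency)
    d_lp = gaussian_filter(demodulate(pair), sigma, mode="reflect")
    u_lp = gaussian_filter(pair.uniform, sigma, mode="reflect")
    return params.eta * d_lp + (pair.uniform - u_lp)


def eta_theoretical(modulation_amplitude: float) -> float:
    """Theoretical fusion weight eta = pi / (2 M)."""
    if modulation_amplitude <= 0:
        raise DomainError("modulation amplitude must be positive")
    return math.pi / (2.0 * modulation_amplitude)


def default_eta_grid(n: int = 16) -> np.ndarray:
    """Log-spaced eta candidates spanning [pi/16, 4 pi]."""
    return np.geomspace(math.pi / 16.0, 4.0 * math.pi, n)


def auto_eta(pair_subset, candidate_etas=None,
             params: HiLoParams | None = None) -> float:
    """Automatic eta selection on a stack subset.

    Each candidate eta reconstructs every pair in the subset; candidates
    are scored by the product of the min-max-normalized mean SE-DCT and
    mean brightness (a scalarization of "simultaneously maximizing
    SE-DCT and brightness").  Ties go to the smaller eta.
    """
    pairs = list(pair_subset)
    if not pairs:
        raise DomainError("need at least one reconstruction pair")
    etas = np.sort(np.asarray(
        default_eta_grid() if candidate_etas is None else candidate_etas,
        dtype=float))
    if etas.size == 1:
        return float(etas[0])
    base = params or HiLoParams.for_pair(pairs[0])

    sed = np.empty(etas.size)
    bri = np.empty(etas.size)
    any_signal = False
    for i, eta in enumerate(etas):
        p = HiLoParams(eta=float(eta), cutoff_frequency=base.cutoff_frequency,
                       modulation_amplitude=base.modulation_amplitude)
        recons = [hilo_reconstruct(pr, p) for pr in pairs]
        if any(np.any(r) for r in recons):
            any_signal = True
        sed[i] = float(np.mean([se_dct(r) for r in recons]))
        bri[i] = float(np.mean([brightness(r) for r in recons]))
    if not any_signal:
        raise DomainError("all reconstructions are identically zero")

    def _norm(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        return np.ones_like(v) if span == 0 else (v - v.min()) / span

    score = _norm(sed) * _norm(bri)
    best = score.max()
    tied = etas[score == best]
    return float(tied.min())


def hilo_stack(stack_pairs, params: HiLoParams | None = None) -> np.ndarray:
    """Reconstruct a whole stack of uniform/structured pairs.

    If ``params`` is omitted, the modulation frequency is estimated once
    from the first structured plane and standard defaults are used.
    Per-plane failures are re-raised with the plane index attached.
    """
    pairs = list(stack_pairs)
    if not pairs:
        raise DomainError("empty stack")
    if params is None:
        est = estimate_modulation_frequency(pairs[0].structured)
        first = ReconstructionPair(pairs[0].uniform, pairs[0].structured,
                                   est.frequency_cyc_per_px)
        params = HiLoParams.for_pair(first)
    out = []
    for i, pr in enumerate(pairs):
        try:
            out.append(hilo_reconstruct(pr, params))
        except Exception as exc:
            raise RuntimeError(f"HiLo reconstruction failed at plane {i}: {exc}"
                               ) from exc
    return np.stack(out)
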