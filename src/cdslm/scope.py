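"""Virtual light-sheet microscope.

Forward model for a digital scanned light-sheet microscope imaging an
optically cleared specimen whose refractive index differs from the one
the detection optics were designed for.  The model captures exactly the
physics the C-DSLM method corrects and exploits:

* a Gaussian-beam light-sheet whose thickness grows away from the beam
  waist (``w(z) = w0 * sqrt(1 + (z/z_R)**2)``),
* sinusoidal intensity modulation of the sheet along the propagation
  axis (the HiLo pattern),
* first-order defocus: the detection focal plane for emission from depth
  ``z`` is displaced by the accumulated index mismatch
  ``integral_0^z (n(z') - n_imm) dz'``,
* defocus-dependent Gaussian blur in the detection plane, and
* Poisson photon noise followed by Gaussian read noise.

No diffraction PSF, scattering or photobleaching is modelled; first-order
defocus is the only aberration, which is the regime the calibration and
autofocus algorithms address.

Axis convention: stacks and volumes are indexed ``(z, y, x)`` with ``z``
the axial (sheet-stepping) axis and ``x`` the sheet propagation /
modulation axis.  All physical quantities are in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate
from scipy.ndimage import gaussian_filter

_FWHM_TO_W = math.sqrt(2.0 * math.log(2.0))  # w0 = FWHM / sqrt(2 ln 2)
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class DomainError(ValueError):
    """Raised when a query lies outside a model's physical domain."""


@dataclass
class SpecimenVolume:
    """A 3D fluorophore-density grid with voxel geometry.

    ``density`` is indexed ``(z, y, x)`` in arbitrary fluorophore units;
    ``voxel_size_um`` is ``(x, y, z)``; ``origin_um`` is the physical
    coordinate of voxel ``(0, 0, 0)``.
    """

    density: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.density.ndim != 3:
            raise DomainError("density must be a 3D (z, y, x) array")
        if np.any(self.density < 0):
            raise DomainError("fluorophore density must be non-negative")
        if any(v <= 0 for v in self.voxel_size_um):
            raise DomainError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    @property
    def z_coords_um(self) -> np.ndarray:
        """Physical z coordinate of each slice."""
        nz = self.density.shape[0]
        return self.origin_um[2] + np.arange(nz) * self.voxel_size_um[2]

    @property
    def x_coords_um(self) -> np.ndarray:
        nx = self.density.shape[2]
        return self.origin_um[0] + np.arange(nx) * self.voxel_size_um[0]


@dataclass(frozen=True)
class LightSheetModel:
    """Gaussian-beam light-sheet with optional sinusoidal modulation.

    The waist radius follows the usual convention
    ``w0 = waist_fwhm_um / sqrt(2 ln 2)`` and the Rayleigh length is
    ``z_R = pi * n * w0**2 / lambda``.  ``modulation_amplitude`` is the
    HiLo pattern depth M in [0, 1]; ``tilt_rad`` tilts the sheet entrance
    angle (shadow mitigation), realised as a linear displacement of the
    sheet centre across the propagation axis.
    """

    wavelength_um: float = 0.488
    waist_fwhm_um: float = 10.0
    refractive_index_medium: float = 1.45
    modulation_amplitude: float = 1.0
    modulation_period_um: float = 16.0
    modulation_phase_rad: float = 0.0
    tilt_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0 or self.waist_fwhm_um <= 0:
            raise DomainError("wavelength and waist FWHM must be positive")
        if not 0.0 <= self.modulation_amplitude <= 1.0:
            raise DomainError("modulation amplitude M must lie in [0, 1]")
        if self.modulation_period_um <= 0:
            raise DomainError("modulation period must be positive")

    @property
    def waist_w0_um(self) -> float:
        return self.waist_fwhm_um / _FWHM_TO_W

    @property
    def rayleigh_length_um(self) -> float:
        w0 = self.waist_w0_um
        return math.pi * self.refractive_index_medium * w0 * w0 / self.wavelength_um


@dataclass(frozen=True)
class RefractiveIndexProfile:
    """Axial refractive-index profile of the specimen + immersion path.

    ``n_of_z`` maps depth (um, measured from the specimen surface at
    z = 0) to the local index; ``n_immersion`` is the index the detection
    optics assume.  ``breakpoints`` lists discontinuities of ``n_of_z``
    so the defocus integral can honour them.
    """

    n_immersion: float
    n_of_z: Callable[[float], float]
    z_min_um: float = 0.0
    z_max_um: float = 1e4
    breakpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 1.0 <= self.n_immersion <= 1.6:
            raise DomainError("immersion index outside plausible range [1.0, 1.6]")

    @classmethod
    def homogeneous(cls, n: float, n_immersion: float = 1.0,
                    z_max_um: float = 1e4) -> "RefractiveIndexProfile":
        """Uniform specimen index; the paper-style n * dz accumulation."""
        return cls(n_immersion=n_immersion, n_of_z=lambda z: n, z_max_um=z_max_um)

    @classmethod
    def matched(cls, n: float = 1.45, z_max_um: float = 1e4) -> "RefractiveIndexProfile":
        """Index-matched medium: zero defocus at every depth."""
        return cls.homogeneous(n, n_immersion=n, z_max_um=z_max_um)

    @classmethod
    def piecewise_constant(cls, boundaries_um: Sequence[float],
                           indices: Sequence[float], n_immersion: float = 1.0,
                           z_max_um: float | None = None) -> "RefractiveIndexProfile":
        """Layered medium: ``indices[i]`` applies for
        ``boundaries_um[i] <= z < boundaries_um[i+1]`` (last layer open)."""
        bounds = np.asarray(boundaries_um, dtype=float)
        vals = np.asarray(indices, dtype=float)
        if bounds.size != vals.size or bounds.size == 0:
            raise DomainError("need one index per layer boundary")
        if np.any(np.diff(bounds) <= 0):
            raise DomainError("layer boundaries must be strictly increasing")

        def n_of_z(z: float) -> float:
            i = int(np.searchsorted(bounds, z, side="right")) - 1
            return float(vals[max(i, 0)])

        zmax = z_max_um if z_max_um is not None else 1e4
        return cls(n_immersion=n_immersion, n_of_z=n_of_z,
                   z_min_um=float(bounds[0]), z_max_um=zmax,
                   breakpoints=tuple(bounds[1:]))


def sheet_width(model: LightSheetModel, axial_dist_um) -> np.ndarray | float:
    """Intensity FWHM of the sheet at distance ``axial_dist_um`` from the waist.

    Gaussian-beam divergence: ``w(z) = w0 sqrt(1 + (z/z_R)^2)``; the
    FWHM scales identically.  Symmetric in the distance.
    """
    z = np.abs(np.asarray(axial_dist_um, dtype=float))
    out = model.waist_fwhm_um * np.sqrt(1.0 + (z / model.rayleigh_length_um) ** 2)
    return out if out.ndim else float(out)


def required_focus_offset(profile: RefractiveIndexProfile, depth_um: float) -> float:
    """First-order defocus at ``depth_um``: the detection-focus displacement
    needed to keep emission from that depth in focus.

    Computed as the accumulated index mismatch
    ``integral_0^depth (n(z') - n_immersion) dz'``, which reduces to
    ``(n - n_imm) * depth`` in homogeneous media and vanishes when the
    medium matches the immersion index.
    """
    depth = float(depth_um)
    if not profile.z_min_um <= depth <= profile.z_max_um:
        raise DomainError(
            f"depth {depth} um outside profile domain "
            f"[{profile.z_min_um}, {profile.z_max_um}]")
    if depth == 0.0:
        return 0.0
    pts = [b for b in profile.breakpoints if 0.0 < b < depth]
    val, _ = integrate.quad(
        lambda z: profile.n_of_z(z) - profile.n_immersion, 0.0, depth,
        points=pts or None, limit=200)
    return float(val)


@dataclass(frozen=True)
class DetectionModel:
    """Wide-field detection arm: pixel grid, in-focus blur and depth of field."""

    depth_of_field_um: float = 10.0
    base_blur_sigma_um: float = 1.0
    pixel_size_um: float = 1.0
    image_shape: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if min(self.depth_of_field_um, self.base_blur_sigma_um,
               self.pixel_size_um) <= 0:
            raise DomainError("detection model parameters must be positive")


def blur_sigma(det: DetectionModel, focal_mismatch_um) -> np.ndarray | float:
    """Lateral Gaussian blur (um) for emission defocused by ``focal_mismatch_um``.

    ``sigma(m) = sqrt(sigma0^2 + (sigma0 * |m| / DOF)^2)``: in focus the
    blur is the base value; at one depth of field it has grown by
    ``sqrt(2)``; beyond that it grows linearly with the mismatch.
    """
    m = np.asarray(focal_mismatch_um, dtype=float)
    s0 = det.base_blur_sigma_um
    k = s0 / det.depth_of_field_um
    out = np.sqrt(s0 * s0 + (k * np.abs(m)) ** 2)
    return out if out.ndim else float(out)


@dataclass
class AcquisitionRecord:
    """One simulated plane: uniform/structured pair plus ground truth."""

    uniform: np.ndarray
    structured: np.ndarray
    sheet_z_um: float
    applied_focus_offset_um: float
    true_focus_offset_um: float
    seed: int | None
    modulation_frequency: float  # cycles / pixel along x

    @property
    def pair(self):
        from cdslm.hilo import ReconstructionPair
        return ReconstructionPair(uniform=self.uniform,
                                  structured=self.structured,
                                  modulation_frequency=self.modulation_frequency)


def _offset_lookup(profile: RefractiveIndexProfile, z_grid: np.ndarray) -> np.ndarray:
    """Cumulative defocus on a grid (trapezoid, exact for piecewise-linear n)."""
    n_vals = np.array([profile.n_of_z(float(z)) for z in z_grid]) - profile.n_immersion
    out = np.concatenate([[0.0], np.cumsum(
        0.5 * (n_vals[1:] + n_vals[:-1]) * np.diff(z_grid))])
    return out


def acquire_plane(vol: SpecimenVolume, sheet: LightSheetModel,
                  det: DetectionModel, profile: RefractiveIndexProfile,
                  sheet_z_um: float, applied_offset_um: float,
                  seed: int | None = None, *,
                  photon_scale: float = 1.0, read_noise_sigma: float = 2.0,
                  waist_x_um: float | None = None,
                  weight_cutoff: float = 1e-4) -> AcquisitionRecord:
    """Image one plane: uniform and structured exposures of the same sheet.

    The sheet excites each voxel with a Gaussian axial weight whose
    thickness and peak amplitude follow the beam divergence away from
    the waist (placed at ``waist_x_um``, default field centre).  The
    structured exposure multiplies the excitation by the sinusoidal
    pattern ``(1 + M cos(2 pi x / period + phase)) / 2`` — a modulated
    sweep delivers half the average power of the uniform sweep, so with
    ``M = 0`` the structured image is exactly half the uniform one.
    Emission from each depth is blurred by its own defocus
    ``applied_offset - required_focus_offset(z)`` before axial summation,
    then Poisson photon noise and Gaussian read noise are applied
    (``seed=None`` disables noise).
    """
    nz, ny, nx = vol.shape
    dz = vol.voxel_size_um[2]
    z_coords = vol.z_coords_um
    if not z_coords[0] <= sheet_z_um <= z_coords[-1]:
        raise DomainError(f"sheet position {sheet_z_um} um outside volume "
                          f"[{z_coords[0]}, {z_coords[-1]}]")
    if det.image_shape != (ny, nx):
        raise DomainError("detection image shape must match the volume's "
                          "lateral (y, x) grid")

    x = vol.x_coords_um
    if waist_x_um is None:
        waist_x_um = 0.5 * (x[0] + x[-1])

    # Sheet geometry per column: FWHM grows away from the waist, peak
    # amplitude falls as w0/w(x) (energy conservation in the sheet).
    fwhm_x = sheet_width(sheet, x - waist_x_um)
    sigma_z = np.asarray(fwhm_x) / _FWHM_TO_SIGMA
    amp_x = sheet.waist_fwhm_um / np.asarray(fwhm_x)
    center_x = sheet_z_um + math.tan(sheet.tilt_rad) * (x - 0.5 * (x[0] + x[-1]))

    pattern_x = 0.5 * (1.0 + sheet.modulation_amplitude * np.cos(
        2.0 * math.pi * x / sheet.modulation_period_um
        + sheet.modulation_phase_rad))

    offsets = _offset_lookup(profile, z_coords)
    true_offset = float(np.interp(sheet_z_um, z_coords, offsets))

    uniform = np.zeros((ny, nx))
    structured = np.zeros((ny, nx))
    # Excitation weight per (slice, column); skip slices the sheet barely touches.
    w = amp_x[None, :] * np.exp(
        -((z_coords[:, None] - center_x[None, :]) ** 2) / (2.0 * sigma_z[None, :] ** 2))
    active = np.nonzero(w.max(axis=1) > weight_cutoff)[0]
    for k in active:
        sl = vol.density[k] * w[k][None, :]
        if not sl.any():
            continue
        mismatch = applied_offset_um - offsets[k]
        s_px = blur_sigma(det, mismatch) / det.pixel_size_um
        uniform += gaussian_filter(sl, s_px, mode="reflect")
        structured += gaussian_filter(sl * pattern_x[None, :], s_px, mode="reflect")

    scale = photon_scale * dz
    uniform *= scale
    structured *= scale

    if seed is not None:
        rng = np.random.default_rng(seed)
        uniform = rng.poisson(uniform).astype(np.float64) \
            + rng.normal(0.0, read_noise_sigma, uniform.shape)
        structured = rng.poisson(structured).astype(np.float64) \
            + rng.normal(0.0, read_noise_sigma, structured.shape)

    freq = det.pixel_size_um / sheet.modulation_period_um
    return AcquisitionRecord(
        uniform=uniform, structured=structured, sheet_z_um=float(sheet_z_um),
        applied_focus_offset_um=float(applied_offset_um),
        true_focus_offset_um=true_offset, seed=seed,
        modulation_frequency=freq)


@dataclass
class VirtualScope:
    """Bundle of specimen + optics + index profile with a convenience
    acquire method; the object the autofocus/scan routines drive."""

    volume: SpecimenVolume
    sheet: LightSheetModel = field(default_factory=LightSheetModel)
    detection: DetectionModel = field(default_factory=DetectionModel)
    profile: RefractiveIndexProfile = field(
        default_factory=lambda: RefractiveIndexProfile.homogeneous(1.45))
    photon_scale: float = 1.0
    read_noise_sigma: float = 2.0

    def __post_init__(self) -> None:
        ny, nx = self.volume.shape[1:]
        if self.detection.image_shape != (ny, nx):
            # Re-derive the camera grid from the specimen; keeps phantoms
            # and optics consistent without repeating shapes everywhere.
            self.detection = DetectionModel(
                depth_of_field_um=self.detection.depth_of_field_um,
                base_blur_sigma_um=self.detection.base_blur_sigma_um,
                pixel_size_um=self.detection.pixel_size_um,
                image_shape=(ny, nx))

    @property
    def known_modulation_frequency(self) -> float:
        """Commanded pattern frequency in cycles/pixel along x."""
        return self.detection.pixel_size_um / self.sheet.modulation_period_um

    def true_focus_offset(self, sheet_z_um: float) -> float:
        return required_focus_offset(self.profile, sheet_z_um)

    def acquire(self, sheet_z_um: float, applied_offset_um: float,
                seed: int | None = None,
                waist_x_um: float | None = None) -> AcquisitionRecord:
        return acquire_plane(
            self.volume, self.sheet, self.detection, self.profile,
            sheet_z_um, applied_offset_um, seed,
            photon_scale=self.photon_scale,
            read_noise_sigma=self.read_noise_sigma,
            waist_x_um=waist_x_um)
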