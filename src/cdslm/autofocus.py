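"""Autofocus search, excitation-sweep limits, calibration, and scan modes.

The focal plane for a given light-sheet position is found in two stages:
a coarse sweep of candidate detection-focus offsets scored by how well
the imaged pattern frequency matches the commanded one (minimum
frequency MSE), then a fine sweep around the coarse pick maximizing the
SE-DCT of the uniform image.  Repeating this at a handful of sheet
positions (typically 4-10) yields a calibration curve that is linearly
interpolated during a full volumetric scan — the C-DSLM mode.  The
standard LSFM mode applies one constant offset for the whole stack and
accumulates first-order defocus with depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from cdslm.metrics import (NoModulationError, estimate_modulation_frequency,
                           modulation_mse, se_dct)
from cdslm.scope import DomainError, VirtualScope


class PatternNotFoundError(RuntimeError):
    """No candidate offset produced a detectable modulation pattern.

    The practical remedy is to lower the pattern frequency and retry."""


@dataclass(frozen=True)
class SearchConfig:
    """Coarse + fine search geometry around a user-supplied focus estimate."""

    coarse_range_um: float = 150.0
    coarse_step_um: float = 15.0
    fine_range_um: float = 30.0
    fine_step_um: float = 3.0
    known_modulation_frequency: float | None = None

    def __post_init__(self) -> None:
        if min(self.coarse_range_um, self.coarse_step_um,
               self.fine_range_um, self.fine_step_um) <= 0:
            raise DomainError("search ranges and steps must be positive")
        if self.fine_step_um > self.coarse_step_um:
            raise DomainError("fine step must not exceed coarse step")

    def coarse_offsets(self, center: float = 0.0) -> np.ndarray:
        r, s = self.coarse_range_um, self.coarse_step_um
        return center + np.arange(-r, r + 0.5 * s, s)

    def fine_offsets(self, center: float) -> np.ndarray:
        r, s = self.fine_range_um, self.fine_step_um
        return center + np.arange(-r, r + 0.5 * s, s)


def _tie_break(candidates: np.ndarray, scores: np.ndarray,
               minimize: bool) -> float:
    """Best candidate; ties resolved toward the smallest absolute offset."""
    scores = np.asarray(scores, dtype=float)
    best = np.nanmin(scores) if minimize else np.nanmax(scores)
    tied = candidates[np.isclose(scores, best, rtol=0.0, atol=0.0)]
    order = np.lexsort((tied, np.abs(tied)))
    return float(tied[order[0]])


def coarse_focus_search(acquire_fn: Callable[[float], np.ndarray],
                        candidate_offsets: Sequence[float],
                        known_frequency: float,
                        max_mse: float | None = None,
                        min_prominence: float = 5.0) -> float:
    """Coarse focal estimate: the candidate offset whose structured image
    best reproduces the commanded pattern frequency (minimum MSE).

    ``acquire_fn(offset)`` must return a structured image.  Candidates
    whose image shows no modulation — or, when ``max_mse`` is given,
    whose frequency error exceeds it (the pattern washed out by defocus
    and the estimate locked onto specimen structure instead) — are
    dropped; if none remains a :class:`PatternNotFoundError` is raised.
    """
    offsets = np.asarray(candidate_offsets, dtype=float)
    if offsets.size < 3:
        raise DomainError("need at least 3 candidate offsets")
    mses = np.full(offsets.size, np.nan)
    band = (0.75 * known_frequency, min(1.25 * known_frequency, 0.5))
    for i, off in enumerate(offsets):
        img = acquire_fn(float(off))
        try:
            est = estimate_modulation_frequency(img, band=band)
        except NoModulationError:
            continue
        mse = modulation_mse(est, known_frequency)
        if est.prominence < min_prominence:
            continue  # in-band peak indistinguishable from noise
        if max_mse is not None and mse > max_mse:
            continue
        mses[i] = mse
    if np.all(np.isnan(mses)):
        raise PatternNotFoundError(
            "no candidate offset produced a detectable pattern; "
            "consider lowering the modulation frequency")
    return _tie_break(offsets[~np.isnan(mses)], mses[~np.isnan(mses)], minimize=True)


def fine_focus_search(acquire_fn: Callable[[float], np.ndarray],
                      center_offset: float, fine_cfg: SearchConfig,
                      max_recenter: int = 3) -> float:
    """Refine a coarse focus estimate by maximizing SE-DCT of the uniform
    image over ``center_offset +/- fine_range`` at ``fine_step``.

    If the maximum falls on a window edge — the coarse estimate was off
    by more than the fine range — the window is re-centred on that edge
    and swept again, up to ``max_recenter`` times, so the refinement
    hill-climbs out of a poor initial guess.
    """
    center = float(center_offset)
    for _ in range(max_recenter + 1):
        offsets = fine_cfg.fine_offsets(center)
        values = np.array([se_dct(acquire_fn(float(off))) for off in offsets])
        best_val = values.max()
        tied = offsets[values == best_val]
        if tied.size > 1 and offsets[0] in tied and offsets[-1] in tied:
            warnings.warn("focus metric has equal maxima at both sweep ends; "
                          "returning the maximum nearest the sweep centre",
                          RuntimeWarning, stacklevel=2)
            return _tie_break(offsets, values, minimize=False)
        best = _tie_break(offsets, values, minimize=False)
        if best not in (offsets[0], offsets[-1]):
            return best
        center = best
    return best


def determine_etl1_limits(sweep_images: Sequence[np.ndarray],
                          sweep_values: Sequence[float]
                          ) -> tuple[float, float]:
    """Excitation-lens sweep limits from an ETL-1 sweep.

    For each image three pixel lines orthogonal to the propagation axis
    (far left, centre, far right columns) are summed.  The sweep value
    maximizing the far-left sum and the one maximizing the far-right sum
    bracket the sweep that parks the beam waist at each field edge; they
    are returned ordered ``(low, high)``.
    """
    values = np.asarray(sweep_values, dtype=float)
    if values.size < 3:
        raise DomainError("need at least 3 sweep values")
    if len(sweep_images) != values.size:
        raise DomainError("one image per sweep value required")
    left, center, right = [], [], []
    for img in sweep_images:
        img = np.asarray(img, dtype=float)
        left.append(img[:, 0].sum())
        center.append(img[:, img.shape[1] // 2].sum())
        right.append(img[:, -1].sum())
    left, right = np.asarray(left), np.asarray(right)
    span = max(np.ptp(left), np.ptp(right))
    scale = max(abs(left).max(), abs(right).max(), 1e-30)
    if span <= 1e-9 * scale:
        warnings.warn("no waist contrast across the sweep; "
                      "returning degenerate equal limits",
                      RuntimeWarning, stacklevel=2)
        v = float(values[0])
        return (v, v)
    lo = float(values[int(np.argmax(left))])
    hi = float(values[int(np.argmax(right))])
    return (lo, hi) if lo <= hi else (hi, lo)


@dataclass(frozen=True)
class CalibrationPoint:
    """Co-planar configuration at one light-sheet position."""

    sheet_z_um: float
    focus_offset_um: float
    etl1_limits: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.etl1_limits[0] > self.etl1_limits[1]:
            raise DomainError("etl1 limits must be ordered (low, high)")


@dataclass
class CalibrationCurve:
    """Ordered calibration points plus the interpolation (Nyquist) step."""

    points: list[CalibrationPoint]
    interpolation_step_um: float = 3.0

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise DomainError("a calibration curve needs at least 2 points")
        z = self.sheet_z_um
        if np.any(np.diff(z) <= 0):
            raise DomainError("calibration sheet positions must be strictly increasing")

    @property
    def sheet_z_um(self) -> np.ndarray:
        return np.array([p.sheet_z_um for p in self.points])

    @property
    def focus_offset_um(self) -> np.ndarray:
        return np.array([p.focus_offset_um for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sheet_z_um": self.sheet_z_um,
            "focus_offset_um": self.focus_offset_um,
            "etl1_low": [p.etl1_limits[0] for p in self.points],
            "etl1_high": [p.etl1_limits[1] for p in self.points],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, interpolation_step_um: float = 3.0
                 ) -> "CalibrationCurve":
        df = pd.read_csv(path)
        pts = [CalibrationPoint(r.sheet_z_um, r.focus_offset_um,
                                (r.etl1_low, r.etl1_high))
               for r in df.itertuples()]
        return cls(pts, interpolation_step_um)


def interpolate_calibration(curve: CalibrationCurve,
                            query_z_um: float) -> CalibrationPoint:
    """Piecewise-linear interpolation of the calibration at ``query_z_um``.

    Queries beyond the first/last calibration point clamp to the end
    values (np.interp semantics)."""
    z = curve.sheet_z_um
    q = float(query_z_um)
    off = float(np.interp(q, z, curve.focus_offset_um))
    lo = float(np.interp(q, z, [p.etl1_limits[0] for p in curve.points]))
    hi = float(np.interp(q, z, [p.etl1_limits[1] for p in curve.points]))
    return CalibrationPoint(q, off, (lo, hi))


def build_calibration(scope: VirtualScope, positions: Sequence[float],
                      cfg: SearchConfig | None = None, *,
                      seed: int | None = 0, etl1_sweep_points: int = 7
                      ) -> CalibrationCurve:
    """Run the full autofocus (coarse MSE + fine SE-DCT + ETL-1 sweep) at
    each requested light-sheet position and assemble a calibration curve.

    The coarse search at each position is centred on a prediction from
    the points already found (linear extrapolation of the offset trend;
    0 for the first position), mirroring the incremental user estimate
    of an interactive calibration.  A washed-out pattern (frequency
    error above half a DFT bin) does not count as a lock, and on a
    failed lock the coarse window is doubled and retried a few times
    before the position is excluded with a warning; at least two
    positions must survive.
    """
    cfg = cfg or SearchConfig()
    known_f = cfg.known_modulation_frequency or scope.known_modulation_frequency
    positions = sorted(float(p) for p in positions)
    if len(positions) < 2:
        raise DomainError("calibration needs at least 2 sheet positions")

    counter = [0]

    def _seed() -> int | None:
        if seed is None:
            return None
        counter[0] += 1
        return (int(seed) * 1_000_003 + counter[0]) % (2 ** 31)

    x = scope.volume.x_coords_um
    sweep_values = np.linspace(x[0], x[-1], etl1_sweep_points)
    nx = scope.volume.shape[2]
    max_mse = (0.5 / nx) ** 2  # half a DFT bin: a genuine pattern lock

    def _predict(z: float) -> float:
        if not points:
            return 0.0
        if len(points) == 1:
            return points[-1].focus_offset_um
        p0, p1 = points[-2], points[-1]
        slope = ((p1.focus_offset_um - p0.focus_offset_um)
                 / (p1.sheet_z_um - p0.sheet_z_um))
        return p1.focus_offset_um + slope * (z - p1.sheet_z_um)

    points: list[CalibrationPoint] = []
    for z in positions:
        center = _predict(z)
        coarse = None
        scale = 1.0
        while scale <= 32.0:
            wide = SearchConfig(
                coarse_range_um=cfg.coarse_range_um * scale,
                coarse_step_um=cfg.coarse_step_um,
                fine_range_um=cfg.fine_range_um,
                fine_step_um=cfg.fine_step_um)
            try:
                coarse = coarse_focus_search(
                    lambda off: scope.acquire(z, off, seed=_seed()).structured,
                    wide.coarse_offsets(center=center), known_f,
                    max_mse=max_mse)
                break
            except PatternNotFoundError:
                scale *= 2.0
        if coarse is None:
            warnings.warn(f"calibration position z={z} um excluded: "
                          "pattern not found", RuntimeWarning, stacklevel=2)
            continue
        fine = fine_focus_search(
            lambda off: scope.acquire(z, off, seed=_seed()).uniform,
            coarse, cfg)
        sweep_imgs = [scope.acquire(z, fine, seed=_seed(), waist_x_um=v).uniform
                      for v in sweep_values]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            limits = determine_etl1_limits(sweep_imgs, sweep_values)
        points.append(CalibrationPoint(z, fine, limits))
    if len(points) < 2:
        raise PatternNotFoundError(
            "fewer than 2 calibration positions succeeded")
    return CalibrationCurve(points, interpolation_step_um=cfg.fine_step_um)


@dataclass
class ScanResult:
    """A volumetric scan: image stacks plus the per-plane focus report."""

    uniform: np.ndarray      # (n_planes, ny, nx)
    structured: np.ndarray
    report: pd.DataFrame     # plane, z, applied, true, residual, sedct
    mode: str = "cdslm"

    def to_csv(self, path) -> None:
        self.report.to_csv(path, index=False)


def _run_scan(scope: VirtualScope, z_planes: np.ndarray,
              offset_fn: Callable[[float], float], seed: int | None,
              mode: str, compute_sedct: bool) -> ScanResult:
    uniforms, structureds, rows = [], [], []
    for i, z in enumerate(z_planes):
        s = None if seed is None else (int(seed) * 7_654_321 + i) % (2 ** 31)
        applied = float(offset_fn(float(z)))
        rec = scope.acquire(float(z), applied, seed=s)
        uniforms.append(rec.uniform)
        structureds.append(rec.structured)
        rows.append({
            "plane": i, "z_um": float(z), "applied_offset_um": applied,
            "true_offset_um": rec.true_focus_offset_um,
            "residual_um": abs(applied - rec.true_focus_offset_um),
            "sedct": se_dct(rec.uniform) if compute_sedct else np.nan,
        })
    return ScanResult(np.stack(uniforms), np.stack(structureds),
                      pd.DataFrame(rows), mode=mode)


def cdslm_scan(scope: VirtualScope, curve: CalibrationCurve,
               z_start: float, z_stop: float, z_step: float,
               seed: int | None = 0, compute_sedct: bool = True
               ) -> ScanResult:
    """Calibrated volumetric scan: at every plane the detection focus
    follows the interpolated calibration curve."""
    if z_step <= 0:
        raise DomainError("z_step must be positive")
    z_planes = np.arange(z_start, z_stop + 0.5 * z_step, z_step)
    return _run_scan(
        scope, z_planes,
        lambda z: interpolate_calibration(curve, z).focus_offset_um,
        seed, "cdslm", compute_sedct)


def standard_scan(scope: VirtualScope, z_start: float, z_stop: float,
                  z_step: float, initial_offset_um: float = 0.0,
                  seed: int | None = 0, compute_sedct: bool = True
                  ) -> ScanResult:
    """Standard LSFM scan: one constant detection-focus offset for the
    whole stack (optionally an initial index-matching offset); residual
    first-order defocus grows with depth in mismatched media."""
    if z_step <= 0:
        raise DomainError("z_step must be positive")
    z_planes = np.arange(z_start, z_stop + 0.5 * z_step, z_step)
    return _run_scan(scope, z_planes, lambda z: float(initial_offset_um),
                     seed, "standard", compute_sedct)
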