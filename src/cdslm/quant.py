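"""Stereology and cell quantification.

Mean linear intercept (MLI): evenly spaced sample lines are laid over a
binary airspace mask and the lengths of airspace chords bounded on both
ends by tissue are pooled; their mean is the chord length L_m, the
standard morphometric readout of airspace size.  The 3D variant extends
the line grid to a volumetric lattice along up to three axis-aligned
line families, pooling chords across the volume.

Cell counting: background subtraction (large-sigma Gaussian), a
user-defined threshold, connected-component labelling, and a size gate
for single cell bodies; oversized components are counted as multiple
cells using the median in-range object size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cdslm.scope import DomainError

_AXIS_INDEX_3D = {"z": 0, "y": 1, "x": 2}
_AXIS_INDEX_2D = {"y": 0, "x": 1}


@dataclass(frozen=True)
class GridSpec:
    """Sample-line lattice: spacing between parallel lines, the axes the
    lines run along, and a lattice offset."""

    spacing_px: int = 1
    axes: tuple[str, ...] = ("z", "y", "x")
    offset_px: int = 0

    def __post_init__(self) -> None:
        if self.spacing_px < 1:
            raise DomainError("grid spacing must be >= 1 pixel")
        if not self.axes:
            raise DomainError("at least one line axis required")
        if any(a not in ("x", "y", "z") for a in self.axes):
            raise DomainError("axes must be a subset of {x, y, z}")


@dataclass
class MLIResult:
    """Chord-length population and its summary statistics."""

    chords_um: np.ndarray
    lm_um: float
    sd_um: float
    n_chords: int
    n_lines: int
    per_axis: dict = field(default_factory=dict)

    @classmethod
    def from_chords(cls, chords, n_lines: int, per_axis=None) -> "MLIResult":
        chords = np.asarray(chords, dtype=float)
        if chords.size == 0:
            raise DomainError("no tissue-bounded chords found")
        return cls(chords_um=chords, lm_um=float(chords.mean()),
                   sd_um=float(chords.std(ddof=1)) if chords.size > 1 else 0.0,
                   n_chords=int(chords.size), n_lines=int(n_lines),
                   per_axis=dict(per_axis or {}))


def _line_chords(air: np.ndarray, inside: np.ndarray) -> list[int]:
    """Lengths of maximal airspace runs on one sample line.

    A run is kept only if it lies wholly inside the region and is
    bounded on both ends by tissue voxels that are themselves inside the
    region; runs touching the image or region border are censored."""
    a = air & inside
    padded = np.concatenate([[False], a, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    out = []
    n = a.size
    for s, e in zip(starts, ends):
        if s == 0 or e == n:            # image border
            continue
        # bounding voxels must be in-region tissue
        if not (inside[s - 1] and not air[s - 1]):
            continue
        if not (inside[e] and not air[e]):
            continue
        out.append(int(e - s))
    return out


def chords_along_lines(mask: np.ndarray, region_mask: np.ndarray | None,
                       grid: GridSpec, voxel_size_um=None) -> np.ndarray:
    """Airspace chord lengths (um) along an axis-aligned line lattice.

    ``mask`` is boolean with True = airspace; ``region_mask`` (True =
    inside the specimen) excludes areas outside the tissue per the MLI
    protocol.  ``voxel_size_um`` gives the voxel edge per array axis
    (defaults to 1 um isotropic).  Works for 2D (y, x) and 3D (z, y, x)
    inputs.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim not in (2, 3):
        raise DomainError("mask must be 2D or 3D")
    region = (np.ones_like(mask) if region_mask is None
              else np.asarray(region_mask, dtype=bool))
    if region.shape != mask.shape:
        raise DomainError("region mask shape mismatch")
    if not region.any():
        raise DomainError("empty region mask")
    axis_map = _AXIS_INDEX_2D if mask.ndim == 2 else _AXIS_INDEX_3D
    if voxel_size_um is None:
        voxel_size_um = (1.0,) * mask.ndim
    chords, _ = _collect_chords(mask, region, grid, axis_map, voxel_size_um)
    return np.asarray(chords, dtype=float)


def _collect_chords(mask, region, grid, axis_map, voxel_size_um):
    """Pool chords over all requested line families; also count lines."""
    all_chords: list[float] = []
    per_axis: dict[str, list[float]] = {}
    n_lines = 0
    for ax_name in grid.axes:
        if ax_name not in axis_map:
            continue
        ax = axis_map[ax_name]
        vox = float(voxel_size_um[ax])
        moved = np.moveaxis(mask, ax, -1)
        moved_r = np.moveaxis(region, ax, -1)
        lead_shape = moved.shape[:-1]
        # lattice of line start positions in the leading axes
        slices = tuple(slice(grid.offset_px % grid.spacing_px, s, grid.spacing_px)
                       for s in lead_shape)
        lines = moved[slices].reshape(-1, moved.shape[-1])
        lines_r = moved_r[slices].reshape(-1, moved.shape[-1])
        axis_chords: list[float] = []
        for air_line, in_line in zip(lines, lines_r):
            if not in_line.any():
                continue
            n_lines += 1
            axis_chords.extend(c * vox for c in _line_chords(air_line, in_line))
        per_axis[ax_name] = axis_chords
        all_chords.extend(axis_chords)
    return all_chords, (n_lines, per_axis)


def mli_2d(mask: np.ndarray, region_mask: np.ndarray | None = None,
           grid_spacing: int = 1, voxel_size_um=(1.0, 1.0),
           offset_px: int = 0) -> MLIResult:
    """2D mean linear intercept: horizontal and vertical line families
    placed independently over the image; L_m is the pooled chord mean."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise DomainError("mli_2d expects a 2D mask")
    grid = GridSpec(spacing_px=grid_spacing, axes=("x", "y"),
                    offset_px=offset_px)
    region = (np.ones_like(mask) if region_mask is None
              else np.asarray(region_mask, dtype=bool))
    if not region.any():
        raise DomainError("empty region mask")
    chords, (n_lines, per_axis) = _collect_chords(
        mask, region, grid, _AXIS_INDEX_2D, voxel_size_um)
    return MLIResult.from_chords(
        chords, n_lines,
        {a: _axis_summary(c) for a, c in per_axis.items()})


def mli_3d(volume_mask: np.ndarray, region_mask: np.ndarray | None = None,
           grid: GridSpec | None = None,
           voxel_size_um=(1.0, 1.0, 1.0)) -> MLIResult:
    """3D mean linear intercept on a volumetric line lattice.

    Lines run along each requested axis from a lattice of positions in
    the transverse plane; chords terminate at the nearest in-region
    tissue voxel along each line.  Per-axis sub-results are retained in
    ``per_axis`` for anisotropy inspection.
    """
    volume_mask = np.asarray(volume_mask, dtype=bool)
    if volume_mask.ndim != 3:
        raise DomainError("mli_3d expects a 3D mask")
    grid = grid or GridSpec()
    region = (np.ones_like(volume_mask) if region_mask is None
              else np.asarray(region_mask, dtype=bool))
    if not region.any():
        raise DomainError("empty region mask")
    chords, (n_lines, per_axis) = _collect_chords(
        volume_mask, region, grid, _AXIS_INDEX_3D, voxel_size_um)
    return MLIResult.from_chords(
        chords, n_lines,
        {a: _axis_summary(c) for a, c in per_axis.items()})


def _axis_summary(chords: list[float]) -> dict:
    arr = np.asarray(chords, dtype=float)
    if arr.size == 0:
        return {"lm_um": np.nan, "n_chords": 0}
    return {"lm_um": float(arr.mean()), "n_chords": int(arr.size)}


@dataclass(frozen=True)
class CellCountConfig:
    """Counting parameters: background scale, positive-pixel threshold and
    the size window (px^2 / px^3) accepted as a single cell body."""

    threshold: float
    size_range_px: tuple[float, float]
    background_sigma_px: float = 50.0

    def __post_init__(self) -> None:
        if self.size_range_px[0] >= self.size_range_px[1]:
            raise DomainError("size range must satisfy min < max")
        if self.background_sigma_px < 0:
            raise DomainError("background sigma must be non-negative")


@dataclass
class CellCountResult:
    """Counted cells with the per-object size table."""

    count: int
    object_sizes: np.ndarray
    multi_cell_splits: int


def count_cells(image: np.ndarray, cfg: CellCountConfig) -> CellCountResult:
    """Count fluorescent cell bodies in a 2D or 3D image.

    A Gaussian-smoothed copy (sigma ``background_sigma_px``) is
    subtracted to homogenize the background, positive pixels are found
    with the user threshold, and connected components (8-connectivity in
    2D, 26 in 3D) are sized.  Components inside the single-cell size
    window count as one cell; components above the window count as
    ``round(size / median_single_cell_size)`` (the multi-cellular-object
    correction); smaller ones are discarded as debris.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim not in (2, 3):
        raise DomainError("expected a 2D or 3D image")
    if cfg.background_sigma_px > 0:
        work = img - ndimage.gaussian_filter(img, cfg.background_sigma_px,
                                             mode="reflect")
    else:
        work = img
    positive = work > cfg.threshold
    structure = np.ones((3,) * img.ndim, dtype=bool)
    labels, n = ndimage.label(positive, structure=structure)
    if n == 0:
        return CellCountResult(0, np.empty(0), 0)
    sizes = np.bincount(labels.ravel())[1:]
    lo, hi = cfg.size_range_px
    in_range = sizes[(sizes >= lo) & (sizes <= hi)]
    oversize = sizes[sizes > hi]
    if in_range.size == 0:
        if oversize.size:
            raise DomainError(
                "only oversize objects found: cannot estimate the "
                "single-cell size for the multi-cell correction")
        return CellCountResult(0, sizes.astype(float), 0)
    median_cell = float(np.median(in_range))
    count = int(in_range.size)
    splits = 0
    for s in oversize:
        count += max(int(round(s / median_cell)), 1)
        splits += 1
    return CellCountResult(count, sizes.astype(float), splits)
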