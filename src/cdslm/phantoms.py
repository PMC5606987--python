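"""Seeded specimen phantoms for the virtual scope.

Three specimen classes stand in for the preparations the method targets:
point-like fluorescent beads (alignment phantoms), elongated fibers
(myelin tracks), and a Voronoi wall foam emulating distal-lung alveolar
airspaces.  The foam generator returns the exact binary air mask it used,
which is the ground truth for mean-linear-intercept stereology.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from cdslm.scope import DomainError, SpecimenVolume


def _check_shape(shape) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 2 for s in shape):
        raise DomainError(f"degenerate volume shape {shape}")
    return shape


def make_bead_volume(n_beads: int, shape=(64, 96, 96),
                     voxel_size_um=(1.0, 1.0, 3.0), seed: int = 0, *,
                     bead_radius_um: float = 2.0,
                     intensity: float = 1000.0,
                     margin_frac: float = 0.1) -> SpecimenVolume:
    """Random hard-sphere beads of uniform brightness.

    Beads are kept ``margin_frac`` of each dimension away from the
    borders so a bead is never clipped by the field of view.
    """
    if n_beads < 0:
        raise DomainError("n_beads must be non-negative")
    nz, ny, nx = _check_shape(shape)
    vx, vy, vz = voxel_size_um
    rng = np.random.default_rng(seed)
    density = np.zeros((nz, ny, nx))
    rz, ry, rx = (max(bead_radius_um / v, 0.5) for v in (vz, vy, vx))
    for _ in range(int(n_beads)):
        cz = rng.uniform(margin_frac * nz, (1 - margin_frac) * nz)
        cy = rng.uniform(margin_frac * ny, (1 - margin_frac) * ny)
        cx = rng.uniform(margin_frac * nx, (1 - margin_frac) * nx)
        z0, z1 = int(max(cz - rz - 1, 0)), int(min(cz + rz + 2, nz))
        y0, y1 = int(max(cy - ry - 1, 0)), int(min(cy + ry + 2, ny))
        x0, x1 = int(max(cx - rx - 1, 0)), int(min(cx + rx + 2, nx))
        zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
        inside = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
                  + ((xx - cx) / rx) ** 2) <= 1.0
        density[z0:z1, y0:y1, x0:x1][inside] = intensity
    return SpecimenVolume(density, voxel_size_um=voxel_size_um)


def make_fiber_volume(n_fibers: int, shape=(64, 96, 96),
                      voxel_size_um=(1.0, 1.0, 3.0), seed: int = 0, *,
                      fiber_radius_um: float = 1.5,
                      intensity: float = 1000.0) -> SpecimenVolume:
    """Random straight fibers spanning the volume, Gaussian cross-section."""
    if n_fibers < 0:
        raise DomainError("n_fibers must be non-negative")
    nz, ny, nx = _check_shape(shape)
    rng = np.random.default_rng(seed)
    skeleton = np.zeros((nz, ny, nx))
    for _ in range(int(n_fibers)):
        p0 = rng.uniform([0, 0, 0], [nz - 1, ny - 1, nx - 1])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = float(np.hypot(np.hypot(nz, ny), nx))
        t = np.linspace(-length, length, int(4 * length))
        pts = p0[None, :] + t[:, None] * direction[None, :]
        ok = np.all((pts >= 0) & (pts <= [nz - 1, ny - 1, nx - 1]), axis=1)
        idx = np.round(pts[ok]).astype(int)
        skeleton[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
    vx, vy, vz = voxel_size_um
    sig = [max(fiber_radius_um / v, 0.4) / 2.0 for v in (vz, vy, vx)]
    density = gaussian_filter(skeleton, sig)
    peak = density.max()
    if peak > 0:
        density *= intensity / peak
    return SpecimenVolume(density, voxel_size_um=voxel_size_um)


def make_foam_volume(mean_airspace_um: float = 30.0, wall_um: float = 4.0,
                     shape=(48, 96, 96), voxel_size_um=(1.0, 1.0, 1.0),
                     seed: int = 0, *, intensity: float = 1000.0
                     ) -> tuple[SpecimenVolume, np.ndarray]:
    """Voronoi wall foam: fluorescent tissue walls around air cells.

    Cell nuclei are sown at a density giving mean cell diameter of
    roughly ``mean_airspace_um``; voxels within ``wall_um`` of a Voronoi
    boundary (difference of the two nearest-nucleus distances below
    ``wall_um``) become fluorescent wall, everything else is air.
    Returns the specimen and the exact boolean air mask (True = air).
    """
    if mean_airspace_um <= 0 or wall_um <= 0:
        raise DomainError("airspace and wall sizes must be positive")
    nz, ny, nx = _check_shape(shape)
    vx, vy, vz = voxel_size_um
    extent = np.array([nz * vz, ny * vy, nx * vx])
    n_cells = max(int(np.prod(extent) / mean_airspace_um ** 3), 2)
    rng = np.random.default_rng(seed)
    nuclei = rng.uniform([0, 0, 0], extent, size=(n_cells, 3))
    zz, yy, xx = np.meshgrid(np.arange(nz) * vz, np.arange(ny) * vy,
                             np.arange(nx) * vx, indexing="ij")
    pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    d, _ = cKDTree(nuclei).query(pts, k=2)
    wall = (d[:, 1] - d[:, 0]) < wall_um
    wall = wall.reshape(nz, ny, nx)
    air_mask = ~wall
    vol = SpecimenVolume(intensity * wall.astype(np.float64),
                         voxel_size_um=voxel_size_um)
    return vol, air_mask


def make_slab_foam(gap_px: int = 20, wall_px: int = 4, shape=(48, 96, 96),
                   voxel_size_um=(1.0, 1.0, 1.0), axis: int = 0, *,
                   intensity: float = 1000.0
                   ) -> tuple[SpecimenVolume, np.ndarray]:
    """Deterministic slab foam: parallel air gaps of exactly ``gap_px``
    voxels separated by walls of ``wall_px`` voxels along ``axis``.

    The hand-checkable phantom for intercept stereology: every interior
    chord along ``axis`` has length exactly ``gap_px`` voxels.
    """
    if gap_px < 1 or wall_px < 1:
        raise DomainError("gap and wall must be at least one voxel")
    shape = _check_shape(shape)
    n = shape[axis]
    period = gap_px + wall_px
    coord = np.arange(n)
    is_wall_1d = (coord % period) < wall_px
    shp = [1, 1, 1]
    shp[axis] = n
    wall = np.broadcast_to(is_wall_1d.reshape(shp), shape).copy()
    air_mask = ~wall
    vol = SpecimenVolume(intensity * wall.astype(np.float64),
                         voxel_size_um=voxel_size_um)
    return vol, air_mask
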