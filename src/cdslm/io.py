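"""Stack I/O, sidecar metadata, and the tiled-acquisition directory layout.

Stacks travel as multi-page TIFF (16-bit for raw counts, 32-bit float
for noiseless ground truth) with a plain-text ``key=value`` sidecar
carrying the acquisition geometry and seed.  Tiled acquisitions are
written in the classic TeraStitcher two-level hierarchy so a stitched
volume can be assembled downstream without re-formatting:

    root/<VVVVVV>/<VVVVVV>_<HHHHHH>/<VVVVVV>_<HHHHHH>_<DDDDDD>.tif

where V/H/D are the vertical/horizontal/axial tile origins in tenths of
a micrometre, zero-padded to six digits.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from cdslm.scope import DomainError

SCAN_MODES = ("cdslm", "standard")


@dataclass
class StackMetadata:
    """Sidecar metadata for one acquired stack."""

    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (x, y, z)
    axial_step_um: float = 1.0
    modulation_period_um: float = 16.0
    seed: int = 0
    scan_mode: str = "cdslm"
    notes: str = ""

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um) or self.axial_step_um <= 0:
            raise DomainError("geometry values must be positive")
        if self.scan_mode not in SCAN_MODES:
            raise DomainError(f"scan_mode must be one of {SCAN_MODES}")

    def to_text(self) -> str:
        vx, vy, vz = self.voxel_size_um
        lines = [
            f"voxel_size_x_um={vx!r}",
            f"voxel_size_y_um={vy!r}",
            f"voxel_size_z_um={vz!r}",
            f"axial_step_um={self.axial_step_um!r}",
            f"modulation_period_um={self.modulation_period_um!r}",
            f"seed={self.seed}",
            f"scan_mode={self.scan_mode}",
            f"notes={self.notes}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "StackMetadata":
        kv = parse_config(text)
        return cls(
            voxel_size_um=(float(kv.get("voxel_size_x_um", 1.0)),
                           float(kv.get("voxel_size_y_um", 1.0)),
                           float(kv.get("voxel_size_z_um", 1.0))),
            axial_step_um=float(kv.get("axial_step_um", 1.0)),
            modulation_period_um=float(kv.get("modulation_period_um", 16.0)),
            seed=int(kv.get("seed", 0)),
            scan_mode=str(kv.get("scan_mode", "cdslm")),
            notes=str(kv.get("notes", "")),
        )


def parse_config(text: str) -> dict[str, str]:
    """Parse flat ``key=value`` configuration text (``#`` comments allowed)."""
    out: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DomainError(f"malformed config line: {raw!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_config(path) -> dict[str, str]:
    return parse_config(Path(path).read_text())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.txt")


def write_stack(stack: np.ndarray, meta: StackMetadata, path) -> Path:
    """Write a multi-page TIFF plus its sidecar metadata file.

    Integer stacks are stored as 16-bit, float stacks as 32-bit float;
    integer data round-trips bit-exactly.
    """
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise DomainError("expected a 2D image or 3D (z, y, x) stack")
    if np.issubdtype(stack.dtype, np.integer):
        data = stack.astype(np.uint16)
    else:
        data = stack.astype(np.float32)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, photometric="minisblack")
    _sidecar_path(path).write_text(meta.to_text())
    return path


def read_stack(path) -> tuple[np.ndarray, StackMetadata]:
    """Read a multi-page TIFF and its sidecar; defaults with a warning if
    the sidecar is missing."""
    path = Path(path)
    try:
        stack = tifffile.imread(path)
    except Exception as exc:
        raise DomainError(f"malformed TIFF {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = StackMetadata.from_text(sidecar.read_text())
    else:
        warnings.warn(f"missing sidecar {sidecar}; using default metadata",
                      RuntimeWarning, stacklevel=2)
        meta = StackMetadata()
    return stack, meta


@dataclass
class TileLayout:
    """Regular tile grid with fractional overlap between neighbours."""

    grid_rows: int
    grid_cols: int
    overlap_fraction: float
    tile_size_um: tuple[float, float]  # (height/vertical, width/horizontal)
    z_origin_um: float = 0.0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise DomainError("grid must have at least one tile")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise DomainError("overlap fraction must lie in [0, 1)")

    @property
    def tile_origins_um(self) -> list[tuple[float, float]]:
        """Row-major (vertical, horizontal) tile origins in um."""
        vh, hw = self.tile_size_um
        pitch_v = vh * (1.0 - self.overlap_fraction)
        pitch_h = hw * (1.0 - self.overlap_fraction)
        return [(r * pitch_v, c * pitch_h)
                for r in range(self.grid_rows) for c in range(self.grid_cols)]


def _tenths(um: float) -> str:
    return f"{int(round(um * 10.0)):06d}"


def write_terastitcher_layout(tiles, layout: TileLayout, root) -> Path:
    """Write tiles in the TeraStitcher two-level directory hierarchy.

    ``tiles`` are row-major 3D stacks, one per grid position; all must
    share a shape.  Coordinates in folder/file names are the tile origins
    in tenths of a micrometre derived from the tile size and overlap.
    """
    root = Path(root)
    tiles = [np.asarray(t) for t in tiles]
    if len(tiles) != layout.grid_rows * layout.grid_cols:
        raise DomainError("number of tiles must match the grid")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise DomainError("all tiles must share a shape")
    seen: set[tuple[str, str]] = set()
    d = _tenths(layout.z_origin_um)
    for tile, (v_um, h_um) in zip(tiles, layout.tile_origins_um):
        v, h = _tenths(v_um), _tenths(h_um)
        if (v, h) in seen:
            raise DomainError(f"tile coordinate collision at V={v} H={h}")
        seen.add((v, h))
        tile_dir = root / v / f"{v}_{h}"
        tile_dir.mkdir(parents=True, exist_ok=True)
        data = (tile.astype(np.uint16)
                if np.issubdtype(tile.dtype, np.integer)
                else tile.astype(np.float32))
        tifffile.imwrite(tile_dir / f"{v}_{h}_{d}.tif", data,
                         photometric="minisblack")
    return root


_V_RE = re.compile(r"^\d{6}$")
_VH_RE = re.compile(r"^(\d{6})_(\d{6})$")
_VHD_RE = re.compile(r"^(\d{6})_(\d{6})_(\d{6})\.tif$")


def validate_terastitcher_layout(root) -> bool:
    """Structurally validate a two-level tiled layout.

    Checks the folder/file name conventions, the consistency of nested
    coordinates, and that row/column coordinates are monotone.  Raises
    :class:`DomainError` on the first violation, returns True otherwise.
    """
    root = Path(root)
    v_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not v_dirs:
        raise DomainError("no row folders found")
    v_coords = []
    h_by_row = []
    for vd in v_dirs:
        if not _V_RE.match(vd.name):
            raise DomainError(f"bad row folder name {vd.name!r}")
        v_coords.append(int(vd.name))
        h_coords = []
        for td in sorted(p for p in vd.iterdir() if p.is_dir()):
            m = _VH_RE.match(td.name)
            if not m or m.group(1) != vd.name:
                raise DomainError(f"bad tile folder name {td.name!r} in {vd.name}")
            h_coords.append(int(m.group(2)))
            tifs = sorted(td.glob("*.tif"))
            if not tifs:
                raise DomainError(f"tile folder {td.name} has no TIFF")
            for t in tifs:
                fm = _VHD_RE.match(t.name)
                if not fm or fm.group(1) != m.group(1) or fm.group(2) != m.group(2):
                    raise DomainError(f"bad tile file name {t.name!r}")
        if not h_coords:
            raise DomainError(f"row folder {vd.name} has no tile folders")
        if sorted(h_coords) != h_coords or len(set(h_coords)) != len(h_coords):
            raise DomainError(f"non-monotone tile coordinates in row {vd.name}")
        h_by_row.append(h_coords)
    if sorted(v_coords) != v_coords or len(set(v_coords)) != len(v_coords):
        raise DomainError("non-monotone row coordinates")
    return True
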