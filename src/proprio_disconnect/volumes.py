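"""Voxel volumes and streamlines: the shared data model of the pipeline.

Every stage of the analysis — lesion masks, tract probability maps,
grey-matter segmentations, disconnectome maps, statistic images — lives on a
common 3D voxel grid.  :class:`VolumeGrid` wraps the array together with its
geometry (voxel size and a 4x4 world transform, NIfTI convention: voxel
centre ``(i, j, k)`` maps to world mm via ``affine @ (i, j, k, 1)``).

No resampling is performed anywhere: stages refuse to mix grids that are not
compatible (same shape, voxel size and transform), mirroring an analysis run
entirely in one normalised space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "StreamlineSet",
    "read_volume",
    "write_volume",
    "grids_compatible",
    "rasterize_streamline",
    "rasterize_streamlines",
    "read_streamlines",
    "write_streamlines",
]

#: geometric tolerance for grid compatibility checks (mm / affine entries)
GRID_TOL = 1e-4


class VolumeFormatError(ValueError):
    """Raised for malformed or unsupported volume files."""


class MaskValueError(ValueError):
    """Raised when a volume used as a binary mask contains non-{0,1} values."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel geometry.

    Parameters
    ----------
    values : ndarray, shape (ni, nj, nk)
        Voxel data. Binary masks, probabilities in [0, 1], or statistics.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform; voxel centres at ``affine @ (i, j, k, 1)``.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.values.ndim} dimensions"
            )
        if any(s < 1 for s in self.values.shape):
            raise VolumeFormatError(f"degenerate shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise VolumeFormatError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise VolumeFormatError("volume contains non-finite values")
        if np.any(self.voxel_size <= 0):
            raise VolumeFormatError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (per axis)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def volume_cc(self) -> float:
        """Volume of the nonzero voxels in cubic centimetres."""
        return float(np.count_nonzero(self.values)) * self.voxel_volume_mm3 / 1000.0

    def is_mask(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def as_mask(self) -> np.ndarray:
        """Boolean array view of a {0,1} mask; rejects anything else."""
        if not self.is_mask():
            bad = np.unique(self.values[~np.isin(self.values, (0, 1))])[:5]
            raise MaskValueError(f"mask contains values other than 0/1: {bad}")
        return self.values.astype(bool)

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry and different data."""
        return VolumeGrid(np.asarray(values), self.affine.copy())

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points (n, 3) to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class StreamlineSet:
    """Streamlines of one control subject: polylines in world mm.

    Each polyline is an (n_points, 3) float array with n_points >= 2
    (a repeated point encodes a degenerate zero-length line).
    """

    control_id: str
    streamlines: list[np.ndarray]

    def __post_init__(self) -> None:
        cleaned = []
        for line in self.streamlines:
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError("each streamline must be an (n>=2, 3) point array")
            if not np.all(np.isfinite(arr)):
                raise ValueError("streamline contains non-finite points")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


# ---------------------------------------------------------------------------
# NIfTI IO


def read_volume(path: str | Path, *, require_mask: bool = False) -> VolumeGrid:
    """Read a NIfTI-1 volume.

    Parameters
    ----------
    require_mask : bool
        If true, reject volumes whose values are not all in {0, 1}.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D volume, got shape {data.shape}"
        )
    grid = VolumeGrid(data, np.asarray(img.affine))
    if require_mask:
        grid.as_mask()
    return grid


def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    """Write a grid as NIfTI-1. Integer arrays stay integer for exact round-trips."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = grid.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, grid.affine)
    nib.save(img, str(path))
    return path


def grids_compatible(a: VolumeGrid, b: VolumeGrid, tol: float = GRID_TOL) -> bool:
    """True iff the two grids share shape, voxel size and world transform."""
    return (
        a.shape == b.shape
        and np.allclose(a.voxel_size, b.voxel_size, atol=tol)
        and np.allclose(a.affine, b.affine, atol=tol)
    )


def require_compatible(*grids: VolumeGrid) -> None:
    first = grids[0]
    for other in grids[1:]:
        if not grids_compatible(first, other):
            raise ValueError(
                "grids are not on a common space "
                f"({first.shape} vs {other.shape}); resampling is not supported"
            )


# ---------------------------------------------------------------------------
# Streamline rasterisation (3D voxel traversal)


def _traverse_segment(p0: np.ndarray, p1: np.ndarray, shape) -> Iterable[tuple]:
    """Amanatides–Woo 3D DDA: every voxel whose cube a segment enters.

    Operates in continuous voxel coordinates where voxel (i,j,k) spans
    [i-0.5, i+0.5) x ... (centres at integer coordinates).
    """
    d = p1 - p0
    length = float(np.linalg.norm(d))
    cur = np.round(p0).astype(int)
    end = np.round(p1).astype(int)

    def in_bounds(v):
        return all(0 <= v[i] < shape[i] for i in range(3))

    if length < 1e-12:
        if in_bounds(cur):
            yield tuple(cur)
        return

    step = np.where(d > 0, 1, -1)
    # parametric distance to the first boundary crossing along each axis
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for ax in range(3):
        if d[ax] != 0:
            boundary = cur[ax] + (0.5 if d[ax] > 0 else -0.5)
            t_max[ax] = (boundary - p0[ax]) / d[ax]
            t_delta[ax] = 1.0 / abs(d[ax])

    if in_bounds(cur):
        yield tuple(cur)
    # walk until the end voxel; bounded iteration guards degenerate rounding
    max_steps = int(np.abs(end - cur).sum()) + 6
    for _ in range(max_steps):
        if np.array_equal(cur, end):
            return
        ax = int(np.argmin(t_max))
        if t_max[ax] > 1.0 + 1e-12:
            return
        cur = cur.copy()
        cur[ax] += step[ax]
        t_max[ax] += t_delta[ax]
        if in_bounds(cur):
            yield tuple(cur)


def rasterize_streamline(line: np.ndarray, grid: VolumeGrid) -> set[tuple]:
    """Voxels (0-based ``(i, j, k)`` tuples) whose cube the polyline enters.

    Deterministic exact traversal; points outside the grid contribute
    nothing (an entirely out-of-grid line yields the empty set).
    """
    pts = grid.world_to_voxel(np.asarray(line, dtype=float))
    voxels: set[tuple] = set()
    if len(pts) == 1:
        voxels.update(_traverse_segment(pts[0], pts[0], grid.shape))
        return voxels
    for a, b in zip(pts[:-1], pts[1:]):
        voxels.update(_traverse_segment(a, b, grid.shape))
    return voxels


def rasterize_streamlines(
    lines: Sequence[np.ndarray], grid: VolumeGrid
) -> list[np.ndarray]:
    """Rasterise many polylines; returns per-line (n, 3) int voxel arrays."""
    out = []
    for line in lines:
        vox = rasterize_streamline(line, grid)
        out.append(
            np.array(sorted(vox), dtype=np.intp).reshape(-1, 3)
            if vox
            else np.empty((0, 3), dtype=np.intp)
        )
    return out


# ---------------------------------------------------------------------------
# Streamline IO: plain-text polylines, plus TRK via nibabel


def write_streamlines(sset: StreamlineSet, path: str | Path) -> Path:
    """Write the whitespace-delimited text dialect.

    One ``x y z`` point (mm) per line; a blank line separates streamlines;
    ``#`` lines are comments. The first comment records the control id.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# control_id: {sset.control_id}\n")
        for i, line in enumerate(sset.streamlines):
            if i:
                fh.write("\n")
            for pt in line:
                fh.write(f"{pt[0]:.6f} {pt[1]:.6f} {pt[2]:.6f}\n")
    return path


def read_streamlines(path: str | Path) -> StreamlineSet:
    """Read streamlines from the text dialect or a TRK file (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".trk":
        trk = nib.streamlines.load(str(path))
        return StreamlineSet(path.stem, [np.asarray(s) for s in trk.streamlines])
    control_id = path.stem
    lines: list[np.ndarray] = []
    current: list[list[float]] = []
    for raw in path.read_text().splitlines():
        text = raw.strip()
        if text.startswith("#"):
            if "control_id:" in text:
                control_id = text.split("control_id:", 1)[1].strip()
            continue
        if not text:
            if current:
                lines.append(np.array(current))
                current = []
            continue
        parts = text.split()
        if len(parts) != 3:
            raise ValueError(f"{path}: expected 3 coordinates, got {text!r}")
        current.append([float(v) for v in parts])
    if current:
        lines.append(np.array(current))
    return StreamlineSet(control_id, lines)
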