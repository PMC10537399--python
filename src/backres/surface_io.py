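"""Point-cloud I/O, horizontal slicing and slice regularization.

Axis convention (fixed package-wide, all units millimetres):

* ``x`` — lateral, left to right as seen from behind the subject,
* ``y`` — vertical, caudal to cranial,
* ``z`` — depth, pointing from the back surface toward the sensor.

A back capture is an unordered :class:`PointCloud`. Downstream analysis works
on horizontal slices: each slab of points around a height ``y_center`` is
reduced to a depth profile ``z = f(x)`` on a strictly uniform lateral grid
(:class:`SliceProfile`), because both the discrete Fourier transform and
digital filtering require equidistant samples. A stack of such profiles in
ascending height order is a :class:`SliceStack`.

Only ASCII file variants are supported (PLY with vertex x/y/z properties,
OBJ ``v`` lines, whitespace-delimited XYZ); binary PLY is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PointCloud",
    "SliceProfile",
    "SliceStack",
    "PointCloudError",
    "MalformedFileError",
    "TruncatedVertexListError",
    "EmptyCloudError",
    "NoUsableSlicesError",
    "load_point_cloud",
    "write_point_cloud",
    "regularize_slice",
    "slice_stack",
    "stack_to_csv",
]


class PointCloudError(ValueError):
    """Base class for point-cloud loading problems."""


class MalformedFileError(PointCloudError):
    """File header or structure cannot be parsed."""


class TruncatedVertexListError(PointCloudError):
    """PLY header announces more vertices than the file contains."""


class EmptyCloudError(PointCloudError):
    """File parsed but contains no points."""


class NoUsableSlicesError(ValueError):
    """Slicing produced no slice with enough usable samples."""


@dataclass
class PointCloud:
    """Unordered 3D points (mm) of one back capture.

    Parameters
    ----------
    points
        ``(N, 3)`` float array of (x, y, z) in the package axis convention.
    source_id
        Free-text label (file stem, synthetic-subject id, ...).
    metadata
        Optional ground-truth annotations; the synthetic generator stores the
        true symmetry-axis curve and frequency cap here for oracle use.
    """

    points: np.ndarray
    source_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass
class SliceProfile:
    """One horizontal slice regularized to a uniform lateral grid.

    The i-th abscissa is exactly ``x0 + i * dx``. ``missing`` marks grid
    cells without supporting data (True = missing); operations that require
    a gap-free series raise if any cell is missing.
    """

    y_center: float
    x0: float
    dx: float
    z: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 1:
            raise ValueError("z must be one-dimensional")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.missing is None:
            self.missing = np.zeros(self.z.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.z.shape:
                raise ValueError("missing mask and z must have the same length")

    @property
    def n(self) -> int:
        return self.z.size

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(~self.missing))

    @property
    def x(self) -> np.ndarray:
        """Grid abscissae, exactly ``x0 + i * dx``."""
        return self.x0 + self.dx * np.arange(self.n)

    @property
    def is_contiguous(self) -> bool:
        """True when no grid cell is missing."""
        return not bool(self.missing.any())

    def copy_with(self, z: np.ndarray | None = None,
                  missing: np.ndarray | None = None) -> "SliceProfile":
        return SliceProfile(
            y_center=self.y_center,
            x0=self.x0,
            dx=self.dx,
            z=self.z.copy() if z is None else np.asarray(z, dtype=float),
            missing=self.missing.copy() if missing is None else np.asarray(missing, dtype=bool),
        )


@dataclass
class SliceStack:
    """Slices of one capture ordered by ascending ``y_center``."""

    slices: list[SliceProfile]
    slab_thickness: float
    slab_spacing: float
    source_id: str = ""

    def __post_init__(self) -> None:
        ys = [s.y_center for s in self.slices]
        if any(b <= a for a, b in zip(ys, ys[1:])):
            raise ValueError("slice y_centers must be strictly increasing")
        dxs = {s.dx for s in self.slices}
        if len(dxs) > 1:
            raise ValueError("all slices must share the same dx")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def y_centers(self) -> np.ndarray:
        return np.array([s.y_center for s in self.slices])

    @property
    def dx(self) -> float:
        return self.slices[0].dx


# ---------------------------------------------------------------------------
# Readers / writers (ASCII only)
# ---------------------------------------------------------------------------

def _parse_xyz(text: str, path: Path) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 3:
            raise MalformedFileError(
                f"{path}: line {lineno} has fewer than 3 columns")
        try:
            rows.append([float(v) for v in parts[:3]])
        except ValueError as exc:
            raise PointCloudError(
                f"{path}: non-numeric vertex row at line {lineno}") from exc
    return np.array(rows, dtype=float).reshape(-1, 3)


def _parse_obj(text: str, path: Path) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith("v "):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise MalformedFileError(
                f"{path}: vertex line {lineno} has fewer than 3 coordinates")
        try:
            rows.append([float(v) for v in parts[1:4]])
        except ValueError as exc:
            raise PointCloudError(
                f"{path}: non-numeric vertex row at line {lineno}") from exc
    return np.array(rows, dtype=float).reshape(-1, 3)


def _parse_ply(text: str, path: Path) -> np.ndarray:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MalformedFileError(f"{path}: malformed header (missing 'ply' magic)")
    n_vertices = None
    prop_names: list[str] = []
    in_vertex_element = False
    body_start = None
    for i, line in enumerate(lines[1:], start=1):
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "format":
            if len(tokens) < 2 or tokens[1] != "ascii":
                raise MalformedFileError(
                    f"{path}: only ASCII PLY is supported (got {' '.join(tokens[1:])})")
        elif tokens[0] == "element":
            in_vertex_element = tokens[1] == "vertex"
            if in_vertex_element:
                try:
                    n_vertices = int(tokens[2])
                except (IndexError, ValueError) as exc:
                    raise MalformedFileError(
                        f"{path}: malformed header (bad vertex count)") from exc
        elif tokens[0] == "property" and in_vertex_element:
            if tokens[1] == "list":
                raise MalformedFileError(
                    f"{path}: list property on vertex element is not supported")
            prop_names.append(tokens[-1])
        elif tokens[0] == "end_header":
            body_start = i + 1
            break
    if body_start is None or n_vertices is None:
        raise MalformedFileError(f"{path}: malformed header (no end_header/vertex element)")
    try:
        cols = [prop_names.index(name) for name in ("x", "y", "z")]
    except ValueError as exc:
        raise MalformedFileError(
            f"{path}: vertex element lacks x/y/z properties") from exc

    data_lines = [ln for ln in lines[body_start:] if ln.strip()]
    if len(data_lines) < n_vertices:
        raise TruncatedVertexListError(
            f"{path}: truncated vertex list "
            f"(header announces {n_vertices}, found {len(data_lines)})")
    rows = np.empty((n_vertices, 3), dtype=float)
    for i in range(n_vertices):
        parts = data_lines[i].split()
        try:
            rows[i] = [float(parts[c]) for c in cols]
        except (IndexError, ValueError) as exc:
            raise PointCloudError(
                f"{path}: non-numeric vertex row (vertex {i})") from exc
    return rows


_PARSERS = {"xyz": _parse_xyz, "obj": _parse_obj, "ply": _parse_ply}
_SUFFIXES = {".xyz": "xyz", ".txt": "xyz", ".obj": "obj", ".ply": "ply"}


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _PARSERS:
            raise ValueError(f"unknown format {fmt!r}; expected ply, obj, xyz or auto")
        return fmt
    try:
        return _SUFFIXES[path.suffix.lower()]
    except KeyError:
        raise ValueError(
            f"cannot infer format from suffix {path.suffix!r}; pass format explicitly")


def load_point_cloud(path: str | Path, fmt: str = "auto") -> PointCloud:
    """Read an ASCII point-cloud file into the package axis convention.

    Faces and normals are discarded; coordinates are taken to already be in
    millimetres with x lateral, y vertical and z toward the sensor.

    Parameters
    ----------
    path
        File to read.
    fmt
        ``"ply"``, ``"obj"``, ``"xyz"`` or ``"auto"`` (infer from suffix).

    Raises
    ------
    FileNotFoundError, MalformedFileError, TruncatedVertexListError,
    EmptyCloudError, PointCloudError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, fmt)
    points = _PARSERS[fmt](path.read_text(), path)
    if points.shape[0] == 0:
        raise EmptyCloudError(f"{path}: empty cloud")
    return PointCloud(points=points, source_id=path.stem)


def write_point_cloud(cloud: PointCloud, path: str | Path, fmt: str = "auto") -> Path:
    """Write a point cloud as ASCII PLY, OBJ or XYZ.

    Coordinates are written with enough digits for a 1e-6 mm round trip
    (PLY uses ``double`` properties for the same reason).
    """
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    pts = cloud.points
    lines: list[str]
    if fmt == "xyz":
        lines = [f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}" for p in pts]
    elif fmt == "obj":
        lines = [f"v {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}" for p in pts]
    else:
        lines = [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(pts)}",
            "property double x",
            "property double y",
            "property double z",
            "end_header",
        ] + [f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}" for p in pts]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Slicing and regularization
# ---------------------------------------------------------------------------

def regularize_slice(points_xz: np.ndarray | Iterable, dx: float,
                     max_gap: float = 3.0, y_center: float = 0.0) -> SliceProfile:
    """Resample scattered (x, z) slab points onto a uniform lateral grid.

    Points are first reduced by averaging z within each dx-wide x-bin, then
    linearly interpolated onto the uniform grid covering the slab's x-range.
    Grid cells whose nearest supporting bin is farther than ``max_gap`` are
    marked missing, and only the largest contiguous non-missing segment is
    retained (the grid is trimmed to it), because spectral analysis and
    filtering require gap-free series.

    Raises
    ------
    ValueError
        Fewer than 2 points, non-positive dx, or no cell survives.
    """
    pts = np.asarray(list(points_xz) if not isinstance(points_xz, np.ndarray)
                     else points_xz, dtype=float)
    pts = pts.reshape(-1, 2)
    if pts.shape[0] < 2:
        raise ValueError("regularize_slice needs at least 2 points")
    if dx <= 0:
        raise ValueError("dx must be positive")
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")

    x, z = pts[:, 0], pts[:, 1]
    x_min, x_max = float(x.min()), float(x.max())

    # Average z (and x) per dx-wide bin; bin abscissa = mean x of its points,
    # so already-gridded inputs pass through unchanged.
    bin_idx = np.floor((x - x_min) / dx).astype(int)
    order = np.argsort(bin_idx, kind="stable")
    bin_sorted = bin_idx[order]
    uniq, starts = np.unique(bin_sorted, return_index=True)
    xb = np.array([x[order][s:e].mean()
                   for s, e in zip(starts, np.append(starts[1:], bin_sorted.size))])
    zb = np.array([z[order][s:e].mean()
                   for s, e in zip(starts, np.append(starts[1:], bin_sorted.size))])
    srt = np.argsort(xb)
    xb, zb = xb[srt], zb[srt]

    n = int(np.floor((x_max - x_min) / dx + 1e-9)) + 1
    xg = x_min + dx * np.arange(n)
    zg = np.interp(xg, xb, zb)

    # Distance from each grid cell to its nearest supporting bin abscissa.
    pos = np.searchsorted(xb, xg)
    left = np.clip(pos - 1, 0, xb.size - 1)
    right = np.clip(pos, 0, xb.size - 1)
    dist = np.minimum(np.abs(xg - xb[left]), np.abs(xg - xb[right]))
    missing = dist > max_gap

    valid = ~missing
    if not valid.any():
        raise ValueError("regularize_slice: all grid cells missing")
    # Largest contiguous run of valid cells.
    padded = np.concatenate(([False], valid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    run_starts, run_ends = edges[::2], edges[1::2]
    best = int(np.argmax(run_ends - run_starts))
    s, e = int(run_starts[best]), int(run_ends[best])

    return SliceProfile(
        y_center=float(y_center),
        x0=float(xg[s]),
        dx=float(dx),
        z=zg[s:e],
        missing=np.zeros(e - s, dtype=bool),
    )


def slice_stack(cloud: PointCloud, slab_thickness: float = 5.0,
                slab_spacing: float = 10.0, dx: float = 0.5,
                max_gap: float = 3.0, min_samples: int = 8) -> SliceStack:
    """Cut a back capture into horizontal slabs and regularize each slab.

    Slab centers span ``[y_min + thickness/2, y_max - thickness/2]`` at
    ``slab_spacing`` steps. Each slab's points (all points within ±thickness/2
    of the center) are regularized via :func:`regularize_slice`; slabs that
    end up with fewer than ``min_samples`` usable grid cells are dropped and
    logged.

    Raises
    ------
    NoUsableSlicesError
        When no slab survives.
    """
    if slab_thickness <= 0:
        raise ValueError("slab_thickness must be positive")
    if slab_spacing < slab_thickness / 2:
        raise ValueError("slab_spacing must be at least slab_thickness / 2")
    if dx <= 0:
        raise ValueError("dx must be positive")
    if len(cloud) < 3:
        raise ValueError("point cloud has fewer than 3 points")

    y_min, y_max = float(cloud.y.min()), float(cloud.y.max())
    lo, hi = y_min + slab_thickness / 2, y_max - slab_thickness / 2
    if lo > hi:
        # Degenerate extent (e.g. planar cloud): single slab at mid-height.
        centers = np.array([(y_min + y_max) / 2])
    else:
        centers = lo + slab_spacing * np.arange(int((hi - lo) / slab_spacing + 1e-9) + 1)

    slices: list[SliceProfile] = []
    for c in centers:
        in_slab = np.abs(cloud.y - c) <= slab_thickness / 2
        if np.count_nonzero(in_slab) < 2:
            logger.debug("slab at y=%.1f dropped: <2 points", c)
            continue
        try:
            prof = regularize_slice(cloud.points[in_slab][:, [0, 2]], dx=dx,
                                    max_gap=max_gap, y_center=float(c))
        except ValueError:
            logger.debug("slab at y=%.1f dropped: regularization failed", c)
            continue
        if prof.n_valid < min_samples:
            logger.debug("slab at y=%.1f dropped: %d < %d usable samples",
                         c, prof.n_valid, min_samples)
            continue
        slices.append(prof)

    if not slices:
        raise NoUsableSlicesError("no usable slices")
    return SliceStack(slices=slices, slab_thickness=float(slab_thickness),
                      slab_spacing=float(slab_spacing), source_id=cloud.source_id)


def stack_to_csv(stack: SliceStack, path: str | Path) -> Path:
    """Export a slice stack as tidy CSV (slice_index, y_center, x, z, missing)."""
    frames = []
    for i, s in enumerate(stack.slices):
        frames.append(pd.DataFrame({
            "slice_index": i,
            "y_center": s.y_center,
            "x": s.x,
            "z": s.z,
            "missing": s.missing.astype(int),
        }))
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
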