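"""Data model and I/O for wall-motion grids, quad meshes and point clouds.

A 4D-ultrasound speckle-tracking export describes the aneurysm wall as a
structured grid of material points: ``n`` rings ("heights") along the vessel
of 36 circumferential points each, with one Cartesian position (mm) per point
and cardiac-cycle frame.  Frame 0 is end-diastole and serves as the reference
configuration for all strain computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MotionGrid",
    "QuadMesh",
    "PointCloud",
    "Axis",
    "CylindricalCoords",
    "read_motion_grid",
    "write_motion_grid",
    "trim_pseudo_apex",
    "build_quad_mesh",
    "read_point_cloud",
    "write_point_cloud",
    "fit_axis",
    "to_cylindrical",
    "from_cylindrical",
]


@dataclass
class MotionGrid:
    """Structured (T, n, m, 3) material-point trajectories of one segmentation.

    Parameters
    ----------
    positions
        Array of shape ``(T, n, m, 3)`` in mm.  ``T`` frames over one cardiac
        cycle (frame 0 = end-diastole), ``n`` heights along the vessel axis,
        ``m`` circumferential points per height (36 in the standard export).
    frame_times
        Optional acquisition time of each frame in seconds.
    """

    positions: np.ndarray
    frame_times: np.ndarray | None = None
    patient_id: str = ""
    segmentation_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 4 or self.positions.shape[-1] != 3:
            raise ValueError(
                f"positions must have shape (T, n, m, 3), got {self.positions.shape}"
            )
        T, n, m, _ = self.positions.shape
        if T < 2:
            raise ValueError(f"need at least 2 frames, got {T}")
        if not 2 <= n <= 36:
            raise ValueError(f"number of heights must be in [2, 36], got {n}")
        if m < 3:
            raise ValueError(f"need at least 3 circumferential points, got {m}")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (T,):
                raise ValueError("frame_times must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_heights(self) -> int:
        return self.positions.shape[1]

    @property
    def n_circ(self) -> int:
        return self.positions.shape[2]

    def frame(self, t: int) -> np.ndarray:
        """Positions at frame ``t`` as an ``(n, m, 3)`` array."""
        return self.positions[t]

    def nodes(self, t: int = 0) -> np.ndarray:
        """Positions at frame ``t`` flattened to ``(n*m, 3)`` (row-major in i, j)."""
        return self.positions[t].reshape(-1, 3)


@dataclass
class QuadMesh:
    """Quadrilateral connectivity of a motion grid, closed circumferentially.

    Element ``(i, j)`` connects nodes ``(i,j), (i,j+1), (i+1,j+1), (i+1,j)``
    with ``j+1`` taken modulo the circumferential count, so column ``m-1``
    wraps back to column 0.  Node ids are ``i * m + j``.
    """

    n_heights: int
    n_circ: int
    elements: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_heights < 2:
            raise ValueError("mesh needs at least 2 heights")
        n, m = self.n_heights, self.n_circ
        i, j = np.meshgrid(np.arange(n - 1), np.arange(m), indexing="ij")
        jp = (j + 1) % m
        self.elements = np.stack(
            [i * m + j, i * m + jp, (i + 1) * m + jp, (i + 1) * m + j], axis=-1
        ).reshape(-1, 4)

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def node_id(self, i: int, j: int) -> int:
        return i * self.n_circ + j

    def element_id(self, i: int, j: int) -> int:
        return i * self.n_circ + j

    def element_ij(self, e: int) -> tuple[int, int]:
        return divmod(e, self.n_circ)

    def element_nodes(self, positions: np.ndarray) -> np.ndarray:
        """Gather node coordinates per element: (n*m, 3) -> (E, 4, 3)."""
        return positions.reshape(-1, 3)[self.elements]


@dataclass
class PointCloud:
    """Unordered 3D point set in mm, tagged by its imaging origin."""

    points: np.ndarray
    label: str = "wall"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (m, 3), got {self.points.shape}")
        if self.points.shape[0] < 1:
            raise ValueError("point cloud is empty")
        if not np.isfinite(self.points).all():
            raise ValueError("points contain non-finite values")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class Axis:
    """Straight reference axis for the cylindrical unwrap."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("axis direction must be nonzero")
        object.__setattr__(self, "direction", d / nrm)

    def flipped(self) -> "Axis":
        return Axis(self.origin, -self.direction)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic right-handed in-plane basis (u, v) with v = d x u."""
        d = self.direction
        k = int(np.argmin(np.abs(d)))
        e = np.zeros(3)
        e[k] = 1.0
        u = e - np.dot(e, d) * d
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return u, v


@dataclass
class CylindricalCoords:
    """Cylindrical coordinates (x_long, phi, R) of a point set about an axis."""

    x_long: np.ndarray
    phi: np.ndarray
    R: np.ndarray
    axis: Axis


# ---------------------------------------------------------------------------
# Motion-grid I/O (delimited text, header "frame,i,j,x,y,z")
# ---------------------------------------------------------------------------

_COLUMNS = ["frame", "i", "j", "x", "y", "z"]


def read_motion_grid(
    path: str | Path,
    patient_id: str = "",
    segmentation_id: str = "",
) -> MotionGrid:
    """Read a motion grid from a delimited table with columns frame,i,j,x,y,z.

    Every (frame, i, j) triple must be present exactly once; indices are
    0-based and must form complete ranges.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
        raise ValueError(f"{path}: non-finite coordinate values")
    T = int(df["frame"].max()) + 1
    n = int(df["i"].max()) + 1
    m = int(df["j"].max()) + 1
    if df["frame"].min() < 0 or df["i"].min() < 0 or df["j"].min() < 0:
        raise ValueError(f"{path}: negative indices")
    positions = np.full((T, n, m, 3), np.nan)
    t_idx = df["frame"].to_numpy(dtype=int)
    i_idx = df["i"].to_numpy(dtype=int)
    j_idx = df["j"].to_numpy(dtype=int)
    if len(df) != len(set(zip(t_idx, i_idx, j_idx))):
        raise ValueError(f"{path}: duplicate (frame, i, j) rows")
    positions[t_idx, i_idx, j_idx] = df[["x", "y", "z"]].to_numpy()
    absent = np.argwhere(np.isnan(positions[..., 0]))
    if absent.size:
        t, i, j = absent[0]
        raise ValueError(f"{path}: missing grid cell (frame={t}, i={i}, j={j})")
    return MotionGrid(positions, patient_id=patient_id, segmentation_id=segmentation_id)


def write_motion_grid(grid: MotionGrid, path: str | Path) -> None:
    """Write a motion grid as CSV; round-trips bit-identically via repr precision."""
    T, n, m, _ = grid.positions.shape
    t, i, j = np.meshgrid(np.arange(T), np.arange(n), np.arange(m), indexing="ij")
    df = pd.DataFrame(
        {
            "frame": t.ravel(),
            "i": i.ravel(),
            "j": j.ravel(),
            "x": grid.positions[..., 0].ravel(),
            "y": grid.positions[..., 1].ravel(),
            "z": grid.positions[..., 2].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def trim_pseudo_apex(grid: MotionGrid, drop_rows: set[int] | frozenset[int]) -> MotionGrid:
    """Remove the artificial cap rows produced by the tracking software's masking.

    ``drop_rows`` must be a contiguous run of height indices at one or both
    ends of the grid (dropping interior rows would break mesh connectivity).
    """
    drop = sorted(int(r) for r in drop_rows)
    n = grid.n_heights
    if not drop:
        return MotionGrid(
            grid.positions.copy(),
            frame_times=grid.frame_times,
            patient_id=grid.patient_id,
            segmentation_id=grid.segmentation_id,
        )
    if any(r < 0 or r >= n for r in drop):
        raise ValueError(f"drop rows out of range [0, {n})")
    keep = [i for i in range(n) if i not in set(drop)]
    if len(keep) < 2:
        raise ValueError("at least 2 heights must remain after trimming")
    # kept rows must themselves be a contiguous run, i.e. drops sit at the ends
    if keep != list(range(keep[0], keep[-1] + 1)):
        raise ValueError(
            "drop_rows must form contiguous runs at the ends of the height range"
        )
    return MotionGrid(
        grid.positions[:, keep[0] : keep[-1] + 1].copy(),
        frame_times=grid.frame_times,
        patient_id=grid.patient_id,
        segmentation_id=grid.segmentation_id,
    )


def build_quad_mesh(grid: MotionGrid) -> QuadMesh:
    """Quadrilateral connectivity of a grid: (n-1) x m elements, closed in j."""
    return QuadMesh(grid.n_heights, grid.n_circ)


# ---------------------------------------------------------------------------
# Point-cloud I/O
# ---------------------------------------------------------------------------


def read_point_cloud(path: str | Path, label: str = "wall") -> PointCloud:
    """Read an XYZ text file or a PLY file (ASCII or binary) as a point cloud."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        import trimesh

        loaded = trimesh.load(str(path), process=False)
        pts = np.asarray(loaded.vertices, dtype=float)
    else:
        pts = np.loadtxt(path, ndmin=2)
        if pts.shape[1] < 3:
            raise ValueError(f"{path}: expected at least 3 columns")
        pts = pts[:, :3]
    return PointCloud(pts, label=label)


def write_point_cloud(cloud: PointCloud, path: str | Path) -> None:
    """Write a point cloud as XYZ text or ASCII PLY depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        import trimesh

        trimesh.PointCloud(cloud.points).export(str(path), file_type="ply")
    else:
        np.savetxt(path, cloud.points, fmt="%.17g")


# ---------------------------------------------------------------------------
# Axis fitting and cylindrical transform
# ---------------------------------------------------------------------------


def fit_axis(points: PointCloud | np.ndarray) -> Axis:
    """Straight vessel axis: first principal direction of the node cloud.

    The sign is fixed deterministically: the direction has a positive
    component along the global coordinate axis of greatest extent.
    """
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points, float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points to fit an axis")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    extent = np.ptp(pts, axis=0)
    if np.max(extent) < 1e-12:
        raise ValueError("degenerate point set: all points coincide")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    k = int(np.argmax(extent))
    if direction[k] < 0:
        direction = -direction
    elif direction[k] == 0 and direction[int(np.argmax(np.abs(direction)))] < 0:
        direction = -direction
    return Axis(centroid, direction)


def to_cylindrical(points: np.ndarray, axis: Axis) -> CylindricalCoords:
    """Cylindrical coordinates about ``axis``.

    ``x_long`` is the signed projection onto the axis direction, ``R`` the
    distance to the axis and ``phi`` the angle in a fixed right-handed frame
    built deterministically from the axis direction; ``phi`` lies in
    (-pi, pi] and is 0 by convention on the axis.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u, v = axis.basis()
    w = pts - axis.origin
    x_long = w @ axis.direction
    a = w @ u
    b = w @ v
    R = np.hypot(a, b)
    phi = np.arctan2(b, a)
    phi = np.where(R == 0, 0.0, phi)
    phi = np.where(phi <= -np.pi, np.pi, phi)  # branch cut (-pi, pi]
    if np.asarray(points).ndim == 1:
        return CylindricalCoords(x_long[0], phi[0], R[0], axis)
    return CylindricalCoords(x_long, phi, R, axis)


def from_cylindrical(coords: CylindricalCoords) -> np.ndarray:
    """Inverse of :func:`to_cylindrical`."""
    u, v = coords.axis.basis()
    x = np.atleast_1d(np.asarray(coords.x_long, dtype=float))
    phi = np.atleast_1d(np.asarray(coords.phi, dtype=float))
    R = np.atleast_1d(np.asarray(coords.R, dtype=float))
    pts = (
        coords.axis.origin
        + np.outer(x, coords.axis.direction)
        + np.outer(R * np.cos(phi), u)
        + np.outer(R * np.sin(phi), v)
    )
    if np.asarray(coords.x_long).ndim == 0:
        return pts[0]
    return pts
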