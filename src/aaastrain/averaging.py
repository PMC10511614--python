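"""Averaged wall-motion models from multiple segmentations of one acquisition.

Each manual segmentation of the same 4D-ultrasound recording yields its own
motion grid, with its own node count and its own random masking error.  To
average them without producing a distorted mesh, all reference geometries are
unwrapped into a common cylindrical (x, phi) plane, a homogeneous grid of
target coordinates is laid over the axial overlap, and each target is
anchored inside a host quadrilateral of every segmentation by inverse
bilinear mapping.  The anchored point then rides on its host element through
the cardiac cycle via the element's linear shape functions, and the averaged
model is the arithmetic mean of the tracked trajectories over segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Axis, MotionGrid, QuadMesh, build_quad_mesh, fit_axis, to_cylindrical

__all__ = [
    "NODE_RS",
    "shape_functions",
    "shape_function_derivatives",
    "inverse_bilinear",
    "UnwrappedSurface",
    "interpolate_reference_surface",
    "HomogeneousGrid",
    "HomogeneousAnchor",
    "AveragedModel",
    "make_homogeneous_grid",
    "locate_in_element",
    "track_homogeneous_points",
    "average_models",
    "build_averaged_model",
    "acquisition_axis",
]

#: local (r, s) coordinates of the four element nodes, matching the stored
#: node order (i,j), (i,j+1), (i+1,j+1), (i+1,j)
NODE_RS = np.array([(-1.0, -1.0), (1.0, -1.0), (1.0, 1.0), (-1.0, 1.0)])

_RS_TOL = 1e-6  # tolerance on |r|,|s| <= 1 for point-in-element acceptance


def shape_functions(r, s) -> np.ndarray:
    """Bilinear quadrilateral shape functions N_a(r, s) = 1/4 (1+r r_a)(1+s s_a).

    Returns an array of 4 weights (last axis) that sum to 1 exactly.
    """
    r = np.asarray(r, dtype=float)[..., None]
    s = np.asarray(s, dtype=float)[..., None]
    return 0.25 * (1.0 + r * NODE_RS[:, 0]) * (1.0 + s * NODE_RS[:, 1])


def shape_function_derivatives(r, s) -> np.ndarray:
    """Derivatives dN_a/d(r,s); shape (..., 2, 4), row 0 = d/dr, row 1 = d/ds."""
    r = np.asarray(r, dtype=float)[..., None]
    s = np.asarray(s, dtype=float)[..., None]
    dr = 0.25 * NODE_RS[:, 0] * (1.0 + s * NODE_RS[:, 1])
    ds = 0.25 * NODE_RS[:, 1] * (1.0 + r * NODE_RS[:, 0])
    return np.stack([dr, ds], axis=-2)


def inverse_bilinear(
    quad: np.ndarray,
    point: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> np.ndarray | None:
    """Local (r, s) of ``point`` inside a 2D quadrilateral, or None.

    Damped Newton iteration on the forward bilinear map; on non-convergence
    from the centroid it restarts from a 5x5 lattice of initial guesses.
    Returns (r, s) regardless of whether the point is inside the element;
    callers check |r|, |s| <= 1 + tol themselves.
    """
    quad = np.asarray(quad, dtype=float)
    point = np.asarray(point, dtype=float)

    def _newton(rs0: np.ndarray) -> np.ndarray | None:
        rs = rs0.copy()
        res = shape_functions(*rs) @ quad - point
        err = np.linalg.norm(res)
        for _ in range(max_iter):
            if err < tol:
                return rs
            J = shape_function_derivatives(*rs) @ quad  # (2,2): dP/d(r,s) rows
            try:
                step = np.linalg.solve(J.T, -res)
            except np.linalg.LinAlgError:
                return None
            lam = 1.0
            for _ in range(12):
                trial = rs + lam * step
                tres = shape_functions(*trial) @ quad - point
                terr = np.linalg.norm(tres)
                if terr < err:
                    rs, res, err = trial, tres, terr
                    break
                lam *= 0.5
            else:
                return None
        return rs if err < tol else None

    rs = _newton(np.zeros(2))
    if rs is not None:
        return rs
    for r0 in np.linspace(-0.8, 0.8, 5):
        for s0 in np.linspace(-0.8, 0.8, 5):
            rs = _newton(np.array([r0, s0]))
            if rs is not None:
                return rs
    return None


class UnwrappedSurface:
    """Reference-frame wall surface unwrapped into the (x_long, phi) plane.

    Supports point location (host element + local coordinates) and bilinear
    evaluation of position and radius anywhere inside the axial range; the
    interpolant is periodic in phi, with cut-spanning elements handled by
    duplicating them at phi +/- 2 pi.
    """

    def __init__(self, grid: MotionGrid, axis: Axis, frame: int = 0):
        self.grid = grid
        self.axis = axis
        self.mesh: QuadMesh = build_quad_mesh(grid)
        n, m = grid.n_heights, grid.n_circ
        cyl = to_cylindrical(grid.nodes(frame), axis)
        self._x = cyl.x_long.reshape(n, m)
        self._phi = cyl.phi.reshape(n, m)
        self._R = cyl.R.reshape(n, m)
        self._pos3d = grid.frame(frame).reshape(n * m, 3)

        # fold-over check: per circumferential column, x_long must increase
        # strictly with the height index
        dx = np.diff(self._x, axis=0)
        bad = np.argwhere(dx <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"surface folds over along x_long between heights {i} and {i + 1} "
                f"(column j={j})"
            )

        # per-element unwrapped 2D coordinates with phi made continuous
        # within the element (nodes shifted by 2 pi toward node 0's branch)
        elems = self.mesh.elements
        ex = self._x.ravel()[elems]
        ephi = self._phi.ravel()[elems]
        ref = ephi[:, :1]
        ephi = ephi - 2 * np.pi * np.round((ephi - ref) / (2 * np.pi))
        self._elem_xy = np.stack([ex, ephi], axis=-1)  # (E, 4, 2)
        self._elem_R = self._R.ravel()[elems]  # (E, 4)
        self._elem_pos = self._pos3d[elems]  # (E, 4, 3)

        # candidate lookup: element centers duplicated at phi - 2pi, 0, + 2pi
        centers = self._elem_xy.mean(axis=1)
        E = centers.shape[0]
        shifts = np.array([-2 * np.pi, 0.0, 2 * np.pi])
        dup = np.concatenate(
            [centers + np.array([0.0, s]) for s in shifts], axis=0
        )
        # normalize phi scale to the element size so the KD-tree metric is
        # roughly isotropic in element units
        self._sx = max(np.mean(np.ptp(ex, axis=1)), 1e-9)
        self._sphi = max(np.mean(np.ptp(ephi, axis=1)), 1e-9)
        self._tree = cKDTree(dup / np.array([self._sx, self._sphi]))
        self._dup_elem = np.tile(np.arange(E), 3)
        self._dup_shift = np.repeat(shifts, E)

    @property
    def axial_range(self) -> tuple[float, float]:
        x_mean = self._x.mean(axis=1)
        return float(x_mean[0]), float(x_mean[-1])

    @property
    def mean_axial_spacing(self) -> float:
        lo, hi = self.axial_range
        return (hi - lo) / (self.grid.n_heights - 1)

    def locate(self, x: float, phi: float, k: int = 8) -> tuple[int, float, float]:
        """Host element and local (r, s) of an unwrapped query point."""
        q = np.array([x / self._sx, phi / self._sphi])
        kq = min(k, len(self._dup_elem))
        _, idx = self._tree.query(q, k=kq)
        idx = np.atleast_1d(idx)
        best = None
        for cand in idx:
            e = int(self._dup_elem[cand])
            shift = self._dup_shift[cand]
            quad = self._elem_xy[e] + np.array([0.0, shift])
            rs = inverse_bilinear(quad, np.array([x, phi]))
            if rs is None:
                continue
            excess = max(abs(rs[0]), abs(rs[1])) - 1.0
            if excess <= _RS_TOL:
                return e, float(rs[0]), float(rs[1])
            if best is None or excess < best[0]:
                best = (excess, e, rs)
        lo, hi = self.axial_range
        if x < lo or x > hi:
            raise ValueError(
                f"query x_long={x:.3f} outside axial range [{lo:.3f}, {hi:.3f}]"
            )
        raise ValueError(f"point (x={x:.3f}, phi={phi:.3f}) lies in no element")

    def __call__(self, x: float, phi: float) -> tuple[float, np.ndarray]:
        """Interpolated (R, position) at unwrapped coordinates (x, phi).

        The radius is interpolated as a scalar field over the unwrapped
        plane and the 3D position is reconstructed from (x, phi, R), so a
        cylinder stays a cylinder: querying between nodes does not collapse
        onto the chords of the mesh.
        """
        e, r, s = self.locate(x, phi)
        w = shape_functions(r, s)
        R = float(w @ self._elem_R[e])
        u, v = self.axis.basis()
        pos = (
            self.axis.origin
            + x * self.axis.direction
            + R * np.cos(phi) * u
            + R * np.sin(phi) * v
        )
        return R, pos

    def element_quad(self, e: int) -> np.ndarray:
        return self._elem_xy[e]

    def element_positions(self, e: int) -> np.ndarray:
        return self._elem_pos[e]


def interpolate_reference_surface(grid: MotionGrid, axis: Axis) -> UnwrappedSurface:
    """Callable reference-surface interpolant (x_long, phi) -> (R, position)."""
    return UnwrappedSurface(grid, axis)


def locate_in_element(
    point_2d: tuple[float, float], surface: UnwrappedSurface
) -> tuple[int, float, float]:
    """Host element id and local (r, s) of a point in the unwrapped plane."""
    return surface.locate(point_2d[0], point_2d[1])


@dataclass
class HomogeneousAnchor:
    """Host element and local coordinates of every homogeneous point, per segmentation."""

    element: np.ndarray  # (K, P) host element ids
    rs: np.ndarray  # (K, P, 2) local coordinates in [-1, 1]


@dataclass
class HomogeneousGrid:
    """Common homogeneous re-mesh targets and per-segmentation anchors."""

    x_targets: np.ndarray  # (n_H,)
    phi_targets: np.ndarray  # (m_H,)
    ref_positions: np.ndarray  # (K, n_H * m_H, 3) anchored H^0 per segmentation
    anchors: HomogeneousAnchor
    surfaces: list[UnwrappedSurface]

    @property
    def n_heights(self) -> int:
        return len(self.x_targets)

    @property
    def n_circ(self) -> int:
        return len(self.phi_targets)


@dataclass
class AveragedModel:
    """Averaged motion model packaged as a MotionGrid, with provenance."""

    grid: MotionGrid
    sources: list[str]


def acquisition_axis(segmentations: list[MotionGrid]) -> Axis:
    """Shared unwrap axis of one acquisition.

    PCA axis of the first segmentation's reference frame, oriented so the
    height index increases along the axis direction; reused for every
    segmentation so phi is comparable across them.
    """
    first = segmentations[0]
    axis = fit_axis(first.nodes(0))
    x = to_cylindrical(first.nodes(0), axis).x_long.reshape(
        first.n_heights, first.n_circ
    )
    if x.mean(axis=1)[0] > x.mean(axis=1)[-1]:
        axis = axis.flipped()
    return axis


def make_homogeneous_grid(
    segmentations: list[MotionGrid],
    axis: Axis | None = None,
    n_H: int | None = None,
    m_H: int = 36,
) -> HomogeneousGrid:
    """Lay a uniform (x_long, phi) target grid over the common axial overlap.

    Targets are inset from the overlap boundary by half a mean axial element
    length so that every target is strictly interior to all segmentations.
    The per-segmentation reference positions H^0 and host-element anchors are
    computed by interpolation / inverse bilinear point location.
    """
    if len(segmentations) < 1:
        raise ValueError("need at least one segmentation")
    T = segmentations[0].n_frames
    if any(s.n_frames != T for s in segmentations):
        raise ValueError("all segmentations of one acquisition must share T")
    if axis is None:
        axis = acquisition_axis(segmentations)
    surfaces = [UnwrappedSurface(s, axis) for s in segmentations]
    lo = max(s.axial_range[0] for s in surfaces)
    hi = min(s.axial_range[1] for s in surfaces)
    if hi <= lo:
        raise ValueError("segmentations have empty axial overlap")
    inset = 0.5 * float(np.mean([s.mean_axial_spacing for s in surfaces]))
    if hi - lo <= 2 * inset:
        raise ValueError("axial overlap smaller than one element length")
    if n_H is None:
        n_H = min(s.n_heights for s in segmentations)
    x_targets = np.linspace(lo + inset, hi - inset, n_H)
    phi_targets = -np.pi + (np.arange(m_H) + 0.5) * 2 * np.pi / m_H

    K, P = len(segmentations), n_H * m_H
    elem = np.zeros((K, P), dtype=int)
    rs = np.zeros((K, P, 2))
    ref_positions = np.zeros((K, P, 3))
    for k, surf in enumerate(surfaces):
        u, v = axis.basis()
        p = 0
        for x in x_targets:
            for phi in phi_targets:
                e, r, s = surf.locate(x, phi)
                elem[k, p] = e
                rs[k, p] = (r, s)
                R = float(shape_functions(r, s) @ surf._elem_R[e])
                ref_positions[k, p] = (
                    axis.origin + x * axis.direction
                    + R * np.cos(phi) * u + R * np.sin(phi) * v
                )
                p += 1
    return HomogeneousGrid(
        x_targets, phi_targets, ref_positions, HomogeneousAnchor(elem, rs), surfaces
    )


def track_homogeneous_points(
    hgrid: HomogeneousGrid, segmentation_index: int
) -> np.ndarray:
    """Trajectories H^t of all homogeneous points through one segmentation.

    H^t = sum_a N_a(r_H, s_H) x^t_a over the host element's nodes; shape
    (T, P, 3).  At t = 0 this reproduces the anchored reference positions.
    """
    surf = hgrid.surfaces[segmentation_index]
    grid = surf.grid
    elems = hgrid.anchors.element[segmentation_index]
    rs = hgrid.anchors.rs[segmentation_index]
    weights = shape_functions(rs[:, 0], rs[:, 1])  # (P, 4)
    node_ids = surf.mesh.elements[elems]  # (P, 4)
    traj = grid.positions.reshape(grid.n_frames, -1, 3)[:, node_ids]  # (T, P, 4, 3)
    return np.einsum("pa,tpac->tpc", weights, traj)


def average_models(tracked: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Arithmetic mean of K homogeneous trajectories; shapes must agree."""
    shapes = {np.asarray(t).shape for t in tracked}
    if len(shapes) != 1:
        raise ValueError(f"trajectory shape mismatch: {sorted(shapes)}")
    arr = np.asarray(tracked, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected K trajectories of shape (T, P, 3)")
    return arr.mean(axis=0)


def build_averaged_model(
    segmentations: list[MotionGrid],
    axis: Axis | None = None,
    n_H: int | None = None,
    m_H: int = 36,
) -> tuple[AveragedModel, HomogeneousGrid]:
    """End-to-end averaged model: re-mesh, anchor, track, average.

    With a single segmentation the result is simply its homogeneous re-mesh,
    which is useful as the K = 1 reference when studying variance reduction.
    """
    if len(segmentations) < 1:
        raise ValueError("averaging needs at least 1 segmentation")
    hgrid = make_homogeneous_grid(segmentations, axis=axis, n_H=n_H, m_H=m_H)
    tracked = [track_homogeneous_points(hgrid, k) for k in range(len(segmentations))]
    mean = average_models(tracked)
    T = mean.shape[0]
    grid = MotionGrid(
        mean.reshape(T, hgrid.n_heights, hgrid.n_circ, 3),
        frame_times=segmentations[0].frame_times,
        patient_id=segmentations[0].patient_id,
        segmentation_id="averaged",
    )
    return AveragedModel(grid, [s.segmentation_id for s in segmentations]), hgrid
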