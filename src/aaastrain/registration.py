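"""Rigid and affine ICP registration of ultrasound geometry to a CT wall cloud.

The moving ultrasound point cloud is aligned to the static CT-derived cloud
by iterating nearest-neighbor correspondence (k-d tree) and bounded
nonlinear least squares on the transform parameters.  The rigid transform is
R_x(alpha) R_y(beta) R_z(gamma) plus a translation; the affine transform
composes a diagonal scaling, the rotation and a full shear matrix,
tau_A = M_s M_r M_h.  Parameter bounds keep the fit away from
unphysiological optima on nearly axisymmetric fusiform geometries, and the
fit is initialized by superimposing the two centroids.

Geometric agreement is quantified by the RMSE over assigned point pairs
(moving to static) and by the Hausdorff distance (largest local deviation);
both directed Hausdorff values are reported alongside the symmetric one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .core import MotionGrid, PointCloud

__all__ = [
    "RigidParams",
    "AffineParams",
    "Bounds",
    "RegistrationResult",
    "apply_transform",
    "nearest_pairs",
    "rmse",
    "hausdorff",
    "hausdorff_directed",
    "icp",
    "select_best_frame",
]


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(b: float) -> np.ndarray:
    c, s = math.cos(b), math.sin(b)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_z(g: float) -> np.ndarray:
    c, s = math.cos(g), math.sin(g)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


@dataclass
class RigidParams:
    """Rigid transform: rotation R_x(alpha) R_y(beta) R_z(gamma), then translation."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        return _rot_x(self.alpha) @ _rot_y(self.beta) @ _rot_z(self.gamma)

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.alpha, self.beta, self.gamma], self.translation])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "RigidParams":
        return cls(x[0], x[1], x[2], np.asarray(x[3:6]))


@dataclass
class AffineParams(RigidParams):
    """Affine transform tau_A = M_s M_r M_h (scale, rotation, shear) + translation."""

    scales: np.ndarray = field(default_factory=lambda: np.ones(3))
    shears: np.ndarray = field(default_factory=lambda: np.zeros(6))
    # shear order: h_xy, h_xz, h_yx, h_yz, h_zx, h_zy

    def __post_init__(self) -> None:
        super().__post_init__()
        self.scales = np.asarray(self.scales, dtype=float)
        self.shears = np.asarray(self.shears, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")

    @property
    def matrix(self) -> np.ndarray:
        Ms = np.diag(self.scales)
        hxy, hxz, hyx, hyz, hzx, hzy = self.shears
        Mh = np.array([[1, hxy, hxz], [hyx, 1, hyz], [hzx, hzy, 1]], dtype=float)
        return Ms @ self.rotation @ Mh

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.alpha, self.beta, self.gamma], self.translation, self.scales, self.shears]
        )

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "AffineParams":
        return cls(x[0], x[1], x[2], np.asarray(x[3:6]), np.asarray(x[6:9]), np.asarray(x[9:15]))


@dataclass
class Bounds:
    """Per-parameter bounds; the rough alignment of the two modalities is known,
    so the search space is kept tight to avoid unphysiological registrations."""

    max_rotation: float = math.radians(30.0)
    max_translation: float = 20.0  # mm, about the centroid-superposition init
    scale_range: tuple[float, float] = (0.8, 1.2)
    max_shear: float = 0.2

    def vectors(self, mode: str, t_center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = [-self.max_rotation] * 3 + list(t_center - self.max_translation)
        hi = [self.max_rotation] * 3 + list(t_center + self.max_translation)
        if mode == "affine":
            lo += [self.scale_range[0]] * 3 + [-self.max_shear] * 6
            hi += [self.scale_range[1]] * 3 + [self.max_shear] * 6
        return np.array(lo), np.array(hi)


@dataclass
class RegistrationResult:
    params: RigidParams | AffineParams
    final_rmse: float
    hausdorff: float
    hausdorff_moving_to_static: float
    hausdorff_static_to_moving: float
    iterations: int
    converged: bool
    rmse_trace: list[float] = field(default_factory=list)


def _points(cloud: PointCloud | np.ndarray) -> np.ndarray:
    return cloud.points if isinstance(cloud, PointCloud) else np.atleast_2d(np.asarray(cloud, float))


def apply_transform(params: RigidParams, cloud: PointCloud | np.ndarray) -> PointCloud | np.ndarray:
    """Map every point p to tau p + t.  Preserves the input container type."""
    pts = _points(cloud)
    out = pts @ params.matrix.T + params.translation
    if isinstance(cloud, PointCloud):
        return PointCloud(out, label=cloud.label)
    return out


def nearest_pairs(
    moving: PointCloud | np.ndarray,
    static: PointCloud | np.ndarray,
    tree: cKDTree | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Index of the Euclidean-nearest static point for each moving point.

    Ties (equal distance within relative 1e-12) are broken toward the lowest
    static index.  Returns (indices, distances).
    """
    mv, st = _points(moving), _points(static)
    if tree is None:
        tree = cKDTree(st)
    k = min(4, st.shape[0])
    d, idx = tree.query(mv, k=k)
    if k == 1:
        return idx.ravel().astype(int), d.ravel()
    tied = d <= d[:, :1] * (1.0 + 1e-12) + 1e-300
    best = np.where(tied, idx, st.shape[0]).min(axis=1)
    return best.astype(int), d[:, 0]


def rmse(
    moving: PointCloud | np.ndarray,
    static: PointCloud | np.ndarray,
    tree: cKDTree | None = None,
) -> float:
    """Root mean squared nearest-pair distance, moving (US) -> static (CT)."""
    _, d = nearest_pairs(moving, static, tree)
    return float(np.sqrt(np.mean(d**2)))


def hausdorff_directed(
    a: PointCloud | np.ndarray, b: PointCloud | np.ndarray, tree: cKDTree | None = None
) -> float:
    """Directed Hausdorff distance max_{p in a} min_{q in b} |p - q|."""
    _, d = nearest_pairs(a, b, tree)
    return float(d.max())


def hausdorff(a: PointCloud | np.ndarray, b: PointCloud | np.ndarray) -> float:
    """Symmetric Hausdorff distance (largest local deviation, either direction)."""
    return max(hausdorff_directed(a, b), hausdorff_directed(b, a))


def _transform_vec(x: np.ndarray, mode: str, pts: np.ndarray) -> np.ndarray:
    params = RigidParams.from_vector(x) if mode == "rigid" else AffineParams.from_vector(x)
    return pts @ params.matrix.T + params.translation


def icp(
    moving: PointCloud | np.ndarray,
    static: PointCloud | np.ndarray,
    mode: str = "rigid",
    bounds: Bounds | None = None,
    init: RigidParams | AffineParams | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    _tree: cKDTree | None = None,
) -> RegistrationResult:
    """Iterative closest point with bounded least-squares parameter updates.

    Alternates nearest-neighbor pairing with a bounded nonlinear
    least-squares fit of the transform parameters, until the RMSE changes by
    less than ``tol`` (mm) or ``max_iter`` iterations.  Initialization
    superimposes the centroids of the two clouds (unless ``init`` is given);
    translation bounds are centered on that initial translation.  In affine
    mode the fit refines from the rigid solution, which stabilizes the nine
    extra parameters.  Deterministic given its inputs.
    """
    if mode not in ("rigid", "affine"):
        raise ValueError(f"unknown mode {mode!r}")
    mv, st = _points(moving), _points(static)
    if st.shape[0] < 4:
        raise ValueError("static cloud needs at least 4 points")
    tree = _tree if _tree is not None else cKDTree(st)
    if bounds is None:
        bounds = Bounds()

    if init is None and mode == "affine":
        rigid = icp(mv, st, "rigid", bounds=bounds, max_iter=max_iter, tol=tol, _tree=tree)
        init = AffineParams(
            rigid.params.alpha,
            rigid.params.beta,
            rigid.params.gamma,
            rigid.params.translation.copy(),
        )
    if init is None:
        x = np.concatenate([np.zeros(3), st.mean(axis=0) - mv.mean(axis=0)])
        t_center = x[3:6].copy()
    else:
        if mode == "affine" and not isinstance(init, AffineParams):
            init = AffineParams(init.alpha, init.beta, init.gamma, init.translation.copy())
        x = init.to_vector()
        t_center = x[3:6].copy()
    lo, hi = bounds.vectors(mode, t_center)
    x = np.clip(x, lo, hi)

    make = RigidParams.from_vector if mode == "rigid" else AffineParams.from_vector
    trace: list[float] = []
    best_x, best_rmse = x.copy(), np.inf
    prev_rmse = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        transformed = _transform_vec(x, mode, mv)
        pair_idx, d = nearest_pairs(transformed, st, tree)
        cur_rmse = float(np.sqrt(np.mean(d**2)))
        trace.append(cur_rmse)
        if cur_rmse < best_rmse:
            best_rmse, best_x = cur_rmse, x.copy()
        if abs(prev_rmse - cur_rmse) < tol:
            converged = True
            break
        prev_rmse = cur_rmse
        target = st[pair_idx]

        def residual(xv: np.ndarray) -> np.ndarray:
            return (_transform_vec(xv, mode, mv) - target).ravel()

        try:
            sol = least_squares(
                residual, x, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            x = sol.x
        except Exception:
            break

    # final metrics at the best-found parameters
    transformed = _transform_vec(best_x, mode, mv)
    _, d = nearest_pairs(transformed, st, tree)
    final_rmse = float(np.sqrt(np.mean(d**2)))
    h_ms = float(d.max())
    h_sm = hausdorff_directed(st, transformed)
    return RegistrationResult(
        params=make(best_x),
        final_rmse=final_rmse,
        hausdorff=max(h_ms, h_sm),
        hausdorff_moving_to_static=h_ms,
        hausdorff_static_to_moving=h_sm,
        iterations=n_iter,
        converged=converged,
        rmse_trace=trace,
    )


def select_best_frame(
    frames: MotionGrid | np.ndarray,
    static: PointCloud | np.ndarray,
    mode: str = "rigid",
    bounds: Bounds | None = None,
) -> tuple[int, list[RegistrationResult]]:
    """Register every frame to the static CT cloud; return the RMSE argmin.

    The exact cardiac phase of the CT scan is unknown, so each ultrasound
    deformation state is registered independently and the frame with the
    smallest RMSE is selected (ties go to the lowest frame index).
    """
    if isinstance(frames, MotionGrid):
        frame_pts = [frames.nodes(t) for t in range(frames.n_frames)]
    else:
        arr = np.asarray(frames, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        frame_pts = [arr[t].reshape(-1, 3) for t in range(arr.shape[0])]
    if len(frame_pts) < 1:
        raise ValueError("need at least one frame")
    st = _points(static)
    tree = cKDTree(st)
    results = [icp(p, st, mode=mode, bounds=bounds, _tree=tree) for p in frame_pts]
    best = int(np.argmin([r.final_rmse for r in results]))
    return best, results
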