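"""In-plane Biot strain of wall elements over the cardiac cycle.

Strain is evaluated per quadrilateral element at its centroid integration
point, in a local frame whose 1-axis is longitudinal and 2-axis is
circumferential.  The local frame is rebuilt for every deformed
configuration, so rigid body motion of the wall drops out; the Biot tensor
eps = U - I (U the right stretch from the polar decomposition of the 2D
deformation gradient) is itself rotation-free and valid for the large
deformations a pulsating aneurysm can undergo.  Frame 0 (end-diastole) is
the reference configuration, so strains are relative to a pre-strained
in vivo state, not an unloaded one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .averaging import shape_function_derivatives
from .core import MotionGrid, QuadMesh, build_quad_mesh

__all__ = [
    "LocalFrame",
    "StrainField",
    "AmplitudeField",
    "local_frame",
    "biot_strain",
    "strain_series",
    "strain_amplitudes",
]

#: shape-function derivatives at the centroid integration point r = s = 0
_DN0 = shape_function_derivatives(0.0, 0.0)  # (2, 4)

#: element-quality cutoffs: flagged elements are excluded from the
#: distribution indices (logged, never silently dropped)
MAX_ASPECT_RATIO = 100.0
MIN_AREA_MM2 = 1e-6


@dataclass
class LocalFrame:
    """Orthonormal in-plane frame at an element centroid for one configuration."""

    e1: np.ndarray  # longitudinal unit vector(s)
    e2: np.ndarray  # circumferential unit vector(s)
    origin: np.ndarray
    frame_index: int = 0


def local_frame(nodes: np.ndarray, frame_index: int = 0) -> LocalFrame:
    """Local element frame from edge vectors, batched over leading axes.

    ``nodes`` has shape (..., 4, 3) in the stored node order (i,j), (i,j+1),
    (i+1,j+1), (i+1,j).  The circumferential axis e2 is the normalized mean
    of the two j -> j+1 edges; the longitudinal axis e1 is the mean of the two
    i -> i+1 edges, Gram-Schmidt orthogonalized against e2.  e1 . e2 = 0 holds
    even for warped (non-planar) elements.
    """
    nodes = np.asarray(nodes, dtype=float)
    c = 0.5 * ((nodes[..., 1, :] - nodes[..., 0, :]) + (nodes[..., 2, :] - nodes[..., 3, :]))
    l = 0.5 * ((nodes[..., 3, :] - nodes[..., 0, :]) + (nodes[..., 2, :] - nodes[..., 1, :]))
    cn = np.linalg.norm(c, axis=-1, keepdims=True)
    if np.any(cn < 1e-12):
        raise ValueError("degenerate element: zero circumferential edge")
    e2 = c / cn
    a = l - np.sum(l * e2, axis=-1, keepdims=True) * e2
    an = np.linalg.norm(a, axis=-1, keepdims=True)
    if np.any(an < 1e-12):
        raise ValueError("degenerate element: longitudinal edge collinear with e2")
    e1 = a / an
    return LocalFrame(e1, e2, nodes.mean(axis=-2), frame_index)


def _project_2d(nodes: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """In-plane 2D coordinates (..., 4, 2) of element nodes in a local frame."""
    d = nodes - frame.origin[..., None, :]
    return np.stack(
        [np.sum(d * frame.e1[..., None, :], axis=-1),
         np.sum(d * frame.e2[..., None, :], axis=-1)],
        axis=-1,
    )


def _sqrtm_spd_2x2(C: np.ndarray) -> np.ndarray:
    """Principal square root of symmetric positive-definite 2x2 matrices.

    Closed form U = (C + sqrt(det C) I) / sqrt(tr C + 2 sqrt(det C)); falls
    back to an eigendecomposition where the denominator is near zero.
    """
    detC = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
    trC = C[..., 0, 0] + C[..., 1, 1]
    s = np.sqrt(np.maximum(detC, 0.0))
    den_sq = trC + 2.0 * s
    eye = np.eye(2)
    safe = den_sq > 1e-12
    den = np.sqrt(np.where(safe, den_sq, 1.0))
    U = (C + s[..., None, None] * eye) / den[..., None, None]
    if not np.all(safe):
        bad = np.argwhere(~safe)
        for idx in bad:
            w, V = np.linalg.eigh(C[tuple(idx)])
            U[tuple(idx)] = (V * np.sqrt(np.maximum(w, 0.0))) @ V.T
    return U


def _deformation_gradient(ref_nodes: np.ndarray, cur_nodes: np.ndarray) -> np.ndarray:
    """In-plane deformation gradient F (..., 2, 2) at the element centroid."""
    X2 = _project_2d(ref_nodes, local_frame(ref_nodes))
    x2 = _project_2d(cur_nodes, local_frame(cur_nodes))
    # A[..., i, k] = d(coord_i)/d(rs_k): Jacobians of the bilinear maps
    A_ref = np.einsum("ka,...ai->...ik", _DN0, X2)
    A_cur = np.einsum("ka,...ai->...ik", _DN0, x2)
    return A_cur @ np.linalg.inv(A_ref)


def biot_strain(ref_nodes: np.ndarray, cur_nodes: np.ndarray) -> np.ndarray:
    """In-plane Biot strain components (eps11, eps22, eps12) of element(s).

    Both node sets are projected into their own configuration's local frame;
    the 2x2 deformation gradient F is evaluated at the centroid integration
    point r = s = 0, and eps = U - I with U = sqrt(F^T F) is expressed in the
    reference local frame (right-stretch convention).  Accepts single
    elements (4, 3) or batches (..., 4, 3).

    Raises if det F <= 0 (element inversion).
    """
    ref_nodes = np.asarray(ref_nodes, dtype=float)
    F = _deformation_gradient(ref_nodes, np.asarray(cur_nodes, dtype=float))
    detF = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(detF <= 0):
        idx = np.argwhere(np.atleast_1d(detF) <= 0)[0]
        raise ValueError(f"element inversion (det F <= 0) at batch index {tuple(idx)}")
    C = np.swapaxes(F, -1, -2) @ F
    U = _sqrtm_spd_2x2(C)
    eps = U - np.eye(2)
    return np.stack([eps[..., 0, 0], eps[..., 1, 1], eps[..., 0, 1]], axis=-1)


def _element_quality(nodes: np.ndarray) -> np.ndarray:
    """Boolean mask of well-shaped elements (aspect and area cutoffs)."""
    edges = np.stack(
        [
            nodes[..., 1, :] - nodes[..., 0, :],
            nodes[..., 2, :] - nodes[..., 3, :],
            nodes[..., 3, :] - nodes[..., 0, :],
            nodes[..., 2, :] - nodes[..., 1, :],
        ],
        axis=-2,
    )
    lengths = np.linalg.norm(edges, axis=-1)
    aspect = lengths.max(axis=-1) / np.maximum(lengths.min(axis=-1), 1e-300)
    d1 = nodes[..., 2, :] - nodes[..., 0, :]
    d2 = nodes[..., 3, :] - nodes[..., 1, :]
    area = 0.5 * np.linalg.norm(np.cross(d1, d2), axis=-1)
    return (aspect <= MAX_ASPECT_RATIO) & (area >= MIN_AREA_MM2)


@dataclass
class StrainField:
    """Per-element, per-frame in-plane Biot strain components.

    ``eps`` has shape (T, E, 3) with components (eps11, eps22, eps12);
    frame 0 is the reference and is identically zero.  ``valid`` flags
    elements passing the shape-quality cutoffs in the reference frame.
    """

    eps: np.ndarray
    mesh: QuadMesh
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.eps.shape[1], dtype=bool)


@dataclass
class AmplitudeField:
    """Per-element peak-to-peak strain amplitudes (amp11, amp22), dimensionless."""

    amp: np.ndarray  # (E, 2)
    valid: np.ndarray

    @property
    def amp11(self) -> np.ndarray:
        return self.amp[:, 0]

    @property
    def amp22(self) -> np.ndarray:
        return self.amp[:, 1]


def strain_series(grid: MotionGrid, mesh: QuadMesh | None = None) -> StrainField:
    """Biot strain of every element for every frame against frame 0."""
    if mesh is None:
        mesh = build_quad_mesh(grid)
    T = grid.n_frames
    ref = mesh.element_nodes(grid.nodes(0))
    E = ref.shape[0]
    eps = np.zeros((T, E, 3))
    for t in range(1, T):
        cur = mesh.element_nodes(grid.nodes(t))
        try:
            eps[t] = biot_strain(ref, cur)
        except ValueError as exc:
            raise ValueError(f"frame {t}: {exc}") from exc
    return StrainField(eps, mesh, _element_quality(ref))


def strain_amplitudes(strains: StrainField) -> AmplitudeField:
    """Peak-to-peak amplitude per element: max over frames minus min.

    The two components are reduced independently, so the extrema may occur
    at different time points; the reference frame's zero participates in the
    extremes.
    """
    if strains.eps.shape[0] < 2:
        raise ValueError("need at least 2 frames for amplitudes")
    amp = np.ptp(strains.eps[:, :, :2], axis=0)
    return AmplitudeField(amp, strains.valid.copy())
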