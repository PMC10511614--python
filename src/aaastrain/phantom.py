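"""Synthetic pulsating-aneurysm phantom with known ground truth.

The phantom is a fusiform tube: base radius plus a Gaussian axial bulge with
an optional circumferential asymmetry (clinically, AAAs bulge anteriorly and
are rarely perfectly axisymmetric; the asymmetry also makes rotation about
the vessel axis observable to the registration stage).  Radial pulsation
follows a raised-cosine cardiac waveform with a prescribed peak
circumferential strain; rectangular calcified patches in the (x, phi) plane
locally reduce compliance by a stiffness factor, so calcified elements
strain proportionally less.  From one phantom the generator emulates

* K noisy manual segmentations of the same acquisition, and
* a CT-like wall point cloud plus a calcification point cloud under a known
  rigid or affine transform,

so that every stage of the pipeline can be validated against exact truth.

Segmentation noise model: manual masking places the wall surface slightly
differently in each segmentation, an error that is constant over the cardiac
cycle; speckle tracking adds a much smaller, temporally smooth error to the
motion itself.  The generator therefore draws, per segmentation,

1. i.i.d. per-node masking offsets with sd ``noise_sd``, held fixed across
   frames (pure geometry error, nearly invisible to strain);
2. a smooth radial bias field of amplitude ``noise_sd / 2`` (observer-
   dependent masking), also fixed across frames;
3. local tracking jitter: temporally smooth (two Fourier modes over the
   cycle), spatially independent per node, sd ``noise_sd / 12`` — this sets
   the random scatter of single-segmentation strains;
4. regional tracking error: temporally smooth and spatially smooth
   (low-order modes in x and phi, radial direction), sd ``noise_sd / 4`` —
   speckle tracking correlates its motion estimates over roughly
   template-sized regions, so its errors appear as slowly varying
   "apparent strain" waves of the same order as the strains being
   measured, rather than white noise.

With the defaults this reproduces the reported repeatability of the
modality: single-segmentation circumferential strain IQR above 1%, averaged
mean strains in the physiologic 0.5-3% band, and regional comparisons that
are unreliable on a single segmentation yet consistent on the averaged
model, because all four components are independent between segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .averaging import shape_functions
from .core import MotionGrid, PointCloud, QuadMesh, build_quad_mesh
from .registration import AffineParams, RigidParams, apply_transform

__all__ = [
    "CalcifiedPatch",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "make_segmentations",
    "make_ct_clouds",
    "surface_point",
]


@dataclass(frozen=True)
class CalcifiedPatch:
    """Rectangle in the unwrapped (x, phi) plane with reduced compliance."""

    x_min: float
    x_max: float
    phi_min: float
    phi_max: float

    def contains(self, x: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (phi >= self.phi_min)
            & (phi <= self.phi_max)
        )


def _default_patches() -> tuple[CalcifiedPatch, ...]:
    return (
        CalcifiedPatch(12.0, 34.0, 0.2, 2.0),
        CalcifiedPatch(30.0, 52.0, -2.6, -0.8),
    )


@dataclass
class PhantomSpec:
    """Geometry, motion, tissue and noise parameters of the phantom.

    Lengths in mm, angles in radians, strains dimensionless.  The defaults
    describe a 60 mm long aneurysm of ~45 mm peak diameter sampled on a
    22 x 36 grid over 20 cardiac frames, with ~1.2% peak circumferential
    strain and calcified patches at 75% of normal compliance.
    """

    base_radius: float = 12.0
    bulge_amplitude: float = 8.0
    bulge_center: float = 30.0
    bulge_width: float = 10.0
    bulge_asymmetry: float = 0.3
    length: float = 60.0
    n_heights: int = 22
    n_circ: int = 36
    n_frames: int = 20
    peak_circ_strain: float = 0.012
    axial_strain_fraction: float = 0.0
    stiffness_factor: float = 0.75  # kappa: compliance of calcified tissue
    calcified_patches: tuple[CalcifiedPatch, ...] = field(default_factory=_default_patches)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.base_radius, self.bulge_width, self.length) <= 0:
            raise ValueError("lengths must be positive")
        if not 0 < self.stiffness_factor <= 1:
            raise ValueError("stiffness_factor must be in (0, 1]")
        if not 0 <= self.peak_circ_strain < 0.2:
            raise ValueError("peak_circ_strain must be in [0, 0.2)")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    # -- analytic fields ---------------------------------------------------

    def radius(self, x: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """End-diastolic wall radius rho(x, phi)."""
        bulge = self.bulge_amplitude * np.exp(
            -((np.asarray(x, float) - self.bulge_center) ** 2) / (2 * self.bulge_width**2)
        )
        return self.base_radius + bulge * (1.0 + self.bulge_asymmetry * np.cos(phi))

    def compliance(self, x: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Compliance map c(x, phi): stiffness_factor inside patches, else 1."""
        x = np.asarray(x, float)
        phi = np.asarray(phi, float)
        c = np.ones(np.broadcast(x, phi).shape)
        for patch in self.calcified_patches:
            c = np.where(patch.contains(x, phi), self.stiffness_factor, c)
        return c

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Raised-cosine cardiac waveform w(t) in [0, 1], w(0) = 0."""
        return 0.5 * (1.0 - np.cos(2 * np.pi * np.asarray(t, float) / self.n_frames))


def surface_point(
    spec: PhantomSpec, x: np.ndarray, phi: np.ndarray, w: float | np.ndarray
) -> np.ndarray:
    """Analytic wall position(s) at unwrapped (x, phi) and waveform value w.

    The vessel axis is the global z axis; radial pulsation scales the local
    radius by (1 + A c w) and the optional axial stretch acts about the
    vessel mid-length.
    """
    x = np.asarray(x, float)
    phi = np.asarray(phi, float)
    R = spec.radius(x, phi) * (1.0 + spec.peak_circ_strain * spec.compliance(x, phi) * w)
    xc = spec.length / 2.0
    z = xc + (x - xc) * (1.0 + spec.axial_strain_fraction * spec.peak_circ_strain * w)
    return np.stack([R * np.cos(phi), R * np.sin(phi), np.broadcast_to(z, R.shape)], axis=-1)


def radial_residual(spec: PhantomSpec, points: np.ndarray, w: float) -> np.ndarray:
    """Signed radial distance of points from the analytic surface at waveform w.

    Evaluated in the phantom's own frame (axis = global z): for each point,
    the measured radius minus the true wall radius at the point's (z, phi).
    Because the surface is nearly radial, this is the surface-normal error up
    to a small slope factor, and it is independent of any fitted axis.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    x = pts[:, 2]
    if spec.axial_strain_fraction != 0.0:
        xc = spec.length / 2.0
        x = xc + (x - xc) / (1.0 + spec.axial_strain_fraction * spec.peak_circ_strain * w)
    R_true = spec.radius(x, phi) * (
        1.0 + spec.peak_circ_strain * spec.compliance(x, phi) * w
    )
    return np.hypot(pts[:, 0], pts[:, 1]) - R_true


@dataclass
class PhantomTruth:
    """Noise-free motion plus exact per-element ground truth."""

    spec: PhantomSpec
    grid: MotionGrid  # noise-free motion, (T, n, m, 3)
    mesh: QuadMesh
    element_amplitudes: np.ndarray  # (E, 2): true (amp11, amp22)
    element_calcified: np.ndarray  # (E,) bool
    node_x: np.ndarray  # (n,) axial grid
    node_phi: np.ndarray  # (m,) circumferential grid


def _node_grid(spec: PhantomSpec, n: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    n = spec.n_heights if n is None else n
    x = np.linspace(0.0, spec.length, n)
    phi = -np.pi + 2 * np.pi * np.arange(spec.n_circ) / spec.n_circ
    return x, phi


def _motion_positions(spec: PhantomSpec, x: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Noise-free (T, n, m, 3) positions on an arbitrary axial grid."""
    X, PHI = np.meshgrid(x, phi, indexing="ij")
    w = spec.waveform(np.arange(spec.n_frames))
    return np.stack([surface_point(spec, X, PHI, wt) for wt in w], axis=0)


def _edge_ratio(a0, b0, a1, b1) -> np.ndarray:
    return np.linalg.norm(a1 - b1, axis=-1) / np.linalg.norm(a0 - b0, axis=-1)


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build the noise-free phantom and its exact per-element ground truth.

    True peak-to-peak amplitudes are computed from chord-length ratios of
    the element edges between the waveform extremes (w = 0 and w = 1), an
    arithmetic construction independent of the shape-function strain path.
    An element counts as calcified when all four of its nodes lie inside a
    calcified patch.
    """
    x, phi = _node_grid(spec)
    positions = _motion_positions(spec, x, phi)
    grid = MotionGrid(positions, patient_id="phantom", segmentation_id="truth")
    mesh = build_quad_mesh(grid)

    X, PHI = np.meshgrid(x, phi, indexing="ij")
    p0 = surface_point(spec, X, PHI, 0.0).reshape(-1, 3)[mesh.elements]
    p1 = surface_point(spec, X, PHI, 1.0).reshape(-1, 3)[mesh.elements]
    circ = 0.5 * (
        _edge_ratio(p0[:, 1], p0[:, 0], p1[:, 1], p1[:, 0])
        + _edge_ratio(p0[:, 2], p0[:, 3], p1[:, 2], p1[:, 3])
    )
    longi = 0.5 * (
        _edge_ratio(p0[:, 3], p0[:, 0], p1[:, 3], p1[:, 0])
        + _edge_ratio(p0[:, 2], p0[:, 1], p1[:, 2], p1[:, 1])
    )
    amp = np.stack([longi - 1.0, circ - 1.0], axis=-1)

    node_calc = spec.compliance(X, PHI) < 1.0
    calcified = node_calc.ravel()[mesh.elements].all(axis=1)
    return PhantomTruth(spec, grid, mesh, amp, calcified, x, phi)


def _smooth_bias_field(
    rng: np.random.Generator, x: np.ndarray, phi: np.ndarray, amplitude: float
) -> np.ndarray:
    """Smooth random radial field with pointwise sd ``amplitude`` (n, m)."""
    X, PHI = np.meshgrid(x, phi, indexing="ij")
    u = 2 * np.pi * X / max(x.max() - x.min(), 1e-9)
    modes = [
        np.ones_like(X),
        np.sqrt(2) * np.cos(PHI),
        np.sqrt(2) * np.sin(PHI),
        np.sqrt(2) * np.cos(u),
        np.sqrt(2) * np.sin(u),
        2.0 * np.cos(PHI) * np.cos(u),
    ]
    coeffs = rng.normal(0.0, amplitude / np.sqrt(len(modes)), size=len(modes))
    return sum(c * m for c, m in zip(coeffs, modes))


def _tracking_noise(
    rng: np.random.Generator, T: int, n: int, m: int, sd: float, n_modes: int = 2
) -> np.ndarray:
    """Temporally smooth, spatially independent noise (T, n, m, 3), pointwise sd ``sd``."""
    t = np.arange(T)
    out = np.zeros((T, n, m, 3))
    for k in range(1, n_modes + 1):
        a = rng.normal(0.0, sd / np.sqrt(2 * n_modes), size=(n, m, 3))
        b = rng.normal(0.0, sd / np.sqrt(2 * n_modes), size=(n, m, 3))
        ct = np.cos(2 * np.pi * k * t / T)[:, None, None, None]
        st = np.sin(2 * np.pi * k * t / T)[:, None, None, None]
        out += np.sqrt(2.0) * (a[None] * ct + b[None] * st)
    return out


def _regional_tracking_noise(
    rng: np.random.Generator,
    x: np.ndarray,
    phi: np.ndarray,
    T: int,
    sd: float,
    n_modes: int = 2,
) -> np.ndarray:
    """Temporally and spatially smooth radial noise field (T, n, m), sd ``sd``.

    Each temporal Fourier mode carries an independent smooth spatial field,
    mimicking the region-scale correlation of speckle-tracking errors.
    """
    t = np.arange(T)
    out = np.zeros((T, len(x), len(phi)))
    for k in range(1, n_modes + 1):
        gc = _smooth_bias_field(rng, x, phi, sd / np.sqrt(2 * n_modes))
        gs = _smooth_bias_field(rng, x, phi, sd / np.sqrt(2 * n_modes))
        ct = np.cos(2 * np.pi * k * t / T)[:, None, None]
        st = np.sin(2 * np.pi * k * t / T)[:, None, None]
        out += np.sqrt(2.0) * (gc[None] * ct + gs[None] * st)
    return out


def make_segmentations(
    truth: PhantomTruth,
    K: int = 10,
    noise_sd: float | None = None,
    heights: list[int] | None = None,
    seed: int | None = None,
) -> list[MotionGrid]:
    """Emulate K manual segmentations of one acquisition.

    Each segmentation re-evaluates the phantom on its own axial grid (the
    observers' masks need not contain the same number of rings) and adds
    the three noise components described in the module docstring.  With
    ``noise_sd = 0`` and equal grid dimensions the segmentations are exact
    copies of the truth.  Reproducible from ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    spec = truth.spec
    sd = spec.noise_sd if noise_sd is None else float(noise_sd)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    heights = heights or [spec.n_heights] * K
    if len(heights) != K:
        raise ValueError("heights must list one grid size per segmentation")
    out = []
    for k in range(K):
        x, phi = _node_grid(spec, heights[k])
        pos = _motion_positions(spec, x, phi)
        T, n, m, _ = pos.shape
        if sd > 0:
            masking = rng.normal(0.0, sd, size=(n, m, 3))
            bias = _smooth_bias_field(rng, x, phi, sd / 2.0)
            X, PHI = np.meshgrid(x, phi, indexing="ij")
            radial = np.stack([np.cos(PHI), np.sin(PHI), np.zeros_like(X)], axis=-1)
            pos = pos + masking[None] + (bias[..., None] * radial)[None]
            # tracking errors scale with the local radius so their apparent
            # strain is homogeneous over the surface (no geometric confound
            # between wide and narrow vessel sections)
            rho_rel = spec.radius(X, PHI)
            rho_rel = rho_rel / rho_rel.mean()
            pos = pos + _tracking_noise(rng, T, n, m, sd / 12.0) * rho_rel[None, :, :, None]
            regional = _regional_tracking_noise(rng, x, phi, T, sd / 4.0) * rho_rel[None]
            pos = pos + regional[..., None] * radial[None]
        out.append(
            MotionGrid(pos, patient_id="phantom", segmentation_id=f"seg{k:02d}")
        )
    return out


def make_ct_clouds(
    truth: PhantomTruth,
    frame: int | None = None,
    wall_density: float = 2.0,
    calc_density: float = 8.0,
    transform: RigidParams | AffineParams | None = None,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PointCloud, PointCloud | None]:
    """CT-like wall and calcification point clouds under a known transform.
    The calcification cloud is None when the phantom has no calcified elements.

    Points are sampled uniformly per unit area on the truth surface at the
    chosen frame (default: quarter cycle, an unknown mid-inflation CT phase);
    calcification points are sampled only on calcified elements.  Both
    clouds are mapped by ``transform`` (identity if None) and jittered with
    isotropic Gaussian noise of sd ``jitter_sd``.
    """
    grid = truth.grid
    t = grid.n_frames // 4 if frame is None else int(frame)
    if not 0 <= t < grid.n_frames:
        raise ValueError(f"frame {t} outside [0, {grid.n_frames})")
    rng = np.random.default_rng(seed)
    nodes = truth.mesh.element_nodes(grid.nodes(t))  # (E, 4, 3)
    d1 = nodes[:, 2] - nodes[:, 0]
    d2 = nodes[:, 3] - nodes[:, 1]
    areas = 0.5 * np.linalg.norm(np.cross(d1, d2), axis=-1)

    def _sample(elem_mask: np.ndarray, density: float) -> np.ndarray:
        a = areas * elem_mask
        total = a.sum()
        n_pts = max(int(round(density * total)), 1)
        elems = rng.choice(len(a), size=n_pts, p=a / total)
        r = rng.uniform(-1, 1, size=n_pts)
        s = rng.uniform(-1, 1, size=n_pts)
        w = shape_functions(r, s)  # (n_pts, 4)
        return np.einsum("pa,pac->pc", w, nodes[elems])

    wall = _sample(np.ones(len(areas)), wall_density)
    if truth.element_calcified.any():
        calc = _sample(truth.element_calcified.astype(float), calc_density)
    else:
        calc = np.empty((0, 3))
    if transform is not None:
        wall = apply_transform(transform, wall)
        if len(calc):
            calc = apply_transform(transform, calc)
    if jitter_sd > 0:
        wall = wall + rng.normal(0.0, jitter_sd, size=wall.shape)
        if len(calc):
            calc = calc + rng.normal(0.0, jitter_sd, size=calc.shape)
    wall_cloud = PointCloud(wall, label="wall")
    calc_cloud = PointCloud(calc, label="calcification") if len(calc) else None
    return wall_cloud, calc_cloud
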