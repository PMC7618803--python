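"""Plane frames, axis (de)composition and pixel-to-world mapping.

A microscopy section is described by a :class:`PlaneFrame` — an orthonormal
in-plane basis (u, v) plus the plane normal n = u x v, anchored at a world-mm
origin.  Undirected 3D fibre axes are decomposed into an in-plane angle
theta in [0, pi) (measured from u towards v) and a signed through-plane
(inclination) angle alpha in (-pi/2, pi/2].  The pair (theta, alpha) is a
bijection over undirected axes once the axis is canonicalised so that its
in-plane projection falls in the upper half-plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlaneFrame",
    "AxisDecomposition",
    "PixelToWorldMap",
    "compose_axis",
    "decompose_axis",
    "map_pixels_to_world",
    "reorient_axis",
    "polar_rotation",
]

#: In-plane projection norm below which an axis counts as plane-normal.
DEGENERACY_EPS = 1e-3


@dataclass(frozen=True)
class PlaneFrame:
    """Orthonormal frame of a microscopy plane in world millimetres."""

    u: np.ndarray
    v: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if abs(np.linalg.norm(u) - 1) > 1e-9 or abs(np.linalg.norm(v) - 1) > 1e-9:
            raise ValueError("plane frame vectors must be unit length")
        if abs(np.dot(u, v)) > 1e-9:
            raise ValueError("plane frame vectors must be orthogonal")

    @property
    def n(self) -> np.ndarray:
        """Unit plane normal u x v."""
        return np.cross(self.u, self.v)

    @classmethod
    def axis_aligned(cls, normal_axis: int = 2, origin=(0.0, 0.0, 0.0)) -> "PlaneFrame":
        """Frame whose plane is perpendicular to a world coordinate axis."""
        axes = np.eye(3)
        u_ax, v_ax = [i for i in range(3) if i != normal_axis]
        return cls(u=axes[u_ax], v=axes[v_ax], origin=np.asarray(origin, float))


@dataclass
class AxisDecomposition:
    """In-plane / through-plane split of undirected axes.

    ``theta`` is undefined (set to 0) where ``degenerate`` is True, i.e. where
    the axis is within tolerance of the plane normal.
    """

    theta: np.ndarray
    alpha: np.ndarray
    degenerate: np.ndarray


def compose_axis(theta, alpha, frame: PlaneFrame) -> np.ndarray:
    """Build unit axes from in-plane angle(s) theta and inclination(s) alpha.

    axis = cos(alpha) (cos(theta) u + sin(theta) v) + sin(alpha) n
    """
    theta = np.asarray(theta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta >= np.pi + 1e-12):
        raise ValueError("theta must lie in [0, pi)")
    if np.any(alpha <= -np.pi / 2 - 1e-12) or np.any(alpha > np.pi / 2 + 1e-12):
        raise ValueError("alpha must lie in (-pi/2, pi/2]")
    ca = np.cos(alpha)
    axis = (
        (ca * np.cos(theta))[..., None] * frame.u
        + (ca * np.sin(theta))[..., None] * frame.v
        + np.sin(alpha)[..., None] * frame.n
    )
    return axis


def _canonical_flip(au, av, an):
    """Sign flip making the in-plane projection angle land in [0, pi).

    Flip when the v-component is negative, or zero with a negative
    u-component; ties (pure-normal axes) flip so the normal component is
    non-negative.  Purely sign-based so decompose(a) == decompose(-a) exactly.
    """
    flip = (av < 0) | ((av == 0) & (au < 0)) | ((av == 0) & (au == 0) & (an < 0))
    s = np.where(flip, -1.0, 1.0)
    return au * s, av * s, an * s


def decompose_axis(axis, frame: PlaneFrame, eps: float = DEGENERACY_EPS) -> AxisDecomposition:
    """Decompose undirected unit axes into (theta, alpha) in ``frame``.

    Axes whose in-plane projection norm is below ``eps`` are flagged
    degenerate: theta is reported as 0 and alpha as +pi/2.
    """
    a = np.asarray(axis, dtype=float)
    scalar = a.ndim == 1
    a = np.atleast_2d(a)
    norms = np.linalg.norm(a, axis=-1)
    if np.any(np.abs(norms - 1) > 1e-6):
        raise ValueError("axes must be unit vectors")
    au = a @ frame.u
    av = a @ frame.v
    an = a @ frame.n
    au, av, an = _canonical_flip(au, av, an)
    proj = np.hypot(au, av)
    degenerate = proj < eps
    theta = np.where(degenerate, 0.0, np.arctan2(av, au))
    # arctan2 returns pi only for av == 0, au < 0 which the flip excludes
    theta = np.mod(theta, np.pi)
    alpha = np.where(degenerate, np.pi / 2, np.arctan2(an, proj))
    if scalar:
        return AxisDecomposition(theta[0], alpha[0], degenerate[0])
    return AxisDecomposition(theta, alpha, degenerate)


def reorient_axis(axis, rotation) -> np.ndarray:
    """Apply orthonormal rotation(s) to axes and renormalise.

    ``rotation`` may be a single 3x3 matrix (applied to all axes) or a
    stack matching the leading shape of ``axis``.
    """
    a = np.asarray(axis, dtype=float)
    R = np.asarray(rotation, dtype=float)
    if R.ndim == 2:
        out = a @ R.T
    else:
        out = np.einsum("...ij,...j->...i", R, a)
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def polar_rotation(mats: np.ndarray) -> np.ndarray:
    """Rotation factor of the polar decomposition of a stack of 3x3 matrices.

    Determinant is forced to +1 (a reflection in the smallest singular
    direction is absorbed), so outputs are proper rotations.
    """
    M = np.asarray(mats, dtype=float)
    single = M.ndim == 2
    M = M.reshape((-1, 3, 3))
    U, _, Vt = np.linalg.svd(M)
    det = np.linalg.det(np.einsum("nij,njk->nik", U, Vt))
    U = U.copy()
    U[:, :, -1] *= np.sign(det)[:, None]
    R = np.einsum("nij,njk->nik", U, Vt)
    return R[0] if single else R.reshape(mats.shape)


@dataclass
class PixelToWorldMap:
    """World positions and local vector rotations for a 2D pixel grid.

    ``rotations`` is either a single 3x3 matrix (pure affine transforms) or a
    per-pixel (rows, cols, 3, 3) stack; ``valid`` flags pixels that mapped
    inside the transform domain.
    """

    positions: np.ndarray
    rotations: np.ndarray
    valid: np.ndarray

    def rotation_at(self, r: int, c: int) -> np.ndarray:
        if self.rotations.ndim == 2:
            return self.rotations
        return self.rotations[r, c]


def _base_positions(shape, pixel_size, frame: PlaneFrame) -> np.ndarray:
    rows, cols = shape
    dr, dc = pixel_size
    if dr <= 0 or dc <= 0:
        raise ValueError("pixel sizes must be positive")
    r = np.arange(rows, dtype=float) * dr
    c = np.arange(cols, dtype=float) * dc
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return (
        frame.origin
        + rr[..., None] * frame.u
        + cc[..., None] * frame.v
    )


def map_pixels_to_world(
    shape,
    pixel_size,
    frame: PlaneFrame,
    affine: np.ndarray | None = None,
    displacement: np.ndarray | None = None,
    displacement_affine: np.ndarray | None = None,
) -> PixelToWorldMap:
    """Map pixel centres of a section into world space.

    Parameters
    ----------
    shape : (rows, cols)
    pixel_size : (drow, dcol) in mm
    frame : section plane frame (pixel (r, c) sits at origin + r*drow*u + c*dcol*v)
    affine : optional 4x4 world affine applied on top of the plane embedding
    displacement, displacement_affine : optional dense displacement field
        (X, Y, Z, 3) sampled on a voxel grid with the given 4x4 affine;
        displacements are added after the affine and local rotations follow
        the rotation factor of the transform Jacobian.
    """
    pos = _base_positions(shape, pixel_size, frame)
    valid = np.ones(shape, dtype=bool)
    if affine is None:
        affine = np.eye(4)
    A = np.asarray(affine, dtype=float)
    lin, trans = A[:3, :3], A[:3, 3]
    pos = pos @ lin.T + trans
    R_aff = polar_rotation(lin)

    if displacement is None:
        return PixelToWorldMap(pos, R_aff, valid)

    disp = np.asarray(displacement, dtype=float)
    DA = np.asarray(displacement_affine, dtype=float) if displacement_affine is not None else np.eye(4)
    DAinv = np.linalg.inv(DA)
    vox = pos @ DAinv[:3, :3].T + DAinv[:3, 3]
    grid = np.array(disp.shape[:3], dtype=float)
    inside = np.all((vox >= 0) & (vox <= grid - 1), axis=-1)
    valid &= inside
    d, J = _sample_displacement(disp, np.clip(vox, 0, grid - 1 - 1e-9))
    # Jacobian of voxel->world displacement: chain through the field's affine
    # and the section affine: total linear = (I + dD/dworld) @ lin
    Jw = np.einsum("...ij,jk->...ik", J, DAinv[:3, :3])
    total = np.einsum("...ij,jk->...ik", np.eye(3) + Jw, lin)
    rot = polar_rotation(total)
    pos = pos + d
    pos[~valid] = np.nan
    return PixelToWorldMap(pos, rot, valid)


def _sample_displacement(disp: np.ndarray, vox: np.ndarray):
    """Trilinear displacement values and central-difference Jacobians."""
    # Precompute gradient of the field on its grid (per component, per axis)
    grads = np.stack(
        [np.stack(np.gradient(disp[..., c], axis=(0, 1, 2)), axis=-1) for c in range(3)],
        axis=-2,
    )  # (X, Y, Z, 3 comp, 3 axis)
    flat = vox.reshape(-1, 3)
    i0 = np.floor(flat).astype(int)
    shape = np.array(disp.shape[:3])
    i0 = np.minimum(i0, shape - 2)
    i0 = np.maximum(i0, 0)
    f = flat - i0
    val = np.zeros((flat.shape[0], 3))
    jac = np.zeros((flat.shape[0], 3, 3))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                idx = (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz)
                val += w[:, None] * disp[idx]
                jac += w[:, None, None] * grads[idx]
    out_shape = vox.shape[:-1]
    return val.reshape(out_shape + (3,)), jac.reshape(out_shape + (3, 3))
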