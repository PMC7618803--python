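"""Hybrid MRI-microscopy orientation matching.

Each valid microscopy pixel carries a precise in-plane fibre angle but no
through-plane information.  The co-located diffusion-MRI voxel carries up to
three Ball-and-Stick (BAS) fibre populations, each with a signal fraction and
a set of posterior orientation samples — 3D but at millimetre resolution.
The hybrid reconstruction draws one BAS sample per pixel with probability
proportional to

    p_i = f_i * cos(dtheta_i)

(f_i the population signal fraction, dtheta_i the in-plane angular difference
between sample i and the microscopy angle, folded into [0, pi/2]) and
combines the sample's through-plane inclination with the microscopy in-plane
angle into a 3D axis at microscopy resolution.  Populations with signal
fraction below 0.05 are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DEGENERACY_EPS,
    PixelToWorldMap,
    compose_axis,
    decompose_axis,
    reorient_axis,
)
from .microscopy import InPlaneAngleMap

__all__ = [
    "MIN_SIGNAL_FRACTION",
    "BasField",
    "MatchResult",
    "HybridOrientationSet",
    "match_probabilities",
    "sample_cumulative",
    "reconstruct_hybrid_axis",
    "hybrid_field",
]

#: populations with mean signal fraction below this are excluded
MIN_SIGNAL_FRACTION = 0.05


@dataclass
class BasField:
    """Ball-and-Stick orientation samples on a regular voxel grid.

    ``samples`` has shape (X, Y, Z, P, S, 3) — P populations of S unit axis
    samples per voxel; ``fractions`` (X, Y, Z, P) holds per-population mean
    signal fractions.  Populations that do not exist in a voxel carry
    fraction 0.
    """

    affine: np.ndarray
    fractions: np.ndarray
    samples: np.ndarray
    min_fraction: float = MIN_SIGNAL_FRACTION

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 6 or self.samples.shape[-1] != 3:
            raise ValueError("samples must be (X, Y, Z, P, S, 3)")
        if self.fractions.shape != self.samples.shape[:4]:
            raise ValueError("fractions shape must match samples populations")
        tot = self.fractions.sum(axis=-1)
        if np.any(tot > 1 + 1e-6):
            raise ValueError("per-voxel signal fractions must sum to <= 1")
        norms = np.linalg.norm(self.samples, axis=-1)
        live = self.fractions > 0
        if np.any(np.abs(norms[live] - 1) > 1e-4):
            raise ValueError("sample vectors must be unit norm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.samples.shape[:3]

    @property
    def n_populations(self) -> int:
        return self.samples.shape[3]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[4]

    @property
    def excluded(self) -> np.ndarray:
        """Boolean (X, Y, Z, P): populations dropped by the fraction rule."""
        return self.fractions < self.min_fraction

    def world_to_voxel(self, positions: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        p = np.atleast_2d(positions)
        return p @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class MatchResult:
    """Per-candidate matching record for one microscopy pixel."""

    dtheta: np.ndarray
    weights: np.ndarray
    probabilities: np.ndarray
    cumulative: np.ndarray
    r: float | None = None
    selected: int | None = None
    fraction_fallback: bool = False


def _fold_angle_diff(a, b):
    """Undirected in-plane angular difference, folded into [0, pi/2]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % np.pi
    return np.minimum(d, np.pi - d)


def _cos_weight(dtheta):
    """cos(dtheta) with an exact zero at right angles so the all-orthogonal
    fallback can trigger (float cos(pi/2) is ~6e-17, never 0)."""
    c = np.cos(dtheta)
    return np.where(dtheta >= np.pi / 2 - 1e-12, 0.0, c)


def match_probabilities(
    theta_mic: float,
    candidate_thetas: np.ndarray,
    candidate_fractions: np.ndarray,
    candidate_degenerate: np.ndarray | None = None,
) -> MatchResult:
    """Selection probabilities p_i = f_i cos(dtheta_i), normalised.

    Candidates whose in-plane projection is degenerate (axis near the plane
    normal) contribute no in-plane evidence and are scored at dtheta = pi/2.
    If every weight vanishes, weights fall back to the fractions alone.
    """
    th = np.asarray(candidate_thetas, dtype=float)
    f = np.asarray(candidate_fractions, dtype=float)
    if th.size == 0:
        raise ValueError("no candidates to match against")
    dtheta = _fold_angle_diff(th, theta_mic)
    if candidate_degenerate is not None:
        dtheta = np.where(np.asarray(candidate_degenerate, bool), np.pi / 2, dtheta)
    w = f * _cos_weight(dtheta)
    fallback = False
    if w.sum() <= 0:
        w = f.astype(float).copy()
        fallback = True
        if w.sum() <= 0:
            raise ValueError("candidate fractions sum to zero")
    p = w / w.sum()
    return MatchResult(dtheta, w, p, np.cumsum(p), fraction_fallback=fallback)


def sample_cumulative(probabilities: np.ndarray, r: float) -> int:
    """Smallest index i with cumulative probability C[i] >= r."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability list")
    c = np.cumsum(p)
    return int(min(np.searchsorted(c, r, side="left"), p.size - 1))


def reconstruct_hybrid_axis(theta_mic, alpha_selected, frame, theta_selected=None) -> np.ndarray:
    """Hybrid 3D axis: microscopy in-plane angle + BAS through-plane angle.

    The sign of a sample's inclination is only meaningful jointly with its
    in-plane angle: when the sample's canonical in-plane angle lies on the
    opposite half-turn from ``theta_mic`` (their true difference exceeds
    90 degrees), the inclination sign is mirrored before composing, so the
    hybrid axis stays on the sample's side of the plane.  Pass
    ``theta_selected`` to enable this alignment; without it the inclination
    is used as given.
    """
    alpha = np.asarray(alpha_selected, dtype=float)
    if theta_selected is not None:
        flip = np.cos(np.asarray(theta_selected, dtype=float) - np.asarray(theta_mic, dtype=float)) < 0
        alpha = np.where(flip, -alpha, alpha)
        alpha = np.where(alpha == -np.pi / 2, np.pi / 2, alpha)
    return compose_axis(theta_mic, alpha, frame)


@dataclass
class HybridOrientationSet:
    """World-space positions with undirected 3D hybrid fibre axes.

    ``pixel_indices`` rows are (map index, row, col); ``population`` records
    the BAS population the selected sample belonged to.  ``counts`` tallies
    the bookkeeping of pixels that could not be matched.
    """

    positions: np.ndarray
    axes: np.ndarray
    voxel_indices: np.ndarray
    pixel_indices: np.ndarray
    population: np.ndarray
    counts: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.axes)


def _pixel_uniforms(seed: int, map_index: int, n_pixels: int) -> np.ndarray:
    """One uniform variate per pixel from a per-map counter-based substream.

    Variates are generated for the full pixel grid in flat order so the draw
    for a pixel does not depend on which other pixels are valid.
    """
    rng = np.random.Generator(np.random.Philox(key=[int(seed), int(map_index)]))
    return rng.random(n_pixels)


def hybrid_field(
    angle_maps,
    pixel_maps,
    bas: BasField,
    seed: int = 0,
    mode: str = "sampled",
    min_fraction: float | None = None,
) -> HybridOrientationSet:
    """Reconstruct hybrid axes for every valid pixel of each section.

    Parameters
    ----------
    angle_maps : list of InPlaneAngleMap
    pixel_maps : list of PixelToWorldMap (same order/shapes)
    bas : BasField
    mode : "sampled" draws via the cumulative fraction-weighted cosine
        probabilities; "argmax" deterministically takes the highest-weight
        candidate (ties to the lowest index).
    """
    if mode not in ("sampled", "argmax"):
        raise ValueError("mode must be 'sampled' or 'argmax'")
    if min_fraction is None:
        min_fraction = bas.min_fraction
    inv = np.linalg.inv(bas.affine)
    shape = np.array(bas.shape)
    P, S = bas.n_populations, bas.n_samples

    out_pos, out_axes, out_vox, out_pix, out_pop = [], [], [], [], []
    counts = {
        "matched": 0,
        "skipped_outside_grid": 0,
        "skipped_no_population": 0,
        "fraction_fallback": 0,
        "degenerate_selected": 0,
    }

    for mi, (amap, pmap) in enumerate(zip(angle_maps, pixel_maps)):
        if not isinstance(amap, InPlaneAngleMap) or not isinstance(pmap, PixelToWorldMap):
            raise TypeError("angle_maps/pixel_maps carry the wrong types")
        frame = amap.plane_frame
        valid = amap.valid_mask & pmap.valid
        if not valid.any():
            continue
        rows, cols = np.nonzero(valid)
        flat = rows * amap.angle.shape[1] + cols
        rs = _pixel_uniforms(seed, mi, amap.angle.size)[flat]
        pos = pmap.positions[rows, cols]
        theta = amap.angle[rows, cols]
        # reorient the world frame per pixel if the transform rotates locally
        if pmap.rotations.ndim == 2:
            frame_u = np.broadcast_to(pmap.rotations @ frame.u, (len(rows), 3))
            frame_v = np.broadcast_to(pmap.rotations @ frame.v, (len(rows), 3))
        else:
            R = pmap.rotations[rows, cols]
            frame_u = np.einsum("nij,j->ni", R, frame.u)
            frame_v = np.einsum("nij,j->ni", R, frame.v)

        vox = np.floor(pos @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        counts["skipped_outside_grid"] += int((~inside).sum())
        if not inside.any():
            continue
        rows, cols, flat, rs = rows[inside], cols[inside], flat[inside], rs[inside]
        pos, theta, vox = pos[inside], theta[inside], vox[inside]
        frame_u, frame_v = frame_u[inside], frame_v[inside]

        vflat = np.ravel_multi_index(vox.T, bas.shape)
        order = np.argsort(vflat, kind="stable")
        for grp in np.split(order, np.nonzero(np.diff(vflat[order]))[0] + 1):
            vi, vj, vk = vox[grp[0]]
            fr = bas.fractions[vi, vj, vk]
            keep_pop = fr >= min_fraction
            if not keep_pop.any():
                counts["skipped_no_population"] += len(grp)
                continue
            pops = np.nonzero(keep_pop)[0]
            cand_axes = bas.samples[vi, vj, vk, pops].reshape(-1, 3)
            cand_f = np.repeat(fr[pops], S)
            cand_pop = np.repeat(pops, S)
            g_frame = _voxel_frame(frame, frame_u[grp], frame_v[grp])
            dec = decompose_axis(cand_axes, g_frame)
            dth = _fold_angle_diff(dec.theta[None, :], theta[grp][:, None])
            dth = np.where(dec.degenerate[None, :], np.pi / 2, dth)
            w = cand_f[None, :] * _cos_weight(dth)
            wsum = w.sum(axis=1)
            fb = wsum <= 0
            if fb.any():
                counts["fraction_fallback"] += int(fb.sum())
                w[fb] = cand_f[None, :]
                wsum = w.sum(axis=1)
            prob = w / wsum[:, None]
            if mode == "argmax":
                sel = np.argmax(w, axis=1)
            else:
                cum = np.cumsum(prob, axis=1)
                # smallest index with C[i] >= r, per pixel
                sel = (cum < rs[grp][:, None]).sum(axis=1)
                sel = np.minimum(sel, prob.shape[1] - 1)
            alpha = dec.alpha[sel]
            deg_sel = dec.degenerate[sel]
            axes = reconstruct_hybrid_axis(
                theta[grp], alpha, g_frame, theta_selected=dec.theta[sel]
            )
            if deg_sel.any():
                # no usable in-plane direction: keep the BAS axis itself
                counts["degenerate_selected"] += int(deg_sel.sum())
                axes[deg_sel] = cand_axes[sel[deg_sel]]
            # rotate composed axes from the canonical frame to per-pixel frames
            axes = _to_pixel_frames(axes, g_frame, frame_u[grp], frame_v[grp])
            out_pos.append(pos[grp])
            out_axes.append(axes)
            out_vox.append(vox[grp])
            out_pix.append(
                np.column_stack([np.full(len(grp), mi), rows[grp], cols[grp]])
            )
            out_pop.append(cand_pop[sel])
            counts["matched"] += len(grp)

    if out_axes:
        result = HybridOrientationSet(
            np.concatenate(out_pos),
            np.concatenate(out_axes),
            np.concatenate(out_vox),
            np.concatenate(out_pix).astype(int),
            np.concatenate(out_pop).astype(int),
            counts,
        )
    else:
        result = HybridOrientationSet(
            np.empty((0, 3)), np.empty((0, 3)), np.empty((0, 3), int),
            np.empty((0, 3), int), np.empty(0, int), counts,
        )
    return result


def _voxel_frame(frame, frame_u, frame_v):
    """Representative frame for a pixel group (identical under pure affines)."""
    from .geometry import PlaneFrame

    u = frame_u[0] / np.linalg.norm(frame_u[0])
    v = frame_v[0] - (frame_v[0] @ u) * u
    return PlaneFrame(u=u, v=v / np.linalg.norm(v), origin=frame.origin)


def _to_pixel_frames(axes, g_frame, frame_u, frame_v):
    """Re-express axes when per-pixel rotations differ within the group."""
    # decompose in the group frame, recompose in each pixel's own frame
    u0, v0, n0 = g_frame.u, g_frame.v, g_frame.n
    cu = axes @ u0
    cv = axes @ v0
    cn = axes @ n0
    u = frame_u / np.linalg.norm(frame_u, axis=1, keepdims=True)
    v = frame_v - np.sum(frame_v * u, axis=1, keepdims=True) * u
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    n = np.cross(u, v)
    out = cu[:, None] * u + cv[:, None] * v + cn[:, None] * n
    return out / np.linalg.norm(out, axis=1, keepdims=True)
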