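"""Probabilistic FOD tractography (documented stand-in tracker).

This is a deliberately simple first-order rejection sampler, not a
re-implementation of iFOD2's two-point arc sampling: at every step a
candidate direction is drawn inside a cone around the incoming direction
and accepted with probability proportional to the trilinearly interpolated
FOD amplitude along it.  It exists so the FOD-building and evaluation
stages can be exercised end-to-end; FOD images can be exported to NIfTI
for external trackers when publication-grade streamlines are needed.

Streamlines terminate when the FOD amplitude falls below the cut-off, the
position leaves the grid, the length budget is exhausted, or the rejection
sampler fails to accept within its draw cap.  Tracks shorter than the
minimum length are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fod import FodImage, max_peak_amplitude
from .sh import sh_basis

__all__ = ["TrackingParams", "Tractogram", "seed_points", "track"]


@dataclass
class TrackingParams:
    """Tracker controls; defaults follow the whole-brain protocol
    (0.2 mm steps, 0.05 amplitude cut-off, 5-120 mm length window,
    30 seeds per voxel)."""

    step_size: float = 0.2
    amplitude_cutoff: float = 0.05
    max_length: float = 120.0
    min_length: float = 5.0
    seeds_per_voxel: int = 30
    max_angle_per_step: float = 20.0
    seed: int = 0
    # draw budget for the per-step rejection sampler; generous caps are the
    # norm for FOD rejection samplers and matter on thin single-voxel tracts
    max_rejection_draws: int = 250

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not (0 < self.min_length < self.max_length):
            raise ValueError("need 0 < min_length < max_length")
        if self.amplitude_cutoff < 0:
            raise ValueError("amplitude cut-off must be >= 0")


@dataclass
class Tractogram:
    """Streamlines as ordered world-mm point arrays with seed provenance."""

    streamlines: list
    seeds: np.ndarray = None
    step_size: float | None = None

    def __post_init__(self):
        if self.seeds is None:
            self.seeds = np.full(len(self.streamlines), -1, dtype=int)
        self.seeds = np.asarray(self.seeds)

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array(
            [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.streamlines]
        )

    def subset(self, index) -> "Tractogram":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        return Tractogram(
            [self.streamlines[i] for i in index],
            self.seeds[index],
            self.step_size,
        )


def seed_points(
    mask: np.ndarray,
    affine: np.ndarray,
    seeds_per_voxel: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Uniform world-mm seed positions inside each true voxel of ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("seed mask is empty")
    if seeds_per_voxel <= 0:
        return np.empty((0, 3))
    rng = np.random.default_rng(seed)
    vox = np.argwhere(mask)
    offs = rng.random((len(vox), seeds_per_voxel, 3))
    pts = (vox[:, None, :] + offs).reshape(-1, 3)
    A = np.asarray(affine, dtype=float)
    return pts @ A[:3, :3].T + A[:3, 3]


def _interp_coeffs_many(fod: FodImage, pos: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of SH coefficients over voxel centres for a
    batch of positions (N, 3); out-of-grid contributions read as zero."""
    pos = np.atleast_2d(pos)
    vox = fod.world_to_voxel(pos) - 0.5
    lo = np.floor(vox).astype(int)
    f = vox - lo
    shape = np.array(fod.shape)
    out = np.zeros((len(pos), fod.coeffs.shape[-1]))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = lo + (dx, dy, dz)
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                ok = np.all((idx >= 0) & (idx < shape), axis=1) & (w > 0)
                if ok.any():
                    ii = idx[ok]
                    out[ok] += w[ok, None] * fod.coeffs[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def _interp_coeffs(fod: FodImage, pos: np.ndarray) -> np.ndarray | None:
    """Trilinear interpolation at a single position (None outside the grid)."""
    vox = fod.world_to_voxel(pos)[0] - 0.5
    lo = np.floor(vox).astype(int)
    shape = np.array(fod.shape)
    if np.any(lo < -1) or np.any(lo > shape - 1):
        return None
    return _interp_coeffs_many(fod, pos[None])[0]


def _cone_directions(incoming: np.ndarray, max_angle_rad: float, n: int, rng) -> np.ndarray:
    """Uniform directions within a cone about ``incoming``."""
    cos_t = rng.uniform(np.cos(max_angle_rad), 1.0, n)
    sin_t = np.sqrt(1 - cos_t**2)
    phi = rng.uniform(0, 2 * np.pi, n)
    local = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    # orthonormal frame with incoming as the third axis
    w = incoming / np.linalg.norm(incoming)
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return local @ np.vstack([u, v, w])


def _voxel_envelopes(fod: FodImage) -> np.ndarray:
    flat = fod.coeffs.reshape(-1, fod.coeffs.shape[-1])
    env = max_peak_amplitude(flat).reshape(fod.shape)
    return 1.1 * np.maximum(env, 0.0)


def _local_envelope(env: np.ndarray, fod: FodImage, pos: np.ndarray) -> float:
    """Upper bound on the interpolated amplitude near ``pos``: the largest
    per-voxel envelope among the 8 trilinear neighbours (a trilinear mix
    cannot exceed its largest contributor)."""
    vox = fod.world_to_voxel(pos)[0] - 0.5
    lo = np.floor(vox).astype(int)
    shape = np.array(fod.shape)
    best = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                i = lo + (dx, dy, dz)
                if np.any(i < 0) or np.any(i >= shape):
                    continue
                best = max(best, env[tuple(i)])
    return best


def _propagate(fod, env, pos0, dir0, params, rng, max_steps):
    """Walk one direction from a seed; returns the visited points (excl. seed).

    Candidate directions are scored by the FOD amplitude at the *arrival*
    point of the step (as in arc-sampling trackers), so steps into regions
    without FOD support are rejected and streamlines stay on the tract.
    """
    pts = []
    pos, direction = pos0.copy(), dir0.copy()
    max_ang = np.deg2rad(params.max_angle_per_step)
    shape = np.array(fod.shape)
    for _ in range(max_steps):
        vox = np.floor(fod.world_to_voxel(pos)[0]).astype(int)
        if np.any(vox < 0) or np.any(vox >= shape):
            break
        envelope = _local_envelope(env, fod, pos)
        if envelope <= params.amplitude_cutoff:
            break
        cands = _cone_directions(direction, max_ang, params.max_rejection_draws, rng)
        accept_u = rng.random(params.max_rejection_draws) * envelope
        chosen = None
        # sequential rejection sampling, evaluated in vectorised chunks
        for start in range(0, params.max_rejection_draws, 64):
            block = cands[start : start + 64]
            coeffs = _interp_coeffs_many(fod, pos + params.step_size * block)
            amps = np.einsum("nk,nk->n", sh_basis(block, fod.lmax), coeffs)
            ok = np.nonzero(
                (amps >= params.amplitude_cutoff)
                & (accept_u[start : start + len(block)] <= amps)
            )[0]
            if ok.size:
                chosen = block[ok[0]]
                break
        if chosen is None:
            break
        direction = chosen
        pos = pos + params.step_size * direction
        pts.append(pos.copy())
    return pts


def _initial_direction(fod, env, pos, params, rng):
    coeffs = _interp_coeffs(fod, pos)
    if coeffs is None:
        return None
    vox = np.floor(fod.world_to_voxel(pos)[0]).astype(int)
    if np.any(vox < 0) or np.any(vox >= np.array(fod.shape)):
        return None
    envelope = _local_envelope(env, fod, pos)
    if envelope <= params.amplitude_cutoff:
        return None
    d = rng.normal(size=(params.max_rejection_draws, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    amps = sh_basis(d, fod.lmax) @ coeffs
    accept_u = rng.random(params.max_rejection_draws) * envelope
    # launch only from genuine FOD lobes: order-8 histogram fits ring at
    # ~0.14 of the peak, so gate on a fraction of the local maximum as well
    threshold = max(params.amplitude_cutoff, 0.2 * envelope / 1.1)
    ok = np.nonzero((amps >= threshold) & (accept_u <= amps))[0]
    if ok.size == 0:
        return None
    return d[ok[0]]


def track(fod: FodImage, seeds: np.ndarray, params: TrackingParams | None = None) -> Tractogram:
    """Track probabilistic streamlines through a FOD image.

    Every seed launches a bidirectional walk; each half consumes the shared
    length budget.  Results are reproducible for a fixed ``params.seed``.
    """
    if params is None:
        params = TrackingParams()
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    env = _voxel_envelopes(fod)
    n_total = int(np.floor(params.max_length / params.step_size))
    streamlines, provenance = [], []
    for si, seed_pos in enumerate(seeds):
        rng = np.random.Generator(np.random.Philox(key=[int(params.seed), si]))
        d0 = _initial_direction(fod, env, seed_pos, params, rng)
        if d0 is None:
            continue
        fwd = _propagate(fod, env, seed_pos, d0, params, rng, n_total)
        bwd = _propagate(fod, env, seed_pos, -d0, params, rng, n_total - len(fwd))
        pts = np.array(bwd[::-1] + [seed_pos] + fwd)
        if len(pts) < 2:
            continue
        length = params.step_size * (len(pts) - 1)
        if length < params.min_length or length > params.max_length:
            continue
        streamlines.append(pts)
        provenance.append(si)
    return Tractogram(streamlines, np.array(provenance, dtype=int), params.step_size)
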