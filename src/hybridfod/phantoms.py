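"""Synthetic fibre phantoms with known ground truth.

A phantom is a set of tubular fibre bundles (polyline centrelines with a
radius) inside a regular voxel grid.  From the bundle geometry the
generator derives every input the hybrid pipeline consumes:

* per-voxel ground-truth fibre populations (occupancy-weighted mean
  tangents) and signal fractions,
* a Ball-and-Stick sample field — samples drawn from a Watson distribution
  about each population axis (concentration ``kappa``; ``kappa = inf``
  copies the axis exactly), emulating posterior orientation scatter,
* microscopy sections — in-plane angle maps on planes normal to a chosen
  axis, with von Mises noise applied on the doubled angle (respecting the
  pi-periodicity of undirected in-plane angles),
* endpoint region labels, per-bundle probability maps, and the true binary
  region-connectivity matrix.

Everything is reproducible from the ``PhantomSpec`` seed.  The phantom emulates
orientation geometry and sampling noise only: no diffusion signal, imaging
point-spread, registration error or staining variability is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import erfi

from .fod import grid_affine
from .geometry import PlaneFrame, PixelToWorldMap, decompose_axis, map_pixels_to_world
from .match import BasField
from .microscopy import InPlaneAngleMap

__all__ = [
    "Bundle",
    "PhantomSpec",
    "PhantomTruth",
    "Phantom",
    "straight_bundle",
    "arc_bundle",
    "make_phantom",
    "degrade_bas",
    "sample_watson",
    "default_spec",
    "parallel_pair_spec",
    "single_bundle_spec",
]


@dataclass
class Bundle:
    """Tubular bundle: dense centreline polyline (mm), radius (mm) and the
    (seed, target) region labels its endpoints connect."""

    centreline: np.ndarray
    radius: float
    regions: tuple[int, int]

    def __post_init__(self):
        self.centreline = np.asarray(self.centreline, dtype=float)
        if self.radius <= 0:
            raise ValueError("bundle radius must be positive")

    @property
    def tangents(self) -> np.ndarray:
        t = np.gradient(self.centreline, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)


def straight_bundle(start, end, radius, regions, n_points: int = 200) -> Bundle:
    t = np.linspace(0, 1, n_points)[:, None]
    line = np.asarray(start, float) + t * (np.asarray(end, float) - np.asarray(start, float))
    return Bundle(line, radius, regions)


def arc_bundle(centre, arc_radius, radius, regions, plane=("x", "z"),
               angles=(np.pi, 0.0), n_points: int = 300) -> Bundle:
    """Circular-arc (U-bend) bundle in a coordinate plane."""
    ax = {"x": 0, "y": 1, "z": 2}
    i, j = ax[plane[0]], ax[plane[1]]
    t = np.linspace(angles[0], angles[1], n_points)
    pts = np.tile(np.asarray(centre, float), (n_points, 1))
    pts[:, i] += arc_radius * np.cos(t)
    pts[:, j] += arc_radius * np.sin(t)
    return Bundle(pts, radius, regions)


@dataclass
class PhantomSpec:
    """Study conditions for a synthetic phantom.

    Defaults mirror the acquisition this emulates: 4 um microscopy pixels
    and 0.35 mm between consecutive sections; ``kappa`` is the Watson
    concentration of BAS sample scatter (50 ~ 8 deg dispersion) and
    ``microscopy_noise_deg`` the in-plane angle noise SD.  Tests and the
    worked examples use coarser pixels to keep problem sizes tractable.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    bundles: list[Bundle]
    section_normal: int = 2
    pixel_size: float = 0.004
    section_spacing: float = 0.35
    kappa: float = 50.0
    microscopy_noise_deg: float = 3.0
    n_populations: int = 3
    n_samples: int = 50
    max_total_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.section_spacing <= 0 or self.pixel_size <= 0 or self.voxel_size <= 0:
            raise ValueError("spacings and sizes must be positive")
        if not (self.kappa > 0):
            raise ValueError("kappa must be positive (may be inf)")

    @property
    def extent(self) -> np.ndarray:
        return np.array(self.shape, float) * self.voxel_size

    @property
    def affine(self) -> np.ndarray:
        return grid_affine(self.voxel_size)


@dataclass
class PhantomTruth:
    """Ground truth: per-voxel population axes/fractions, per-pixel axes per
    section, and the binary region connectivity."""

    voxel_axes: np.ndarray
    voxel_fractions: np.ndarray
    voxel_bundles: np.ndarray
    pixel_axes: list
    pixel_bundles: list
    pixel_valid: list
    connectivity: np.ndarray
    region_labels: list


@dataclass
class Phantom:
    """Everything the pipeline consumes, plus the truth that generated it."""

    spec: PhantomSpec
    truth: PhantomTruth
    bas: BasField
    angle_maps: list
    pixel_maps: list
    labels: np.ndarray
    probability_maps: dict
    wm_mask: np.ndarray


# ---------------------------------------------------------------------------
# Watson sampling

def sample_watson(mu: np.ndarray, kappa: float, n: int, rng) -> np.ndarray:
    """Draw undirected axes from a bipolar Watson distribution about mu.

    The |cos| of the polar angle is sampled by numerically inverting the
    exact CDF erfi(sqrt(kappa) t) / erfi(sqrt(kappa)); kappa = inf returns
    exact copies of mu.
    """
    mu = np.asarray(mu, float)
    mu = mu / np.linalg.norm(mu)
    if np.isinf(kappa):
        return np.tile(mu, (n, 1))
    grid = np.linspace(0.0, 1.0, 4097)
    cdf = erfi(np.sqrt(kappa) * grid) / erfi(np.sqrt(kappa))
    t = np.interp(rng.random(n), cdf, grid)
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    ct = t * sign
    st = np.sqrt(np.clip(1 - ct**2, 0, None))
    phi = rng.uniform(0, 2 * np.pi, n)
    local = np.column_stack([st * np.cos(phi), st * np.sin(phi), ct])
    # rotate local +z to mu
    a = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(mu, a)
    u /= np.linalg.norm(u)
    v = np.cross(mu, u)
    return local @ np.vstack([u, v, mu])


# ---------------------------------------------------------------------------
# geometry queries

class _BundleField:
    """Nearest-centreline queries for a set of bundles."""

    def __init__(self, bundles):
        self.bundles = bundles
        self.trees = [cKDTree(b.centreline) for b in bundles]
        self.tangents = [b.tangents for b in bundles]

    def query(self, points: np.ndarray):
        """Per point: (bundle index of the closest containing bundle or -1,
        unit tangent axis)."""
        points = np.atleast_2d(points)
        best = np.full(len(points), -1, dtype=int)
        bestd = np.full(len(points), np.inf)
        axes = np.zeros((len(points), 3))
        for bi, (b, tree, tang) in enumerate(zip(self.bundles, self.trees, self.tangents)):
            d, idx = tree.query(points)
            hit = (d <= b.radius) & (d < bestd)
            best[hit] = bi
            bestd[hit] = d[hit]
            axes[hit] = tang[idx[hit]]
        return best, axes

    def memberships(self, points: np.ndarray) -> np.ndarray:
        """Boolean (n_points, n_bundles) containment matrix."""
        points = np.atleast_2d(points)
        out = np.zeros((len(points), len(self.bundles)), dtype=bool)
        for bi, (b, tree) in enumerate(zip(self.bundles, self.trees)):
            d, _ = tree.query(points)
            out[:, bi] = d <= b.radius
        return out

    def bundle_tangents(self, points: np.ndarray, bi: int) -> np.ndarray:
        """Tangent of bundle ``bi`` at its centreline point nearest each point."""
        _, idx = self.trees[bi].query(np.atleast_2d(points))
        return self.tangents[bi][idx]


def _mean_axis(axes: np.ndarray) -> np.ndarray:
    """Mean undirected axis: principal eigenvector of the scatter matrix."""
    M = axes.T @ axes
    w, V = np.linalg.eigh(M)
    return V[:, -1]


# ---------------------------------------------------------------------------
# generation

def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate all pipeline inputs plus ground truth from a spec."""
    extent = spec.extent
    for b in spec.bundles:
        if np.any(b.centreline < -1e-9) or np.any(b.centreline > extent + 1e-9):
            raise ValueError("bundle centreline leaves the grid")
    rng = np.random.default_rng(spec.seed)
    fld = _BundleField(spec.bundles)
    P, S = spec.n_populations, spec.n_samples
    if len(spec.bundles) and P < 1:
        raise ValueError("need at least one population slot")

    vox_axes, vox_frac, vox_bundles = _voxel_truth(spec, fld)
    bas = _simulate_bas(spec, vox_axes, vox_frac, rng)
    angle_maps, pixel_maps, pix_axes, pix_bundles, pix_valid = _microscopy_sections(spec, fld, rng)
    labels, region_labels = _region_labels(spec)
    prob_maps = _probability_maps(spec, fld)
    conn = _true_connectivity(spec, region_labels)
    wm = vox_frac.sum(axis=-1) > 0

    truth = PhantomTruth(
        vox_axes, vox_frac, vox_bundles, pix_axes, pix_bundles, pix_valid,
        conn, region_labels,
    )
    return Phantom(spec, truth, bas, angle_maps, pixel_maps, labels, prob_maps, wm)


def _voxel_truth(spec: PhantomSpec, fld: _BundleField):
    """Population axes and fractions per voxel from sub-voxel occupancy."""
    X, Y, Z = spec.shape
    P = spec.n_populations
    q = 3  # sub-samples per voxel edge
    off = (np.arange(q) + 0.5) / q
    sub = np.stack(np.meshgrid(off, off, off, indexing="ij"), -1).reshape(-1, 3)
    vox_axes = np.zeros((X, Y, Z, P, 3))
    vox_frac = np.zeros((X, Y, Z, P))
    vox_bundles = np.full((X, Y, Z, P), -1, dtype=int)
    idx = np.indices(spec.shape).reshape(3, -1).T
    pts = (idx[:, None, :] + sub[None, :, :]) * spec.voxel_size  # (N, q^3, 3)
    flat = pts.reshape(-1, 3)
    member = fld.memberships(flat).reshape(len(idx), len(sub), len(spec.bundles))
    # each population's axis averages that bundle's own tangents only
    tangent = np.stack(
        [fld.bundle_tangents(flat, bi).reshape(len(idx), len(sub), 3)
         for bi in range(len(spec.bundles))],
        axis=2,
    )  # (N, q^3, n_bundles, 3)
    occ = member.mean(axis=1)  # (N, n_bundles)
    for n, (i, j, k) in enumerate(idx):
        present = np.nonzero(occ[n] > 0)[0]
        if len(present) == 0:
            continue
        order = present[np.argsort(occ[n][present])[::-1]][:P]
        fr = occ[n][order]
        fr = fr * spec.max_total_fraction / max(fr.sum(), 1.0)
        for p, bi in enumerate(order):
            inb = member[n, :, bi]
            vox_axes[i, j, k, p] = _mean_axis(tangent[n, inb, bi])
            vox_frac[i, j, k, p] = fr[p]
            vox_bundles[i, j, k, p] = bi
    return vox_axes, vox_frac, vox_bundles


def _simulate_bas(spec: PhantomSpec, vox_axes, vox_frac, rng) -> BasField:
    X, Y, Z, P, _ = vox_axes.shape
    S = spec.n_samples
    samples = np.zeros((X, Y, Z, P, S, 3))
    live = np.argwhere(vox_frac > 0)
    for i, j, k, p in live:
        samples[i, j, k, p] = sample_watson(vox_axes[i, j, k, p], spec.kappa, S, rng)
    return BasField(spec.affine, vox_frac, samples)


def _microscopy_sections(spec: PhantomSpec, fld: _BundleField, rng):
    """Angle maps on sections normal to the chosen axis, noisy in 2*theta."""
    nrm = spec.section_normal
    extent = spec.extent
    n_sections = int(np.floor(extent[nrm] / spec.section_spacing))
    in_plane = [a for a in range(3) if a != nrm]
    rows = int(np.round(extent[in_plane[0]] / spec.pixel_size))
    cols = int(np.round(extent[in_plane[1]] / spec.pixel_size))
    sd2 = 2 * np.deg2rad(spec.microscopy_noise_deg)  # SD on the doubled angle
    kappa_vm = None if sd2 == 0 else 1.0 / sd2**2

    angle_maps, pixel_maps, pix_axes, pix_bundles, pix_valid = [], [], [], [], []
    for s in range(n_sections):
        origin = np.zeros(3)
        # centre pixels within their footprint; sections at half-spacing offsets
        origin[in_plane[0]] = spec.pixel_size / 2
        origin[in_plane[1]] = spec.pixel_size / 2
        origin[nrm] = (s + 0.5) * spec.section_spacing
        frame = PlaneFrame(
            u=np.eye(3)[in_plane[0]], v=np.eye(3)[in_plane[1]], origin=origin
        )
        pmap = map_pixels_to_world((rows, cols), (spec.pixel_size, spec.pixel_size), frame)
        pos = pmap.positions.reshape(-1, 3)
        bi, axes = fld.query(pos)
        valid = (bi >= 0).reshape(rows, cols)
        dec = decompose_axis(
            np.where(np.linalg.norm(axes, axis=1, keepdims=True) > 0, axes, [1.0, 0, 0]),
            frame,
        )
        theta = dec.theta.reshape(rows, cols)
        valid &= ~dec.degenerate.reshape(rows, cols)
        if kappa_vm is not None:
            noise = rng.vonmises(0.0, kappa_vm, size=theta.shape) / 2.0
            theta = np.mod(theta + noise, np.pi)
        angle_maps.append(
            InPlaneAngleMap(theta, valid, (spec.pixel_size, spec.pixel_size), frame)
        )
        pixel_maps.append(pmap)
        pix_axes.append(axes.reshape(rows, cols, 3))
        pix_bundles.append(bi.reshape(rows, cols))
        pix_valid.append(valid)
    return angle_maps, pixel_maps, pix_axes, pix_bundles, pix_valid


def _region_labels(spec: PhantomSpec):
    """Spherical endpoint regions around each bundle's centreline ends.

    The sphere radius is at least one voxel size so thin bundles still get
    a non-empty region; voxels claimed by several regions take the label of
    the nearest endpoint."""
    labels = np.zeros(spec.shape, dtype=int)
    flat = labels.reshape(-1)
    world = (np.indices(spec.shape).reshape(3, -1).T + 0.5) * spec.voxel_size
    best = np.full(len(world), np.inf)
    region_labels = []
    for b in spec.bundles:
        for end, lab in zip((b.centreline[0], b.centreline[-1]), b.regions):
            region_labels.append(lab)
            r = max(1.5 * b.radius, spec.voxel_size)
            d = np.linalg.norm(world - end, axis=1)
            hit = (d <= r) & (d < best)
            flat[hit] = lab
            best[hit] = d[hit]
    return labels, sorted(set(region_labels))


def _probability_maps(spec: PhantomSpec, fld: _BundleField):
    """Per-bundle voxel probability maps: 1 where the voxel overlaps the
    bundle (sub-sampled occupancy, robust to bundles thinner than a voxel)."""
    q = 3
    off = (np.arange(q) + 0.5) / q
    sub = np.stack(np.meshgrid(off, off, off, indexing="ij"), -1).reshape(-1, 3)
    idx = np.indices(spec.shape).reshape(3, -1).T
    pts = ((idx[:, None, :] + sub[None, :, :]) * spec.voxel_size).reshape(-1, 3)
    member = fld.memberships(pts).reshape(len(idx), len(sub), len(spec.bundles))
    return {
        bi: member[:, :, bi].any(axis=1).reshape(spec.shape).astype(float)
        for bi in range(len(spec.bundles))
    }


def _true_connectivity(spec: PhantomSpec, region_labels):
    n = len(region_labels)
    col = {lab: i for i, lab in enumerate(region_labels)}
    conn = np.zeros((n, n))
    for b in spec.bundles:
        a, c = b.regions
        conn[col[a], col[c]] = 1.0
        conn[col[c], col[a]] = 1.0
    return conn


# ---------------------------------------------------------------------------
# perturbations

def degrade_bas(
    bas: BasField,
    drop_lowest_population: bool = False,
    kappa_factor: float | None = None,
    kappa: float | None = None,
    seed: int = 0,
) -> BasField:
    """Controlled BAS degradations for ablation studies.

    ``drop_lowest_population`` zeroes the lowest-fraction live population of
    every multi-population voxel; ``kappa_factor`` rescales the Watson
    concentration (values < 1 inflate scatter) by re-drawing samples about
    each population's mean axis; ``kappa`` sets it absolutely.  With no
    option the field is returned bit-identical.
    """
    fractions = bas.fractions.copy()
    samples = bas.samples.copy()
    if drop_lowest_population:
        live = fractions > 0
        multi = live.sum(axis=-1) >= 2
        for i, j, k in np.argwhere(multi):
            fr = fractions[i, j, k]
            cand = np.nonzero(fr > 0)[0]
            drop = cand[np.argmin(fr[cand])]
            fractions[i, j, k, drop] = 0.0
            samples[i, j, k, drop] = 0.0
    if kappa_factor is not None or kappa is not None:
        rng = np.random.default_rng(seed)
        for i, j, k, p in np.argwhere(fractions > 0):
            mu = _mean_axis(samples[i, j, k, p])
            if kappa is None:
                cur = _estimate_kappa(samples[i, j, k, p], mu)
                new_kappa = cur * kappa_factor
            else:
                new_kappa = kappa
            samples[i, j, k, p] = sample_watson(mu, new_kappa, bas.n_samples, rng)
    return BasField(bas.affine, fractions, samples, bas.min_fraction)


def _estimate_kappa(samples: np.ndarray, mu: np.ndarray) -> float:
    """Moment estimate of the Watson concentration from mean cos^2."""
    c2 = float(np.mean((samples @ mu) ** 2))
    # invert E[t^2] = d/dk log integral numerically on a grid
    ks = np.geomspace(0.5, 2000, 512)
    e = np.array([_watson_c2(k) for k in ks])
    return float(np.interp(c2, e, ks))


def _watson_c2(kappa: float) -> float:
    t = np.linspace(0, 1, 2001)
    w = np.exp(kappa * (t**2 - 1))
    return float(np.trapezoid(t**2 * w, t) / np.trapezoid(w, t))


# ---------------------------------------------------------------------------
# stock phantoms

def default_spec(pixel_size: float = 0.15, seed: int = 0, **overrides) -> PhantomSpec:
    """The default study phantom: 24^3 voxels at 0.6 mm.

    Sections are normal to y (the stacking axis, mirroring coronal
    sectioning), so bundles routed within x-z planes are microscopy-resolved
    while the through-plane direction is only visible to the BAS field.
    Contents: two straight bundles crossing at 90 degrees in-plane, a U-bend
    (an in-plane curve, as gyral fibres are in coronal sections), two
    parallel bundles 0.5 mm apart (the bottleneck fixture), and one oblique
    bundle at 45 degrees through the sections, which exercises the
    through-plane fusion.

    The default pixel size here is coarser than the 4 um instrument pixel;
    at full resolution a single section would carry ~13 million pixels,
    which adds nothing to orientation statistics on a smooth phantom.
    """
    e = 24 * 0.6  # 14.4 mm
    bundles = [
        straight_bundle((0.7, 7.2, 7.2), (e - 0.7, 7.2, 7.2), 0.8, (1, 2)),
        straight_bundle((7.2, 7.2, 0.7), (7.2, 7.2, e - 0.7), 0.8, (3, 4)),
        arc_bundle((7.2, 11.0, 2.8), 3.5, 0.7, (5, 6), plane=("x", "z")),
        straight_bundle((0.7, 3.6, 10.8), (e - 0.7, 3.6, 10.8), 0.2, (7, 8)),
        straight_bundle((0.7, 3.6, 11.3), (e - 0.7, 3.6, 11.3), 0.2, (9, 10)),
        straight_bundle((2.0, 2.0, 12.9), (12.0, 12.0, 12.9), 0.7, (11, 12)),
    ]
    kwargs = dict(
        shape=(24, 24, 24), voxel_size=0.6, bundles=bundles,
        section_normal=1, pixel_size=pixel_size, seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def parallel_pair_spec(pixel_size: float = 0.1, seed: int = 0, **overrides) -> PhantomSpec:
    """Two parallel bundles 0.5 mm apart (centre to centre) along x — the
    toy bottleneck: merged inside 1.0 mm voxels, separable at 0.2 mm.
    Sections are normal to y and the bundle centres sit on a section plane;
    the 0.12 mm radius keeps an empty voxel column between the bundles on a
    0.2 mm grid."""
    bundles = [
        straight_bundle((0.6, 1.925, 1.5), (11.4, 1.925, 1.5), 0.12, (1, 2)),
        straight_bundle((0.6, 1.925, 2.0), (11.4, 1.925, 2.0), 0.12, (3, 4)),
    ]
    kwargs = dict(
        shape=(20, 6, 6), voxel_size=0.6, bundles=bundles,
        section_normal=1, pixel_size=pixel_size, seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def single_bundle_spec(pixel_size: float = 0.05, seed: int = 0, **overrides) -> PhantomSpec:
    """One straight bundle along x — the simplest recovery fixture.

    The finer default pixel (0.05 mm) keeps per-voxel orientation counts
    high enough at 0.4 mm grids for stable peak statistics."""
    bundles = [straight_bundle((0.6, 1.8, 1.8), (8.4, 1.8, 1.8), 0.6, (1, 2))]
    kwargs = dict(
        shape=(15, 6, 6), voxel_size=0.6, bundles=bundles,
        section_normal=1, pixel_size=pixel_size, seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)
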