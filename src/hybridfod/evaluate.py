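"""Streamline refinement, fixel bookkeeping and tracer-comparison statistics.

Refinement follows the two-stage scheme used for whole-brain tract
segmentation: streamlines are first scored against a tract probability
atlas (mean probability over intersected voxels, discard below 0.2), then
outliers are removed — streamlines more than 4 standard deviations longer
than the mean length, or deviating more than 5 standard deviations from
the tract "core" (the point-wise mean of streamlines resampled to 50
equidistant points).

Evaluation against reference (tracer-style) connectivity uses streamline-
fraction connectivity matrices, ROC analysis of binarised matrices,
overlap categorisation and log-log Pearson correlation of connection
weights.  Fixel utilities quantify bottleneck regions: a fixel is one FOD
peak of one voxel, and a fixel traversed by streamlines of two or more
tracts marks a bottleneck ("multi-bundle fixel").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tracking import Tractogram

__all__ = [
    "atlas_probability_filter",
    "outlier_filter",
    "density_map",
    "assign_fixels",
    "bottleneck_mask",
    "crossing_fibre_ratio",
    "connectivity_matrix",
    "roc_vs_reference",
    "overlap_matrix",
    "log_correlation",
    "resample_streamline",
    "ConnectivityMatrix",
    "RocCurve",
    "FixelMaps",
]


# ---------------------------------------------------------------------------
# voxel traversal helpers

def _streamline_voxels(points: np.ndarray, affine: np.ndarray, shape) -> np.ndarray:
    """Unique voxel indices intersected by a streamline's points (in-grid)."""
    inv = np.linalg.inv(affine)
    vox = np.floor(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    inside = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    vox = vox[inside]
    if len(vox) == 0:
        return vox
    return np.unique(vox, axis=0)


# ---------------------------------------------------------------------------
# refinement filters

def atlas_probability_filter(
    tractogram: Tractogram,
    probability_map: np.ndarray,
    affine: np.ndarray,
    threshold: float = 0.2,
):
    """Keep streamlines whose mean atlas probability is >= ``threshold``.

    The score of a streamline is the mean of the probability map over the
    unique voxels it intersects.  Streamlines entirely outside the map are
    discarded and counted separately.

    Returns (filtered tractogram, counts dict).
    """
    pmap = np.asarray(probability_map, dtype=float)
    if pmap.min() < 0 or pmap.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    keep, n_outside, n_low = [], 0, 0
    for i, sl in enumerate(tractogram.streamlines):
        vox = _streamline_voxels(sl, affine, pmap.shape)
        if len(vox) == 0:
            n_outside += 1
            continue
        score = pmap[vox[:, 0], vox[:, 1], vox[:, 2]].mean()
        if score < threshold:
            n_low += 1
        else:
            keep.append(i)
    counts = {"kept": len(keep), "discarded_low_score": n_low, "discarded_outside": n_outside}
    return tractogram.subset(np.array(keep, dtype=int)), counts


def resample_streamline(points: np.ndarray, n: int = 50) -> np.ndarray:
    """Resample a polyline to ``n`` points equidistant in arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(points[:1], n, axis=0)
    t = np.linspace(0, s[-1], n)
    return np.column_stack([np.interp(t, s, points[:, k]) for k in range(3)])


def _tract_core(resampled: np.ndarray) -> np.ndarray:
    """Point-wise mean after orienting streamlines against a running mean."""
    core = resampled[0].copy()
    aligned = [resampled[0]]
    for sl in resampled[1:]:
        fwd = np.linalg.norm(sl[0] - core[0]) + np.linalg.norm(sl[-1] - core[-1])
        rev = np.linalg.norm(sl[-1] - core[0]) + np.linalg.norm(sl[0] - core[-1])
        sl = sl if fwd <= rev else sl[::-1]
        aligned.append(sl)
        core = np.mean(aligned, axis=0)
    return np.mean(aligned, axis=0), np.array(aligned)


def outlier_filter(
    tractogram: Tractogram,
    length_sd: float = 4.0,
    deviation_sd: float = 5.0,
    n_core_points: int = 50,
) -> Tractogram:
    """Remove length and core-deviation outliers (length pass first).

    Streamlines strictly longer than mean + ``length_sd``·SD are removed;
    the survivors define the tract core (point-wise mean of 50-point
    resamplings) and streamlines whose mean distance to the core strictly
    exceeds mean + ``deviation_sd``·SD of deviations are removed.  With a
    single streamline (SD undefined) nothing is removed.
    """
    n = len(tractogram)
    if n == 0:
        return tractogram
    if n == 1:
        return tractogram.subset(np.array([0]))
    lengths = tractogram.lengths()
    keep = lengths <= lengths.mean() + length_sd * lengths.std()
    t = tractogram.subset(keep)
    if len(t) <= 1:
        return t
    resampled = np.array([resample_streamline(sl, n_core_points) for sl in t.streamlines])
    core, aligned = _tract_core(resampled)
    dev = np.linalg.norm(aligned - core, axis=2).mean(axis=1)
    keep2 = dev <= dev.mean() + deviation_sd * dev.std()
    return t.subset(keep2)


def density_map(tractogram: Tractogram, shape, affine: np.ndarray) -> np.ndarray:
    """Fraction of the tract's streamlines intersecting each voxel."""
    if len(tractogram) == 0:
        raise ValueError("empty tractogram")
    dens = np.zeros(shape)
    for sl in tractogram.streamlines:
        vox = _streamline_voxels(sl, affine, shape)
        if len(vox):
            dens[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return dens / len(tractogram)


# ---------------------------------------------------------------------------
# fixels

@dataclass
class FixelMaps:
    """Per-voxel fixel directions with per-tract densities and masks.

    ``directions`` maps voxel index tuples to (F, 3) arrays; ``density``
    and ``mask`` are per-voxel (F,) arrays for one tract.
    """

    directions: dict
    density: dict
    mask: dict
    n_streamlines: int
    unassigned_visits: int = 0

    def masked_fixels(self) -> set:
        out = set()
        for vox, m in self.mask.items():
            for fi in np.nonzero(m)[0]:
                out.add((vox, int(fi)))
        return out


def assign_fixels(
    tractogram: Tractogram,
    peak_directions: dict,
    shape,
    affine: np.ndarray,
    density_threshold: float = 0.05,
) -> FixelMaps:
    """Assign streamline-voxel visits to best-aligned fixels.

    ``peak_directions`` maps voxel index tuples (i, j, k) to (F, 3) unit
    direction arrays (from FOD peak extraction).  Each visit is assigned to
    the fixel maximising |dot| with the local streamline tangent; the
    per-tract fixel density (assigned streamlines / total streamlines) is
    thresholded at ``density_threshold`` of the tract's maximum fixel
    density to produce the fixel mask.
    """
    if len(tractogram) == 0:
        raise ValueError("empty tractogram")
    inv = np.linalg.inv(affine)
    counts: dict = {}
    unassigned = 0
    for sl in tractogram.streamlines:
        vox = np.floor(sl @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        inside = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
        tang = np.gradient(sl, axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        seen = set()
        for p in range(len(sl)):
            if not inside[p]:
                continue
            key = tuple(vox[p])
            if key in seen:
                continue
            seen.add(key)
            dirs = peak_directions.get(key)
            if dirs is None or len(dirs) == 0:
                unassigned += 1
                continue
            fi = int(np.argmax(np.abs(np.asarray(dirs) @ tang[p])))
            counts[(key, fi)] = counts.get((key, fi), 0) + 1
    density: dict = {}
    for (vox, fi), c in counts.items():
        arr = density.setdefault(vox, np.zeros(len(peak_directions[vox])))
        arr[fi] = c / len(tractogram)
    dmax = max((a.max() for a in density.values()), default=0.0)
    mask = {vox: a >= density_threshold * dmax for vox, a in density.items()} if dmax > 0 else {}
    return FixelMaps(
        directions={v: np.asarray(peak_directions[v]) for v in density},
        density=density,
        mask=mask,
        n_streamlines=len(tractogram),
        unassigned_visits=unassigned,
    )


def bottleneck_mask(fixel_maps: list[FixelMaps]):
    """Fixels used by >= 2 tracts ("multi-bundle fixels") and counts.

    Returns (multi_bundle set of (voxel, fixel) keys, counts dict).
    """
    if len(fixel_maps) < 2:
        raise ValueError("need fixel masks from at least two tracts")
    usage: dict = {}
    for fm in fixel_maps:
        for key in fm.masked_fixels():
            usage[key] = usage.get(key, 0) + 1
    multi = {k for k, c in usage.items() if c >= 2}
    counts = {
        "single_bundle": sum(1 for c in usage.values() if c == 1),
        "multi_bundle": len(multi),
        "total": len(usage),
    }
    return multi, counts


def crossing_fibre_ratio(peak_counts: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of fibre-containing masked voxels with >= 2 FOD peaks."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    pc = np.asarray(peak_counts)
    fibre = mask & (pc >= 1)
    n_fibre = int(fibre.sum())
    if n_fibre == 0:
        raise ValueError("no fibre-containing voxels in mask")
    return float((pc[fibre] >= 2).sum() / n_fibre)


# ---------------------------------------------------------------------------
# connectivity and tracer comparison

@dataclass
class ConnectivityMatrix:
    """Seed-region x target-region matrix of normalised streamline fractions
    (or reference FLNe weights)."""

    values: np.ndarray
    seed_labels: list
    target_labels: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.seed_labels), len(self.target_labels)):
            raise ValueError("matrix shape must match label lists")
        if np.any(self.values < 0):
            raise ValueError("connectivity entries must be non-negative")


def connectivity_matrix(
    tractograms_by_seed: dict,
    label_image: np.ndarray,
    affine: np.ndarray,
    target_labels: list,
) -> ConnectivityMatrix:
    """Streamline-fraction connectivity: row r, column c is the fraction of
    streamlines seeded in region r terminating in region c.

    A streamline's target is the label at its endpoint(s): the final point
    is preferred; if it is unlabelled (or labels the seed region itself) the
    first point is consulted.  Seed regions with zero streamlines yield a
    zero row.
    """
    label_image = np.asarray(label_image)
    inv = np.linalg.inv(affine)
    seed_labels = list(tractograms_by_seed.keys())
    values = np.zeros((len(seed_labels), len(target_labels)))
    col = {lab: j for j, lab in enumerate(target_labels)}
    for i, seed_lab in enumerate(seed_labels):
        t = tractograms_by_seed[seed_lab]
        if len(t) == 0:
            continue
        for sl in t.streamlines:
            assigned = None
            for p in (sl[-1], sl[0]):
                v = np.floor(p @ inv[:3, :3].T + inv[:3, 3]).astype(int)
                if np.any(v < 0) or np.any(v >= np.array(label_image.shape)):
                    continue
                lab = label_image[tuple(v)]
                if lab != 0 and lab != seed_lab and lab in col:
                    assigned = lab
                    break
            if assigned is not None:
                values[i, col[assigned]] += 1
        values[i] /= len(t)
    return ConnectivityMatrix(values, seed_labels, list(target_labels))


@dataclass
class RocCurve:
    """ROC of binarised prediction vs binarised reference connectivity."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    auc: float

    @property
    def tpr(self) -> np.ndarray:
        return self.tp / np.maximum(self.tp + self.fn, 1)

    @property
    def tnr(self) -> np.ndarray:
        return self.tn / np.maximum(self.tn + self.fp, 1)


def _as_values(m) -> np.ndarray:
    return m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)


def roc_vs_reference(
    pred,
    ref,
    ref_threshold: float = 1e-4,
    pred_thresholds: np.ndarray | None = None,
) -> RocCurve:
    """ROC curve of ``pred`` against ``ref`` binarised at ``ref_threshold``.

    Prediction cells are called positive when strictly above each threshold
    (default 101 thresholds evenly spaced on [0, 0.25]); AUC is the
    trapezoidal integral over (1 - TNR, TPR).
    """
    P, R = _as_values(pred), _as_values(ref)
    if P.shape != R.shape:
        raise ValueError("prediction and reference shapes differ")
    if pred_thresholds is None:
        pred_thresholds = np.linspace(0.0, 0.25, 101)
    positive = R >= ref_threshold
    if positive.all() or not positive.any():
        raise ValueError("reference is all-positive or all-negative; AUC undefined")
    tp, fp, tn, fn = [], [], [], []
    for t in pred_thresholds:
        call = P > t
        tp.append(int((call & positive).sum()))
        fp.append(int((call & ~positive).sum()))
        tn.append(int((~call & ~positive).sum()))
        fn.append(int((~call & positive).sum()))
    tp, fp, tn, fn = map(np.array, (tp, fp, tn, fn))
    tpr = tp / (tp + fn)
    fpr = fp / (fp + tn)
    order = np.lexsort((tpr, fpr))
    x = np.concatenate([[0.0], fpr[order], [1.0]])
    y = np.concatenate([[0.0], tpr[order], [1.0]])
    auc = float(np.trapezoid(y, x))
    return RocCurve(np.asarray(pred_thresholds), tp, fp, tn, fn, auc)


def overlap_matrix(pred, ref, pred_threshold: float, ref_threshold: float = 1e-4):
    """Categorise cells as both / pred-only / ref-only / neither.

    Returns (category array of strings, counts dict); "pred-only" cells are
    tractography false positives against the tracer reference.
    """
    P, R = _as_values(pred), _as_values(ref)
    if P.shape != R.shape:
        raise ValueError("prediction and reference shapes differ")
    p = P > pred_threshold
    r = R >= ref_threshold
    cat = np.full(P.shape, "neither", dtype=object)
    cat[p & r] = "both"
    cat[p & ~r] = "pred-only"
    cat[~p & r] = "ref-only"
    counts = {
        "both": int((p & r).sum()),
        "pred-only": int((p & ~r).sum()),
        "ref-only": int((~p & r).sum()),
        "neither": int((~p & ~r).sum()),
        "false_positive": int((p & ~r).sum()),
    }
    return cat, counts


def log_correlation(pred, ref, pred_floor: float = 1e-4, ref_floor: float = 1e-6):
    """Pearson correlation of log10 connection weights above both floors.

    Returns (rho, n_kept); raises when fewer than 3 cells survive.
    """
    P, R = _as_values(pred), _as_values(ref)
    if P.shape != R.shape:
        raise ValueError("prediction and reference shapes differ")
    keep = (P > pred_floor) & (R > ref_floor)
    n = int(keep.sum())
    if n < 3:
        raise ValueError("fewer than 3 cells above both floors; correlation undefined")
    rho, _ = stats.pearsonr(np.log10(P[keep]), np.log10(R[keep]))
    return float(rho), n
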