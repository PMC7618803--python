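"""Resolve a bottleneck and score connectivity against a reference.

Two parallel bundles 0.5 mm apart share voxels (and fixels) on a 1.0 mm
grid but separate cleanly at 0.2 mm.  Streamlines seeded in one bundle's
origin are refined (atlas-probability and outlier filters) and assigned to
fixels; fixels used by both tracts mark the bottleneck.  Finally the
tract endpoints build a connectivity matrix that is compared to the
phantom's ground-truth connections via ROC.
"""

import numpy as np

from hybridfod import (
    TrackingParams,
    assign_fixels,
    atlas_probability_filter,
    bottleneck_mask,
    build_fod_image,
    connectivity_matrix,
    fod_peaks,
    grid_affine,
    hybrid_field,
    make_phantom,
    outlier_filter,
    parallel_pair_spec,
    roc_vs_reference,
    seed_points,
    track,
)
from hybridfod.evaluate import ConnectivityMatrix
from hybridfod.fod import normalise_unit_peak

ph = make_phantom(parallel_pair_spec())
hs = hybrid_field(ph.angle_maps, ph.pixel_maps, ph.bas, seed=5)
z_centres = {0: 1.5, 1: 2.0}
tracts = {}

for res in (1.0, 0.2):
    shape = tuple(int(np.ceil(e / res)) for e in ph.spec.extent)
    A = grid_affine(res)
    img = normalise_unit_peak(build_fod_image(hs, shape, A))
    peaks = {
        tuple(ijk): fod_peaks(img.coeffs[tuple(ijk)]).directions
        for ijk in np.argwhere(img.provenance == 1)
    }
    fms = []
    for b, zc in z_centres.items():
        centres = (np.indices(shape).reshape(3, -1).T + 0.5) * res
        mask = (centres[:, 0] < 1.6) & (np.abs(centres[:, 2] - zc) <= res / 2 + 0.26)
        mask = mask.reshape(shape) & (img.provenance == 1)
        tg = track(img, seed_points(mask, A, 30, seed=6 + b), TrackingParams(seed=8 + b))
        tg, _ = atlas_probability_filter(tg, ph.probability_maps[b], ph.spec.affine, 0.2)
        tg = outlier_filter(tg)
        fms.append(assign_fixels(tg, peaks, shape, A))
        if res == 0.2:
            tracts[b] = tg
    _, counts = bottleneck_mask(fms)
    print(f"{res:.1f} mm grid: {counts['multi_bundle']} multi-bundle fixels "
          f"({counts['total']} used in total)")

# connectivity of the 0.2 mm tracts against the phantom's ground truth
conn = connectivity_matrix(
    {1: tracts[0], 3: tracts[1]}, ph.labels, ph.spec.affine,
    ph.truth.region_labels,
)
rows = [ph.truth.region_labels.index(s) for s in conn.seed_labels]
ref = ConnectivityMatrix(
    ph.truth.connectivity[rows], conn.seed_labels, ph.truth.region_labels
)
curve = roc_vs_reference(conn, ref, pred_thresholds=np.linspace(0, 0.25, 101))
print(f"connectivity rows (seed 1): {np.round(conn.values[0], 2)}")
print(f"ROC AUC vs ground truth:    {curve.auc:.3f}")
print("(fewer shared fixels at 0.2 mm = resolved bottleneck; AUC 1.0 means the")
print(" tracts connect exactly the regions their bundles were built to connect)")
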