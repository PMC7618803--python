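"""Build FODs at several resolutions and track a straight bundle.

Hybrid axes from a single-bundle phantom are binned into 256-point
orientation histograms per voxel and fitted with order-8 even spherical
harmonics at 1.0 / 0.6 / 0.4 mm.  The same orientations produce FODs at
every resolution (total histogram mass is conserved), and the stand-in
probabilistic tracker reconstructs the bundle end to end.
"""

import numpy as np

from hybridfod import (
    TrackingParams,
    build_fod_image,
    fod_peaks,
    grid_affine,
    hybrid_field,
    make_phantom,
    single_bundle_spec,
    track,
)
from hybridfod.fod import normalise_unit_peak

ph = make_phantom(single_bundle_spec())
hs = hybrid_field(ph.angle_maps, ph.pixel_maps, ph.bas, seed=2)
print(f"hybrid orientations: {len(hs)}")

extent = np.array([9.0, 3.6, 3.6])
for res in (1.0, 0.6, 0.4):
    shape = tuple(int(np.ceil(e / res)) for e in extent)
    img = build_fod_image(hs, shape, grid_affine(res))
    occupied = int((img.provenance == 1).sum())
    centres = (np.indices(shape).reshape(3, -1).T + 0.5) * res
    in_bundle = np.linalg.norm(centres[:, 1:] - [1.8, 1.8], axis=1) <= 0.6
    in_bundle &= (centres[:, 0] > 1.0) & (centres[:, 0] < 8.0)
    worst = 0.0
    for ijk in np.argwhere(in_bundle.reshape(shape)):
        pk = fod_peaks(img.coeffs[tuple(ijk)])
        if len(pk):
            worst = max(worst, np.rad2deg(np.arccos(min(1, abs(pk.directions[0][0])))))
    print(f"{res:.1f} mm grid: {occupied:4d} occupied voxels, "
          f"worst in-bundle peak deviation from the bundle axis {worst:.1f} deg")

# track through the 0.6 mm FODs (0.2 mm steps, 0.05 cutoff, 5-120 mm)
fod = normalise_unit_peak(build_fod_image(hs, (15, 6, 6), grid_affine(0.6)))
seeds = np.tile([4.5, 1.8, 1.8], (50, 1))  # bundle midpoint
tg = track(fod, seeds, TrackingParams(seed=3))
lengths = tg.lengths()
print(f"streamlines kept: {len(tg)}/50, median length {np.median(lengths):.1f} mm")
print("(the bundle spans ~9 mm; full-length streamlines mean the tracker")
print(" followed the FOD tube from end to end)")
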