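"""Fuse microscopy in-plane angles with Ball-and-Stick samples.

Generates the default study phantom (crossing bundles, an in-plane U-bend,
a bottleneck pair and an oblique bundle) twice — once noiseless, once at
the standard noise level (Watson kappa=50 BAS scatter, 3-degree microscopy
noise) — and reconstructs 3D hybrid axes for every microscopy pixel.  The
printed errors show that the fusion is exact in the noiseless limit and
beats the raw diffusion samples under noise.
"""

import numpy as np

from hybridfod import default_spec, hybrid_field, make_phantom


def median_error(phantom, hybrid):
    truth = np.array(
        [phantom.truth.pixel_axes[m][r, c] for m, r, c in hybrid.pixel_indices]
    )
    return np.rad2deg(
        np.median(np.arccos(np.clip(np.abs(np.sum(hybrid.axes * truth, -1)), 0, 1)))
    )


# noiseless limit: BAS samples equal the population axes, angles exact
ph0 = make_phantom(default_spec(kappa=np.inf, microscopy_noise_deg=0.0))
hs0 = hybrid_field(ph0.angle_maps, ph0.pixel_maps, ph0.bas, seed=1)
print(f"pixels matched (noiseless):        {len(hs0)}")
print(f"median error, noiseless (deg):     {median_error(ph0, hs0):.2e}")

# standard noise: the fusion should sit between microscopy (3 deg, in-plane
# only) and the raw BAS samples (~7 deg, 3D)
ph = make_phantom(default_spec())
hs = hybrid_field(ph.angle_maps, ph.pixel_maps, ph.bas, seed=1)
live = np.argwhere(ph.truth.voxel_fractions > 0)
bas_err = np.concatenate(
    [
        np.arccos(
            np.clip(np.abs(ph.bas.samples[i, j, k, p] @ ph.truth.voxel_axes[i, j, k, p]), 0, 1)
        )
        for i, j, k, p in live[::5]
    ]
)
print(f"median error, hybrid (deg):        {median_error(ph, hs):.2f}")
print(f"median error, raw BAS (deg):       {np.rad2deg(np.median(bas_err)):.2f}")
print("(the hybrid axes inherit microscopy's in-plane precision and only the")
print(" through-plane component carries the diffusion-sample uncertainty)")
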