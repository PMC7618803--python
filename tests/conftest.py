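import numpy as np
import pytest

import hybridfod as h


@pytest.fixture(scope="session")
def frame_z():
    """Plane frame with u=x, v=y, n=z."""
    return h.PlaneFrame.axis_aligned(2)


@pytest.fixture(scope="session")
def zero_noise_phantom():
    """Default study phantom in the noiseless limit (exact BAS and angles)."""
    spec = h.default_spec(kappa=np.inf, microscopy_noise_deg=0.0)
    return h.make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default study phantom at the standard noise level (kappa=50, 3 deg)."""
    return h.make_phantom(h.default_spec())


@pytest.fixture(scope="session")
def single_bundle_phantom():
    return h.make_phantom(h.single_bundle_spec())


@pytest.fixture(scope="session")
def single_bundle_hybrid(single_bundle_phantom):
    ph = single_bundle_phantom
    return h.hybrid_field(ph.angle_maps, ph.pixel_maps, ph.bas, seed=11)


@pytest.fixture(scope="session")
def parallel_pair_phantom():
    return h.make_phantom(h.parallel_pair_spec())


def pixel_truth_axes(phantom, hybrid):
    """Ground-truth axis for every hybrid record."""
    return np.array(
        [phantom.truth.pixel_axes[m][r, c] for m, r, c in hybrid.pixel_indices]
    )


def population_retained(phantom, hybrid):
    """True where the record's own bundle population survived the 0.05
    signal-fraction exclusion in its voxel."""
    tb = np.array(
        [phantom.truth.pixel_bundles[m][r, c] for m, r, c in hybrid.pixel_indices]
    )
    vb = phantom.truth.voxel_bundles[tuple(hybrid.voxel_indices.T)]
    vf = phantom.truth.voxel_fractions[tuple(hybrid.voxel_indices.T)]
    out = np.zeros(len(hybrid), dtype=bool)
    for i in range(len(hybrid)):
        own = vb[i] == tb[i]
        out[i] = own.any() and vf[i][own].max() >= phantom.bas.min_fraction
    return out


def axis_error(a, b):
    """Undirected angular error between unit axes (radians)."""
    return np.arccos(np.clip(np.abs(np.sum(a * b, axis=-1)), 0.0, 1.0))
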