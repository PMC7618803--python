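import numpy as np
import pytest

import hybridfod as h
from hybridfod.fod import (
    FodImage,
    build_fod_image,
    fit_sh,
    fod_peaks,
    grid_affine,
    max_peak_amplitude,
    normalise_unit_peak,
    orientation_histogram,
    scale_fod,
    sphere_points,
)
from hybridfod.sh import eval_sh, n_coeffs, sh_basis

from conftest import axis_error


@pytest.fixture(scope="module")
def points():
    return sphere_points()


class TestSpherePoints:
    def test_default_count_and_unit_norm(self, points):
        assert points.points.shape == (256, 3)
        assert np.allclose(np.linalg.norm(points.points, axis=1), 1.0)

    def test_exact_antipodal_pairing(self, points):
        for i in range(points.n_pairs):
            j = points.antipode_index(i)
            assert np.array_equal(points.points[j], -points.points[i])
            assert points.antipode_index(j) == i

    def test_minimal_pairwise_angle_exceeds_7deg(self, points):
        d = np.clip(points.points @ points.points.T, -1, 1)
        np.fill_diagonal(d, -1)
        assert np.rad2deg(np.arccos(d.max())) > 7.0

    def test_determinism(self):
        assert np.array_equal(sphere_points().points, sphere_points().points)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            sphere_points(4)


class TestOrientationHistogram:
    def test_empty_input_all_zero(self, points):
        assert orientation_histogram(np.empty((0, 3)), points).sum() == 0

    def test_axis_on_a_set_point(self, points):
        ax = np.tile(points.points[10], (7, 1))
        counts = orientation_histogram(ax, points)
        assert counts[10] == 7
        assert counts[points.antipode_index(10)] == 7
        assert counts.sum() == 14

    def test_mass_conservation_random(self, points):
        rng = np.random.default_rng(0)
        axes = rng.normal(size=(321, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        assert orientation_histogram(axes, points).sum() == 2 * 321

    def test_antipodal_input_invariance(self, points):
        rng = np.random.default_rng(1)
        axes = rng.normal(size=(40, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        a = orientation_histogram(axes, points)
        b = orientation_histogram(-axes, points)
        assert np.array_equal(a, b)


class TestFitSh:
    def test_uniform_counts_pure_l0(self, points):
        c = fit_sh(np.ones(256), points)
        assert abs(c[0]) > 1e-3
        assert np.abs(c[1:]).max() < 1e-10 * abs(c[0])

    def test_band_limited_recovery(self, points):
        """The LS fit on 256 points recovers any even function of order <= 8
        exactly (up to the unit-mass normalisation)."""
        rng = np.random.default_rng(2)
        B = sh_basis(points.points, 8)
        for _ in range(5):
            c = rng.normal(size=n_coeffs(8))
            c[0] = 3.0 + abs(c[0])  # keep the sampled sum positive
            vals = B @ c
            fitted = fit_sh(vals, points) * vals.sum()
            assert np.abs(fitted - c).max() / np.abs(c).max() < 1e-8

    def test_empty_histogram_zero_coefficients(self, points):
        assert np.array_equal(fit_sh(np.zeros(256), points), np.zeros(45))

    def test_single_axis_argmax_near_input(self, points):
        ax = points.points[40]
        c = fit_sh(orientation_histogram(ax[None], points), points)
        dense = sphere_points(1000).points
        best = dense[np.argmax(eval_sh(c, dense))]
        assert np.rad2deg(axis_error(best, ax)) < 5.0

    def test_emitted_fods_antipodally_symmetric(self, points):
        rng = np.random.default_rng(3)
        axes = rng.normal(size=(30, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        c = fit_sh(orientation_histogram(axes, points), points)
        dirs = rng.normal(size=(50, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert np.allclose(eval_sh(c, dirs), eval_sh(c, -dirs), atol=1e-12)


class TestFodPeaks:
    def test_single_axis_single_peak(self, points):
        ax = points.points[25]
        c = fit_sh(orientation_histogram(np.tile(ax, (5, 1)), points), points)
        pk = fod_peaks(c)
        assert len(pk) == 1
        assert np.rad2deg(axis_error(pk.directions[0], ax)) < 5.0

    def test_two_orthogonal_axes_two_peaks(self, points):
        axes = np.vstack([np.tile([0, 0, 1.0], (5, 1)), np.tile([1.0, 0, 0], (5, 1))])
        c = fit_sh(orientation_histogram(axes, points), points)
        pk = fod_peaks(c)
        assert len(pk) == 2
        sep = np.rad2deg(axis_error(pk.directions[0], pk.directions[1]))
        assert sep >= 85.0

    def test_zero_fod_no_peaks(self):
        assert len(fod_peaks(np.zeros(45))) == 0

    def test_amplitudes_descending_and_separated(self, points):
        axes = np.vstack([np.tile([0, 0, 1.0], (6, 1)), np.tile([1.0, 1.0, 0], (4, 1))])
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        pk = fod_peaks(fit_sh(orientation_histogram(axes, points), points))
        assert np.all(np.diff(pk.amplitudes) <= 0)
        for i in range(len(pk)):
            for j in range(i + 1, len(pk)):
                assert np.rad2deg(axis_error(pk.directions[i], pk.directions[j])) > 25


class TestScaleFod:
    def test_self_reference_scale_one(self, points):
        c = fit_sh(orientation_histogram(np.array([[0, 0, 1.0]]), points), points)
        assert np.allclose(scale_fod(c, c), c)

    def test_doubled_reference_doubles_coefficients(self, points):
        c = fit_sh(orientation_histogram(np.array([[0, 1.0, 0]]), points), points)
        assert np.allclose(scale_fod(c, 2 * c), 2 * c)

    def test_random_pairs_match_max_peaks(self, points):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(size=45)
            b = rng.normal(size=45)
            a[0], b[0] = 2 + abs(a[0]), 2 + abs(b[0])
            scaled = scale_fod(a, b)
            ra = max_peak_amplitude(scaled)
            rb = max_peak_amplitude(b)
            assert abs(ra - rb) / rb < 1e-6

    def test_scaling_idempotent(self, points):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=45), rng.normal(size=45)
        a[0], b[0] = 2.0, 2.0
        once = scale_fod(a, b)
        twice = scale_fod(once, b)
        assert np.allclose(once, twice, atol=1e-9)

    def test_zero_hybrid_stays_zero(self):
        assert np.array_equal(scale_fod(np.zeros(45), np.ones(45)), np.zeros(45))

    def test_zero_reference_unit_max(self, points):
        c = fit_sh(orientation_histogram(np.array([[1.0, 0, 0]]), points), points)
        scaled = scale_fod(c, np.zeros(45))
        assert abs(max_peak_amplitude(scaled) - 1.0) < 1e-9

    def test_l0_mode(self):
        a = np.zeros(45)
        a[0] = 0.5
        b = np.zeros(45)
        b[0] = 1.5
        assert np.isclose(scale_fod(a, b, method="l0")[0], 1.5)


def _hybrid_from(positions, axes):
    n = len(positions)
    return h.HybridOrientationSet(
        np.asarray(positions, float), np.asarray(axes, float),
        np.zeros((n, 3), int), np.zeros((n, 3), int), np.zeros(n, int),
    )


class TestBuildFodImage:
    def test_gap_fill_copies_reference_exactly(self):
        rng = np.random.default_rng(6)
        ref_coeffs = rng.normal(size=(2, 2, 2, 45))
        ref = FodImage(ref_coeffs, grid_affine(1.0))
        hybrid = _hybrid_from(np.array([[0.5, 0.5, 0.5]]), np.array([[1.0, 0, 0]]))
        img = build_fod_image(hybrid, (2, 2, 2), grid_affine(1.0), reference=ref)
        assert img.provenance[0, 0, 0] == 1
        gaps = img.provenance == 2
        assert gaps.sum() == 7
        assert np.array_equal(img.coeffs[gaps], ref_coeffs[gaps])

    def test_histogram_mass_conserved_across_resolutions(self, single_bundle_hybrid):
        """The same orientation set binned at 1.0 / 0.6 / 0.4 mm keeps the
        identical total histogram mass (2 per contained axis)."""
        hs = single_bundle_hybrid
        extent = np.array([9.0, 3.6, 3.6])
        pts = sphere_points()
        masses = []
        for res in (1.0, 0.6, 0.4):
            shape = tuple(int(np.ceil(e / res)) for e in extent)
            inv = np.linalg.inv(grid_affine(res))
            vox = np.floor(hs.positions @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            inside = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
            total = 0.0
            vflat = np.ravel_multi_index(vox[inside].T, shape)
            for grp in np.split(np.argsort(vflat), np.nonzero(np.diff(np.sort(vflat)))[0] + 1):
                total += orientation_histogram(
                    hs.axes[inside][grp], pts
                ).sum()
            masses.append(total)
        assert masses[0] == masses[1] == masses[2] == 2 * int(
            np.all(hs.positions >= 0, axis=1).sum()
        )

    def test_single_bundle_peaks_follow_tangent(self, single_bundle_hybrid, single_bundle_phantom):
        ph = single_bundle_phantom
        tangent = np.array([1.0, 0.0, 0.0])
        extent = np.array([9.0, 3.6, 3.6])
        for res in (1.0, 0.6, 0.4):
            shape = tuple(int(np.ceil(e / res)) for e in extent)
            img = build_fod_image(single_bundle_hybrid, shape, grid_affine(res))
            centres = (np.indices(shape).reshape(3, -1).T + 0.5) * res
            inside = np.linalg.norm(
                centres[:, 1:] - np.array([1.8, 1.8]), axis=1
            ) <= 0.6
            inside &= (centres[:, 0] > 1.0) & (centres[:, 0] < 8.0)
            for ijk in np.argwhere(inside.reshape(shape)):
                pk = fod_peaks(img.coeffs[tuple(ijk)])
                assert len(pk) >= 1
                assert np.rad2deg(axis_error(pk.directions[0], tangent)) < 5.0

    def test_provenance_empty_without_reference(self):
        hybrid = _hybrid_from(np.array([[0.5, 0.5, 0.5]]), np.array([[0, 1.0, 0]]))
        img = build_fod_image(hybrid, (2, 2, 2), grid_affine(1.0))
        assert img.provenance[0, 0, 0] == 1
        assert (img.provenance == 0).sum() == 7
        assert np.array_equal(img.coeffs[img.provenance == 0], np.zeros((7, 45)))

    def test_unit_peak_normalisation(self, single_bundle_hybrid):
        img = build_fod_image(single_bundle_hybrid, (9, 4, 4), grid_affine(1.0))
        unit = normalise_unit_peak(img)
        occupied = unit.provenance == 1
        flat = unit.coeffs[occupied]
        assert np.allclose(max_peak_amplitude(flat), 1.0, atol=1e-9)
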