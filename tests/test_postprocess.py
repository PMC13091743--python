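"""Post-processing chain: prostate extraction, centerline fit, urethra, zones."""

import numpy as np
import pytest
from scipy import ndimage

import zoneline as zl
from zoneline.errors import EmptyProstateWarning, NoUrethraError, UniformWeightWarning
from zoneline.postprocess import _nearest_zone_bruteforce, _nearest_zone_edt


def _probs_from_foreground(geom, fg_mask, fg_code=4):
    """One-hot probability volume with the given foreground voxels as one class."""
    data = np.zeros(geom.shape, np.int16)
    data[fg_mask] = fg_code
    return zl.one_hot(zl.LabelVolume(geom, data))


class TestExtractProstate:
    def test_all_background_yields_empty_mask_with_warning(self, geom_iso):
        prob = _probs_from_foreground(geom_iso, np.zeros(geom_iso.shape, bool))
        with pytest.warns(EmptyProstateWarning):
            mask = zl.extract_prostate(prob)
        assert not mask.any()

    def test_single_voxel_component(self, geom_iso):
        fg = np.zeros(geom_iso.shape, bool)
        fg[3, 4, 5] = True
        mask = zl.extract_prostate(_probs_from_foreground(geom_iso, fg))
        assert np.array_equal(mask, fg)

    def test_keeps_only_largest_component(self, geom_iso):
        # two disjoint blobs of 5 and 3 voxels; oracle = exhaustive labelling
        fg = np.zeros(geom_iso.shape, bool)
        fg[1, 1, 1:6] = True  # 5 voxels
        fg[6, 6, 0:3] = True  # 3 voxels, far away
        mask = zl.extract_prostate(_probs_from_foreground(geom_iso, fg))
        labelled, n = ndimage.label(fg, structure=np.ones((3, 3, 3)))
        assert n == 2
        sizes = ndimage.sum_labels(fg, labelled, range(1, n + 1))
        expected = labelled == (1 + int(np.argmax(sizes)))
        assert np.array_equal(mask, expected)
        assert mask.sum() == 5


class TestSliceCandidates:
    def _prob_with_urethra_plane(self, geom, plane_by_slice):
        data = np.zeros((6,) + geom.shape)
        data[1] = plane_by_slice  # urethra class
        data[0] = 1.0 - data.sum(axis=0)
        return zl.ProbabilityVolume(geom, data)

    def test_single_max_voxel(self, geom_iso):
        u = np.zeros(geom_iso.shape)
        u[2, 3, 5] = 1.0
        prob = self._prob_with_urethra_plane(geom_iso, u)
        cands = zl.slice_candidates(prob, np.ones(geom_iso.shape, bool))
        by_slice = {c.slice_index: c for c in cands}
        assert by_slice[2].centre_mm == (5.0, 3.0)
        assert by_slice[2].weight == 1.0

    def test_tied_voxels_use_centre_of_mass(self):
        geom = zl.VolumeGeometry(spacing_mm=(1.0, 1.0, 1.0), shape=(3, 8, 8))
        u = np.zeros(geom.shape)
        u[1, 2, 1] = 0.6  # x = 1.0 mm
        u[1, 2, 2] = 0.6  # x = 2.0 mm, same y
        prob = self._prob_with_urethra_plane(geom, u)
        cands = [c for c in zl.slice_candidates(prob, np.ones(geom.shape, bool)) if c.slice_index == 1]
        assert cands[0].centre_mm == (1.5, 2.0)
        assert cands[0].weight == pytest.approx(0.6)

    def test_zero_probability_slice_has_no_candidate(self, geom_iso):
        u = np.zeros(geom_iso.shape)
        u[0, 1, 1] = 0.5
        prob = self._prob_with_urethra_plane(geom_iso, u)
        cands = zl.slice_candidates(prob, np.ones(geom_iso.shape, bool))
        assert [c.slice_index for c in cands] == [0]


class TestFitCenterline:
    GEOM = zl.VolumeGeometry(spacing_mm=(1.0, 1.0, 1.0), shape=(8, 8, 8))

    @staticmethod
    def _cand(i, x, y, w=1.0):
        return zl.SliceCandidate(i, (x, y), w)

    def test_exact_quadratic_recovery(self):
        cands = [self._cand(z, z**2, 0.0) for z in range(4)]
        curve = zl.fit_centerline(cands, self.GEOM)
        assert np.allclose(curve.coeff_x, (1, 0, 0), atol=1e-9)
        assert np.allclose(curve.coeff_y, (0, 0, 0), atol=1e-9)

    def test_zero_weight_outlier_is_ignored(self):
        base = [self._cand(z, 2.0 * z + 1.0, -z, 1.0) for z in range(5)]
        with_outlier = base + [self._cand(2, 500.0, -500.0, 0.0)]
        c_ref = zl.fit_centerline(base, self.GEOM)
        c_out = zl.fit_centerline(with_outlier, self.GEOM)
        assert np.allclose(c_out.coeff_x, c_ref.coeff_x, atol=1e-9)
        assert np.allclose(c_out.coeff_y, c_ref.coeff_y, atol=1e-9)

    def test_two_slices_reduce_to_exact_line(self):
        cands = [self._cand(0, 1.0, 5.0), self._cand(3, 7.0, -1.0)]
        curve = zl.fit_centerline(cands, self.GEOM)
        assert curve.coeff_x[0] == 0.0 and curve.coeff_y[0] == 0.0
        assert np.allclose(curve(0.0), (1.0, 5.0), atol=1e-9)
        assert np.allclose(curve(3.0), (7.0, -1.0), atol=1e-9)

    def test_single_slice_gives_constant_curve(self):
        curve = zl.fit_centerline([self._cand(2, 4.0, 6.0)], self.GEOM)
        assert np.allclose(curve(17.3), (4.0, 6.0))

    def test_empty_candidates_raise(self):
        with pytest.raises(NoUrethraError):
            zl.fit_centerline([], self.GEOM)

    def test_all_zero_weights_fall_back_to_uniform(self):
        cands = [self._cand(z, float(z), 0.0, 0.0) for z in range(4)]
        with pytest.warns(UniformWeightWarning):
            curve = zl.fit_centerline(cands, self.GEOM)
        assert np.allclose(curve(2.0), (2.0, 0.0), atol=1e-9)


class TestRasteriseUrethra:
    def test_radius_bound_and_expected_disc(self):
        geom = zl.VolumeGeometry(spacing_mm=(0.5, 0.5, 3.0), shape=(3, 40, 40))
        curve = zl.QuadraticCurve((0, 0, 10.0), (0, 0, 10.0))  # on a voxel centre
        prostate = np.ones(geom.shape, bool)
        mask = zl.rasterise_urethra(curve, prostate, geom, zl.UrethraGeometrySpec(6.0))
        xg, yg = geom.inplane_coords()
        for i in range(geom.shape[0]):
            d = np.sqrt((xg[mask[i]] - 10.0) ** 2 + (yg[mask[i]] - 10.0) ** 2)
            assert d.max() <= 3.0 + 1e-12
            # every in-range voxel centre is included, none missing
            assert mask[i].sum() == int(((xg - 10) ** 2 + (yg - 10) ** 2 <= 9.0).sum())

    def test_no_urethra_outside_prostate_slices(self, geom_aniso):
        prostate = np.zeros(geom_aniso.shape, bool)
        prostate[2:5, 10:20, 10:20] = True
        curve = zl.QuadraticCurve((0, 0, 7.0), (0, 0, 7.0))
        mask = zl.rasterise_urethra(curve, prostate, geom_aniso)
        assert not mask[[0, 1, 5, 6, 7]].any()
        assert (mask & ~prostate).sum() == 0

    def test_coarse_grid_keeps_containing_voxel(self):
        geom = zl.VolumeGeometry(spacing_mm=(4.0, 4.0, 3.0), shape=(2, 8, 8))
        curve = zl.QuadraticCurve((0, 0, 13.0), (0, 0, 9.0))  # between voxel centres
        mask = zl.rasterise_urethra(curve, np.ones(geom.shape, bool), geom)
        assert mask.any(axis=(1, 2)).all()  # at least one voxel per slice


class TestResolveZones:
    def _prob(self, geom, labels):
        return zl.one_hot(zl.LabelVolume(geom, labels))

    def test_unassigned_voxel_adopts_adjacent_zone(self, geom_iso):
        labels = np.zeros(geom_iso.shape, np.int16)
        labels[3, 3, 3] = 4  # TZ
        prob = self._prob(geom_iso, labels)
        prostate = np.zeros(geom_iso.shape, bool)
        prostate[3, 3, 3] = prostate[3, 3, 4] = True  # one unassigned neighbour
        out = zl.resolve_zones(prob, prostate, np.zeros(geom_iso.shape, bool))
        assert out.data[3, 3, 4] == 4

    def test_equidistant_tie_goes_to_lowest_code(self, geom_iso):
        labels = np.zeros(geom_iso.shape, np.int16)
        labels[3, 3, 2] = 4  # TZ at x=2
        labels[3, 3, 6] = 2  # PZ at x=6
        prob = self._prob(geom_iso, labels)
        prostate = np.zeros(geom_iso.shape, bool)
        prostate[3, 3, 2:7] = True
        out = zl.resolve_zones(prob, prostate, np.zeros(geom_iso.shape, bool))
        assert out.data[3, 3, 4] == 2  # exactly 2 mm from both; PZ (code 2) wins

    def test_identity_when_zones_already_clean(self, small_phantom):
        truth, _ = small_phantom
        prob = zl.one_hot(truth)
        prostate = truth.foreground()
        urethra = truth.mask(1)
        out = zl.resolve_zones(prob, prostate, urethra)
        assert np.array_equal(out.data, truth.data)

    def test_bruteforce_and_edt_routes_agree(self):
        rng = np.random.default_rng(7)
        geom = zl.VolumeGeometry(spacing_mm=(0.7, 0.9, 2.1), shape=(6, 12, 12))
        for _ in range(10):
            labels = np.zeros(geom.shape, np.int16)
            for code in (2, 3, 4, 5):
                i, j, k = (rng.integers(0, s) for s in geom.shape)
                labels[i, j, k] = code
            prostate = np.ones(geom.shape, bool)
            zone_masks = {c: labels == c for c in (2, 3, 4, 5) if (labels == c).any()}
            unassigned = prostate & (labels == 0)
            idx = np.argwhere(unassigned)
            bf = _nearest_zone_bruteforce(idx, {c: np.argwhere(m) for c, m in zone_masks.items()}, geom)
            edt = _nearest_zone_edt(unassigned, zone_masks, geom)
            assert np.array_equal(bf, edt)


class TestPostprocessCase:
    def test_straight_urethra_one_hot_identity(self):
        params = zl.PhantomParams(
            urethra_rel_coeff_x=(0, 0, 0), urethra_rel_coeff_y=(0, 0, 0),
            blur_sigma_mm=0.0, noise_rate=0.0,
        )
        truth, probs = zl.generate_phantom(params)
        out = zl.postprocess_case(probs)
        assert np.array_equal(out.data, truth.data)

    def test_all_background_passthrough(self, geom_iso):
        data = np.zeros((6,) + geom_iso.shape)
        data[0] = 1.0
        prob = zl.ProbabilityVolume(geom_iso, data)
        with pytest.warns(EmptyProstateWarning):
            out = zl.postprocess_case(prob)
        assert not out.data.any()

    def test_interior_holes_filled_by_nearest_zone(self, small_phantom):
        truth, _ = small_phantom
        data = truth.data.copy()
        interior = ndimage.binary_erosion(truth.foreground(), iterations=2)
        holes = np.zeros_like(interior)
        pts = np.argwhere(interior & (data > 1))[::50]
        holes[tuple(pts.T)] = True
        data[holes] = 0  # punch argmax-background holes inside the gland
        prob = zl.one_hot(zl.LabelVolume(truth.geometry, data))
        res = zl.postprocess_case(prob, full_output=True)
        out = res.labels
        assert not (out.data[res.prostate_mask] == 0).any()
        # nearest-zone oracle: each hole voxel matches a brute-force scan over
        # the retained (largest-component) zone voxels
        urethra = res.urethra_mask
        retained = {}
        for c in (2, 3, 4, 5):
            zmask = (data == c) & res.prostate_mask & ~urethra
            if not zmask.any():
                continue
            lab, n = ndimage.label(zmask, structure=np.ones((3, 3, 3)))
            sizes = ndimage.sum_labels(zmask, lab, range(1, n + 1))
            retained[c] = np.argwhere(lab == 1 + int(np.argmax(sizes)))
        idx = np.argwhere(holes & ~urethra)
        bf = _nearest_zone_bruteforce(idx, retained, truth.geometry)
        assert np.array_equal(out.data[tuple(idx.T)], bf)

    def test_partition_invariant(self, small_phantom):
        _, probs = small_phantom
        res = zl.postprocess_case(probs, full_output=True)
        labels = res.labels.data
        assert np.array_equal(labels != 0, res.prostate_mask)
        assert np.array_equal(labels == 1, res.urethra_mask)

    def test_determinism(self, small_phantom):
        _, probs = small_phantom
        a = zl.postprocess_case(probs)
        b = zl.postprocess_case(probs)
        assert np.array_equal(a.data, b.data)
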