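import numpy as np
import pytest

from petlymph import (
    PetVolume,
    ReferenceRegions,
    detect_candidates,
    organ_involvement,
    quantify_patient,
    segment_41pct,
    segment_lesions,
)
from petlymph.lesions import Lesion, LesionSet


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return PetVolume.from_spacing(np.asarray(data, dtype=float), spacing)


class TestDetectCandidates:
    def test_two_disjoint_spheres_found(self, two_sphere_phantom):
        vol, _ = two_sphere_phantom
        comps = detect_candidates(vol, seed_threshold_suv=2.5)
        assert len(comps) == 2

    def test_ordered_by_descending_suvmax(self, two_sphere_phantom):
        vol, _ = two_sphere_phantom
        comps = detect_candidates(vol, seed_threshold_suv=2.5)
        maxima = [vol.data[tuple(c.T)].max() for c in comps]
        assert maxima == sorted(maxima, reverse=True)
        assert maxima[0] == pytest.approx(8.0)

    def test_uniform_background_yields_nothing(self):
        vol = _vol(np.full((10, 10, 10), 0.5))
        assert detect_candidates(vol, seed_threshold_suv=2.5) == []

    def test_corner_touching_blobs_merge_under_26_connectivity(self):
        data = np.zeros((6, 6, 6))
        data[1, 1, 1] = data[1, 1, 2] = 5.0  # blob A
        data[2, 2, 3] = data[2, 2, 4] = 5.0  # blob B, corner-adjacent to A
        vol = _vol(data)
        assert len(detect_candidates(vol, 2.5, connectivity=26, min_voxels=1)) == 1
        assert len(detect_candidates(vol, 2.5, connectivity=6, min_voxels=1)) == 2

    def test_min_voxels_discards_specks(self):
        data = np.zeros((8, 8, 8))
        data[1, 1, 1] = 5.0
        data[5, 5, 5] = data[5, 5, 6] = 5.0
        vol = _vol(data)
        assert len(detect_candidates(vol, 2.5, min_voxels=2)) == 1
        assert len(detect_candidates(vol, 2.5, min_voxels=1)) == 2

    def test_monotone_in_seed_threshold(self, two_sphere_phantom):
        vol, _ = two_sphere_phantom
        counts = [len(detect_candidates(vol, thr, min_voxels=1)) for thr in (1.0, 3.0, 6.5, 9.0)]
        assert counts == sorted(counts, reverse=True)


class TestSegment41pct:
    def test_uniform_sphere_recovered_within_5pct(self, two_sphere_phantom):
        vol, truth = two_sphere_phantom
        lesions = segment_lesions(vol, min_voxels=1)
        assert len(lesions) == 2
        got = sorted(l.volume_cm3 * 1000 for l in lesions)
        want = sorted(t.volume_mm3 for t in truth)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=0.05)

    def test_centroid_matches_sphere_center(self, two_sphere_phantom):
        vol, truth = two_sphere_phantom
        lesions = segment_lesions(vol, min_voxels=1)
        centers = sorted(map(tuple, (t.center_mm for t in truth)))
        got = sorted(map(tuple, (l.centroid_mm for l in lesions)))
        for g, w in zip(got, centers):
            assert np.linalg.norm(np.array(g) - np.array(w)) < 2.0  # within one voxel

    def test_isocontour_threshold_arithmetic(self):
        # component SUVs {8, 6, 4, 3}: 41% of 8 = 3.28 keeps {8, 6, 4}
        data = np.zeros((5, 8, 5))
        data[2, 1:5, 2] = [8.0, 6.0, 4.0, 3.0]
        vol = _vol(data)
        comp = np.argwhere(data >= 2.5)
        lesion = segment_41pct(comp, vol)
        assert len(lesion.voxel_indices) == 3
        assert lesion.suv_mean == pytest.approx(6.0)
        assert lesion.suv_max == pytest.approx(8.0)

    def test_relative_threshold_scale_invariance(self, two_sphere_phantom):
        vol, _ = two_sphere_phantom
        scaled = PetVolume(data=vol.data * 3.7, affine=vol.affine)
        a = segment_lesions(vol, min_voxels=1)
        b = segment_lesions(scaled, seed_threshold_suv=2.5 * 3.7, min_voxels=1)
        assert len(a) == len(b)
        for la, lb in zip(a, b):
            np.testing.assert_array_equal(la.voxel_indices, lb.voxel_indices)

    def test_single_voxel_component_degenerates_gracefully(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 7.0
        lesion = segment_41pct(np.array([[2, 2, 2]]), _vol(data))
        assert len(lesion.voxel_indices) == 1
        assert lesion.suv_mean == pytest.approx(7.0)

    def test_grows_beyond_seed_component(self):
        # seed threshold 2.5 catches only the 3.0 core; 41% of 3 = 1.23
        # pulls in the 1.5 rim around it
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 3.0
        data[3, 3, 2] = data[3, 3, 4] = 1.5
        comps = detect_candidates(_vol(data), 2.5, min_voxels=1)
        lesion = segment_41pct(comps[0], _vol(data))
        assert len(lesion.voxel_indices) == 3


class TestQuantifyPatient:
    @staticmethod
    def _lesion(volume_cm3, suv_mean, suv_max=None):
        return Lesion(
            voxel_indices=np.array([[0, 0, 0]]),
            suv_max=suv_max or suv_mean,
            suv_mean=suv_mean,
            volume_cm3=volume_cm3,
            centroid_mm=np.zeros(3),
        )

    def test_tlg_is_sum_of_volume_times_mean(self):
        ls = LesionSet([self._lesion(10, 5.0), self._lesion(20, 2.5)])
        assert ls.total_tlg == pytest.approx(10 * 5 + 20 * 2.5)
        assert ls.total_mtv_cm3 == pytest.approx(30)

    def test_mtv_additivity_invariant_to_order(self):
        a, b, c = self._lesion(1.5, 3.0), self._lesion(7.25, 4.0), self._lesion(0.5, 9.0)
        assert LesionSet([a, b, c]).total_mtv_cm3 == pytest.approx(LesionSet([c, a, b]).total_mtv_cm3)

    def test_empty_lesion_set_rejected(self, two_sphere_phantom):
        from petlymph import PatientMeta, suv_maps

        vol, _ = two_sphere_phantom
        activity = PetVolume(data=vol.data, affine=vol.affine, units="kBq/mL")
        maps = suv_maps(activity, PatientMeta("male", 74, 176, 185))
        with pytest.raises(ValueError, match="empty lesion set"):
            quantify_patient(maps, LesionSet([]))


class TestOrganInvolvement:
    @pytest.mark.parametrize(
        "spleen,liver,focal,expected",
        [
            (3.2, 2.0, False, True),  # diffuse > 1.5x liver
            (2.9, 2.0, False, False),  # below the 1.5x bar
            (1.0, 2.0, True, True),  # focal uptake dominates
            (3.0, 2.0, False, False),  # exactly 1.5x is not above it
        ],
    )
    def test_spleen_rule(self, spleen, liver, focal, expected):
        refs = ReferenceRegions(liver_suv_mean=liver, spleen_suv_mean=spleen, spleen_focal_flag=focal)
        assert organ_involvement(refs)["spleen_involved"] is expected

    def test_marrow_requires_focal_uptake(self):
        refs = ReferenceRegions(liver_suv_mean=2.0, marrow_focal_flag=True)
        assert organ_involvement(refs)["marrow_involved"] is True
        refs = ReferenceRegions(liver_suv_mean=2.0, marrow_focal_flag=False)
        assert organ_involvement(refs)["marrow_involved"] is False

    def test_missing_liver_reference_raises(self):
        with pytest.raises(ValueError, match="liver"):
            organ_involvement(ReferenceRegions(liver_suv_mean=0.0))
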