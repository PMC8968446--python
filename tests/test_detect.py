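"""Subtraction, candidate extraction and the center-of-gravity rule."""

import numpy as np
import pytest

from _oracles import threshold_components_oracle
from mscad.detect import (
    CandidateStatus,
    DifferenceMap,
    LesionCandidate,
    classify_candidate,
    extract_candidates,
    quantify,
    subtract,
)
from mscad.errors import GeometryError
from mscad.io_formats import VolumeImage
from mscad.preprocess import BrainMask


def _volume(arr, spacing=(1, 1, 1)):
    return VolumeImage(
        voxels=np.asarray(arr, dtype=float),
        spacing=np.asarray(spacing, dtype=float),
        origin=np.zeros(3),
        direction=np.eye(3),
    )


def _box_mask(shape, margin=1, spacing=(1, 1, 1)):
    m = np.zeros(shape, dtype=bool)
    m[margin:-margin, margin:-margin, margin:-margin] = True
    return BrainMask(mask=m, spacing=np.asarray(spacing, dtype=float))


def _diff_from_delta(delta, mask):
    delta = np.where(mask.mask, delta, 0.0)
    vol = _volume(delta, mask.spacing)
    return DifferenceMap(delta=delta, mask=mask, geometry=vol.geometry)


class TestSubtract:
    def test_identical_inputs_give_zero_map(self):
        mask = _box_mask((10, 10, 10))
        v = _volume(np.random.default_rng(0).normal(100, 5, (10, 10, 10)))
        d = subtract(v, v, mask)
        assert np.all(d.delta == 0)

    def test_inserted_sphere_is_positive_inside_mask_only(self):
        mask = _box_mask((16, 16, 16), margin=2)
        base = np.full((16, 16, 16), 100.0)
        tp2 = base.copy()
        tp2[6:10, 6:10, 6:10] += 40.0
        d = subtract(_volume(tp2), _volume(base), mask)
        assert np.all(d.delta[6:10, 6:10, 6:10] == 40.0)
        outside = ~mask.mask
        assert np.all(d.delta[outside] == 0)

    def test_out_of_mask_change_is_suppressed(self):
        mask = _box_mask((12, 12, 12), margin=3)
        base = np.full((12, 12, 12), 100.0)
        tp2 = base.copy()
        tp2[0, 0, 0] += 500.0  # outside the mask
        d = subtract(_volume(tp2), _volume(base), mask)
        assert d.delta[0, 0, 0] == 0

    def test_grid_mismatch_raises(self):
        mask = _box_mask((10, 10, 10))
        a = _volume(np.zeros((10, 10, 10)))
        b = _volume(np.zeros((10, 10, 10)), spacing=(1, 1, 2))
        with pytest.raises(GeometryError):
            subtract(a, b, mask)


class TestExtractCandidates:
    def test_zero_map_yields_no_candidates(self):
        mask = _box_mask((10, 10, 10))
        d = _diff_from_delta(np.zeros((10, 10, 10)), mask)
        assert extract_candidates(d) == []

    def test_single_blob_with_known_volume(self):
        """A 12-voxel suprathreshold blob at 1 mm^3 spacing -> one 12 mm^3 candidate."""
        rng = np.random.default_rng(3)
        mask = _box_mask((20, 20, 20))
        delta = rng.normal(0, 1, (20, 20, 20))
        delta[8:11, 8:12, 9] = 50.0  # 3*4*1 = 12 voxels
        d = _diff_from_delta(delta, mask)
        cands = extract_candidates(d, k=3.0, min_volume=3.0)
        assert len(cands) == 1
        assert cands[0].volume_mm3 == pytest.approx(12.0)
        assert cands[0].n_voxels == 12
        assert quantify(cands[0]) == pytest.approx(12.0)

    def test_min_volume_filters_small_components(self):
        mask = _box_mask((20, 20, 20))
        delta = np.random.default_rng(4).normal(0, 1, (20, 20, 20))
        delta[5:8, 5:8, 5:8] = 60.0  # 27 voxels, survives
        delta[15, 15, 15:17] = 60.0  # 2 voxels, filtered at min_volume=3
        d = _diff_from_delta(delta, mask)
        cands = extract_candidates(d, k=3.0, min_volume=3.0)
        assert len(cands) == 1
        assert cands[0].n_voxels == 27

    def test_cog_is_rounded_centroid_inside_bounding_box(self):
        mask = _box_mask((16, 16, 16))
        delta = np.zeros((16, 16, 16))
        delta[4:9, 6, 6] = 100.0
        d = _diff_from_delta(delta, mask)
        (cand,) = extract_candidates(d, k=3.0, min_volume=1.0)
        assert cand.cog == (6, 6, 6)

    def test_matches_brute_force_oracle_on_random_grids(self, rng):
        """Candidate voxel sets equal flood-fill + z-threshold oracle, exactly."""
        for _ in range(10):
            shape = tuple(int(rng.integers(8, 20)) for _ in range(3))
            delta = rng.normal(0, 1, shape)
            # plant a few bright boxes so components exist
            for _b in range(int(rng.integers(1, 4))):
                c = [int(rng.integers(2, s - 4)) for s in shape]
                w = [int(rng.integers(1, 4)) for _ in range(3)]
                delta[c[0]:c[0]+w[0], c[1]:c[1]+w[1], c[2]:c[2]+w[2]] += rng.uniform(5, 20)
            mask = _box_mask(shape)
            k = float(rng.uniform(1.5, 3.0))
            min_vol = float(rng.integers(1, 5))
            d = _diff_from_delta(delta, mask)
            got = {
                frozenset(map(tuple, c.voxel_indices))
                for c in extract_candidates(d, k=k, min_volume=min_vol)
            }
            want = threshold_components_oracle(d.delta, mask.mask, k, min_vol, 1.0)
            assert got == want

    def test_candidate_sets_are_disjoint(self, rng):
        mask = _box_mask((24, 24, 24))
        delta = rng.normal(0, 1, (24, 24, 24))
        delta[4:7, 4:7, 4:7] += 30
        delta[15:18, 15:18, 15:18] += 30
        d = _diff_from_delta(delta, mask)
        cands = extract_candidates(d, k=3.0, min_volume=1.0)
        assert len(cands) >= 2
        seen = set()
        for c in cands:
            s = set(map(tuple, c.voxel_indices))
            assert not (seen & s)
            seen |= s


class TestClassifyCandidate:
    def _candidate_at(self, cog, shape=(8, 8, 8)):
        vol = _volume(np.zeros(shape))
        return LesionCandidate(
            voxel_indices=np.array([cog]),
            cog=cog,
            volume_mm3=1.0,
            peak_delta=1.0,
            geometry=vol.geometry,
        )

    @pytest.mark.parametrize(
        "i1,i2,expected",
        [
            (250.0, 180.0, CandidateStatus.FALSE_POSITIVE),
            (100.0, 240.0, CandidateStatus.NEW_LESION),
            (150.0, 150.0, CandidateStatus.NEW_LESION),  # tie keeps sensitivity
        ],
    )
    def test_cog_intensity_rule(self, i1, i2, expected):
        """Brighter at Timepoint-1 -> artifact; otherwise a new lesion."""
        tp1 = _volume(np.zeros((8, 8, 8)))
        tp2 = _volume(np.zeros((8, 8, 8)))
        tp1.voxels[4, 4, 4] = i1
        tp2.voxels[4, 4, 4] = i2
        c = classify_candidate(self._candidate_at((4, 4, 4)), tp1, tp2)
        assert c.status is expected

    def test_out_of_bounds_cog_raises(self):
        tp = _volume(np.zeros((4, 4, 4)))
        big = _volume(np.zeros((8, 8, 8)))
        cand = self._candidate_at((6, 6, 6))
        with pytest.raises(GeometryError):
            classify_candidate(cand, tp, big)

    def test_depends_only_on_cog_intensities(self, rng):
        tp1 = _volume(rng.normal(100, 10, (8, 8, 8)))
        tp2 = _volume(rng.normal(100, 10, (8, 8, 8)))
        c = self._candidate_at((3, 5, 2))
        first = classify_candidate(c, tp1, tp2).status
        tp1b = tp1.with_voxels(rng.normal(100, 10, (8, 8, 8)))
        tp1b.voxels[3, 5, 2] = tp1.voxels[3, 5, 2]
        tp2b = tp2.with_voxels(rng.normal(100, 10, (8, 8, 8)))
        tp2b.voxels[3, 5, 2] = tp2.voxels[3, 5, 2]
        assert classify_candidate(c, tp1b, tp2b).status is first


class TestQuantify:
    @pytest.mark.parametrize(
        "n,spacing,expected",
        [(10, (1, 1, 1), 10.0), (8, (1, 1, 3), 24.0), (1, (0.5, 0.5, 0.5), 0.125)],
    )
    def test_volume_is_count_times_voxel_volume(self, n, spacing, expected):
        vol = _volume(np.zeros((12, 12, 12)), spacing)
        idx = np.array([[0, 0, i] for i in range(n)])
        c = LesionCandidate(
            voxel_indices=idx,
            cog=tuple(idx[n // 2]),
            volume_mm3=expected,
            peak_delta=1.0,
            geometry=vol.geometry,
        )
        assert quantify(c, spacing) == pytest.approx(expected)

    def test_empty_voxel_set_rejected(self):
        vol = _volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            LesionCandidate(
                voxel_indices=np.empty((0, 3), dtype=int),
                cog=(0, 0, 0),
                volume_mm3=0.0,
                peak_delta=0.0,
                geometry=vol.geometry,
            )
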