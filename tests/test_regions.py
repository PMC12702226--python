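"""High-CBF segmentation, overlap metrics, and weekly dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asldyn.quantify import CbfMap, QuantParams
from asldyn.regions import (
    DynamicsSeries,
    RegionSet,
    assign_week,
    cohort_dynamics_summary,
    cohort_threshold,
    gm_cbf_stats,
    overlap_metrics,
    relative_change_series,
    segment_high_cbf,
)
from asldyn.phantom import ScheduleSpec
from asldyn.volume import Volume

from conftest import bfs_components


def _cbf_map(data, voxel=(4.0, 4.0, 8.0)):
    vol = Volume(np.asarray(data, dtype=float), voxel)
    return CbfMap(
        values=vol,
        params_used=QuantParams(alpha=0.59),
        mask_valid=vol.with_data(np.ones(vol.shape, dtype=bool)),
    )


def _regions(ctv, gtv=None, voxel=(4.0, 4.0, 8.0)):
    ctv = np.asarray(ctv, dtype=bool)
    gtv = np.zeros_like(ctv) if gtv is None else np.asarray(gtv, dtype=bool)
    return RegionSet(
        gtv=Volume(gtv, voxel),
        ctv=Volume(ctv, voxel),
        contralateral_gm=Volume(np.zeros_like(ctv), voxel),
    )


class TestGmStats:
    def test_uniform_field(self):
        cbf = _cbf_map(np.full((4, 4, 4), 50.0))
        mask = cbf.values.with_data(np.ones((4, 4, 4), dtype=bool))
        assert gm_cbf_stats(cbf, mask) == (50.0, 50.0)

    def test_q95_matches_sort_based_oracle(self):
        vals = np.arange(1.0, 101.0).reshape(5, 5, 4)
        cbf = _cbf_map(vals)
        mask = cbf.values.with_data(np.ones(vals.shape, dtype=bool))
        _, q95 = gm_cbf_stats(cbf, mask)
        # linear interpolation between order statistics, computed by hand:
        # position 0.95*(n-1) = 94.05 in the sorted 1..100 -> 95.05
        srt = np.sort(vals.ravel())
        pos = 0.95 * (srt.size - 1)
        lo, frac = int(pos), pos - int(pos)
        assert q95 == pytest.approx(srt[lo] + frac * (srt[lo + 1] - srt[lo]))
        assert q95 == pytest.approx(95.05)

    def test_translation_equivariance(self, rng):
        data = rng.uniform(10, 90, (6, 6, 4))
        mask_arr = rng.uniform(size=data.shape) > 0.4
        mask = Volume(mask_arr, (4.0, 4.0, 8.0))
        m1, q1 = gm_cbf_stats(_cbf_map(data), mask)
        m2, q2 = gm_cbf_stats(_cbf_map(data + 7.5), mask)
        assert m2 == pytest.approx(m1 + 7.5)
        assert q2 == pytest.approx(q1 + 7.5)

    def test_empty_mask_rejected(self):
        cbf = _cbf_map(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            gm_cbf_stats(cbf, cbf.values.with_data(np.zeros((3, 3, 3), dtype=bool)))


class TestCohortThreshold:
    def test_median_of_three(self):
        assert cohort_threshold([70.0, 79.0, 85.0]) == 79.0

    def test_single_patient(self):
        assert cohort_threshold([81.5]) == 81.5

    def test_permutation_invariance(self, rng):
        vals = list(rng.uniform(60, 100, 9))
        shuffled = list(vals)
        rng.shuffle(shuffled)
        assert cohort_threshold(vals) == cohort_threshold(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_threshold([])


class TestSegmentHighCbf:
    def test_all_subthreshold_is_empty_not_included(self):
        cbf = _cbf_map(np.full((5, 5, 5), 40.0))
        region = segment_high_cbf(cbf, _regions(np.ones((5, 5, 5))), 79.0)
        assert region.volume_cm3 == 0.0
        assert not region.included
        assert not region.mask.data.any()

    def test_largest_of_two_blobs_kept(self):
        data = np.zeros((6, 6, 6))
        data[0, 0, 0:5] = 100.0  # 5-voxel blob
        data[4, 4, 0:3] = 100.0  # 3-voxel blob
        cbf = _cbf_map(data)
        region = segment_high_cbf(cbf, _regions(np.ones((6, 6, 6))), 79.0)
        assert int(region.mask.data.sum()) == 5
        assert region.mask.data[0, 0, 2]
        comps = bfs_components(data > 79.0)
        assert int(region.mask.data.sum()) == max(len(c) for c in comps)

    def test_volume_and_inclusion_rule(self):
        data = np.zeros((6, 6, 6))
        data[2, 2, 0:10] = 0.0
        data[1:3, 1:3, 1:4] = 90.0  # a 2x2x3 = 12-voxel block... adjust to 10
        data[2, 2, 1] = 0.0
        data[2, 2, 2] = 0.0
        cbf = _cbf_map(data)  # 10 voxels at 4x4x8 mm^3 = 0.128 cm^3 each
        region = segment_high_cbf(cbf, _regions(np.ones((6, 6, 6))), 79.0)
        assert int(region.mask.data.sum()) == 10
        assert region.volume_cm3 == pytest.approx(1.28)
        assert region.included  # strictly above 1 cm^3

    def test_strict_threshold(self):
        data = np.full((4, 4, 4), 79.0)
        data[0, 0, 0] = 79.0001
        region = segment_high_cbf(_cbf_map(data), _regions(np.ones((4, 4, 4))), 79.0)
        assert int(region.mask.data.sum()) == 1

    def test_ctv_restriction_applied_before_labelling(self):
        data = np.zeros((6, 6, 1))
        data[0:6, 0, 0] = 100.0  # line crossing the CTV boundary
        ctv = np.zeros((6, 6, 1), dtype=bool)
        ctv[0:3] = True
        region = segment_high_cbf(_cbf_map(data), _regions(ctv), 79.0)
        assert int(region.mask.data.sum()) == 3

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_brute_force_oracle_on_random_grids(self, connectivity):
        rng = np.random.default_rng(77)
        for _ in range(60):
            data = rng.uniform(0, 100, (8, 8, 8))
            ctv = rng.uniform(size=(8, 8, 8)) > 0.3
            region = segment_high_cbf(
                _cbf_map(data), _regions(ctv), 60.0, connectivity=connectivity
            )
            comps = bfs_components((data > 60.0) & ctv, connectivity=connectivity)
            expected = max((len(c) for c in comps), default=0)
            assert int(region.mask.data.sum()) == expected

    def test_raising_threshold_never_increases_volume(self, rng):
        data = rng.uniform(0, 120, (8, 8, 8))
        regions = _regions(np.ones((8, 8, 8)))
        vols = [
            segment_high_cbf(_cbf_map(data), regions, thr).volume_cm3
            for thr in (40.0, 60.0, 80.0, 100.0)
        ]
        assert all(b <= a for a, b in zip(vols, vols[1:]))


class TestOverlapMetrics:
    def _region_from_mask(self, mask, voxel=(4.0, 4.0, 8.0)):
        mask = np.asarray(mask, dtype=bool)
        vol = Volume(mask, voxel)
        from asldyn.regions import HighCbfRegion

        return HighCbfRegion(
            mask=vol,
            volume_cm3=vol.count_to_cm3(int(mask.sum())),
            threshold_used=79.0,
            included=True,
        )

    def test_subset_of_gtv_has_zero_outside(self):
        gtv = np.zeros((4, 4, 4), dtype=bool)
        gtv[0:3] = True
        h = np.zeros_like(gtv)
        h[0, 0, 0] = True
        ov = overlap_metrics(self._region_from_mask(h), Volume(gtv))
        assert ov.pct_outside_gtv == 0.0

    def test_disjoint_from_gtv(self):
        gtv = np.zeros((4, 4, 4), dtype=bool)
        gtv[0] = True
        h = np.zeros_like(gtv)
        h[3] = True
        ov = overlap_metrics(self._region_from_mask(h), Volume(gtv))
        assert ov.pct_outside_gtv == 100.0
        assert ov.pct_gtv_occupied == 0.0

    def test_worked_counts_10_40_4(self):
        # |hCBF|=10, |GTV|=40, intersection=4 -> (10%, 60%)
        gtv = np.zeros((5, 5, 4), dtype=bool)
        gtv.ravel()[:40] = True
        h = np.zeros_like(gtv)
        h.ravel()[36:46] = True  # 4 voxels inside the GTV, 6 outside
        assert int((h & gtv).sum()) == 4 and int(h.sum()) == 10
        ov = overlap_metrics(self._region_from_mask(h), Volume(gtv))
        assert ov.pct_gtv_occupied == pytest.approx(10.0)
        assert ov.pct_outside_gtv == pytest.approx(60.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_overlap_identity_on_random_masks(self, seed):
        r = np.random.default_rng(seed)
        h = r.uniform(size=(5, 5, 5)) > 0.6
        g = r.uniform(size=(5, 5, 5)) > 0.5
        if not h.any() or not g.any():
            return
        ov = overlap_metrics(self._region_from_mask(h), Volume(g))
        inside_pct = 100.0 * (h & g).sum() / h.sum()
        assert ov.pct_outside_gtv + inside_pct == pytest.approx(100.0, abs=1e-12)

    def test_empty_gtv_rejected(self):
        h = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="GTV"):
            overlap_metrics(self._region_from_mask(h), Volume(np.zeros((3, 3, 3), dtype=bool)))

    def test_empty_hcbf_flagged(self):
        g = np.ones((3, 3, 3), dtype=bool)
        ov = overlap_metrics(self._region_from_mask(np.zeros((3, 3, 3), dtype=bool)), Volume(g))
        assert ov.empty_hcbf and ov.pct_outside_gtv is None


class TestWeeksAndDynamics:
    @pytest.mark.parametrize(
        "day,week", [(1, 1), (7, 1), (8, 2), (14, 2), (15, 3), (29, 5)]
    )
    def test_assign_week(self, day, week):
        assert assign_week(day) == week

    def test_day_below_one_rejected(self):
        with pytest.raises(ValueError):
            assign_week(0)

    def test_relative_change_on_printed_volumes(self):
        # weekly volumes 41, 26, 11 cm^3 -> 0%, -36.6%, -73.2%
        ds = relative_change_series({1: 41.0, 2: 26.0, 3: 11.0}, subject="ex")
        assert ds.pct_change[1] == 0.0
        assert ds.pct_change[2] == pytest.approx(-36.6, abs=0.05)
        assert ds.pct_change[3] == pytest.approx(-73.2, abs=0.05)

    def test_constant_volumes_give_zero_change(self):
        ds = relative_change_series({1: 10.0, 2: 10.0, 3: 10.0})
        assert all(v == 0.0 for v in ds.pct_change.values())

    def test_vanishing_region_is_minus_100(self):
        ds = relative_change_series({1: 5.0, 4: 0.0})
        assert ds.pct_change[4] == -100.0

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="week 1"):
            relative_change_series({2: 10.0})
        with pytest.raises(ValueError, match="positive"):
            relative_change_series({1: 0.0, 2: 5.0})

    def test_cohort_summary_single_patient(self):
        ds = relative_change_series({1: 10.0, 2: 7.0, 3: 4.0}, subject="A")
        sched = ScheduleSpec(subject="A", scan_days=(2, 9, 16))
        out = cohort_dynamics_summary([ds], [sched])
        assert out.median_pct_change == ds.pct_change
        assert out.included_subjects == ("A",)

    def test_late_baseline_excluded_and_logged(self):
        good = relative_change_series({1: 10.0, 2: 7.0}, subject="A")
        late = DynamicsSeries(subject="B", volumes_by_week={1: 5.0}, pct_change={1: 0.0})
        scheds = [
            ScheduleSpec(subject="A", scan_days=(2, 9)),
            ScheduleSpec(subject="B", scan_days=(9, 16)),  # week-2 baseline
        ]
        out = cohort_dynamics_summary([good, late], scheds)
        assert "B" in out.excluded and "week" in out.excluded["B"]
        assert out.included_subjects == ("A",)

    def test_single_scan_excluded(self):
        ds = DynamicsSeries(subject="C", volumes_by_week={1: 5.0}, pct_change={1: 0.0})
        sched = ScheduleSpec(subject="C", scan_days=(3,))
        with pytest.raises(ValueError, match="no eligible"):
            cohort_dynamics_summary([ds], [sched])
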