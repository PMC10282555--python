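"""Weight maps, microstructure maps, tract means, profiles, scan-rescan."""

import numpy as np
import pandas as pd
import pytest

from unravel.core import FixelField
from unravel.geometry import Subsegment, Tract, VoxelGrid, split_tract
from unravel.maps import (
    MicrostructureMap,
    WeightMaps,
    compute_microstructure_map,
    compute_weight_maps,
    scan_rescan_stats,
    segment_level_map,
    streamline_profile,
    tract_mean,
)

X = np.array([1.0, 0.0, 0.0])


def tiny_field(metric=(0.8, 0.2), fractions=(0.5, 0.5), angles=(0.0, 90.0)):
    """One-voxel field with two in-plane fixels."""
    ori = np.zeros((1, 1, 1, 2, 3))
    for k, a in enumerate(angles):
        r = np.radians(a)
        ori[0, 0, 0, k] = [np.cos(r), np.sin(r), 0.0]
    frac = np.zeros((1, 1, 1, 2))
    frac[0, 0, 0] = fractions
    m = np.zeros((1, 1, 1, 2))
    m[0, 0, 0] = metric
    return FixelField(np.eye(4), ori, frac, {"M": m})


def sub(voxel=(0, 0, 0), direction=X, length=1.0, sid=0, gid=0):
    return Subsegment(voxel=voxel, direction=np.asarray(direction, float),
                      length=length, streamline_id=sid, segment_id=gid)


class TestWeightMaps:
    def test_single_subsegment_cfo(self):
        ff = tiny_field()
        wm = compute_weight_maps([sub()], ff, "cfo")
        np.testing.assert_allclose(wm.fixel_weights[0, 0, 0], [1.0, 0.0])
        assert wm.total_length[0, 0, 0] == pytest.approx(1.0)

    def test_two_halves_vol(self):
        ff = tiny_field(fractions=(0.6, 0.4) / np.array(1.0))
        wm = compute_weight_maps([sub(length=0.5), sub(length=0.5, gid=1)], ff, "vol")
        np.testing.assert_allclose(wm.fixel_weights[0, 0, 0], [0.6, 0.4], atol=1e-12)
        assert wm.total_length[0, 0, 0] == pytest.approx(1.0)

    def test_empty_subsegments_zero_maps(self):
        ff = tiny_field()
        wm = compute_weight_maps([], ff, "ang")
        assert not wm.fixel_weights.any() and not wm.total_length.any()

    def test_fixel_free_voxel_accumulates_only_total(self):
        ori = np.zeros((1, 1, 1, 2, 3))
        frac = np.zeros((1, 1, 1, 2))
        ff = FixelField(np.eye(4), ori, frac, {"M": np.zeros((1, 1, 1, 2))})
        wm = compute_weight_maps([sub()], ff, "ang")
        assert wm.total_length[0, 0, 0] == pytest.approx(1.0)
        assert not wm.fixel_weights.any()


class TestMicrostructureMap:
    def test_hand_evaluated_weighted_average(self):
        ff = tiny_field(metric=(0.9, 0.5))
        wm = WeightMaps(np.array([3.0, 1.0]).reshape(1, 1, 1, 2),
                        np.full((1, 1, 1), 4.0), "ang")
        mm = compute_microstructure_map(wm, ff, "M")
        assert mm.values[0, 0, 0] == pytest.approx(0.8)

    def test_degenerate_weighting(self):
        ff = tiny_field(metric=(0.8, 0.2))
        wm = WeightMaps(np.array([1.0, 0.0]).reshape(1, 1, 1, 2),
                        np.ones((1, 1, 1)), "cfo")
        assert compute_microstructure_map(wm, ff, "M").values[0, 0, 0] == pytest.approx(0.8)

    def test_zero_weight_voxel_is_nan(self):
        ff = tiny_field()
        wm = WeightMaps(np.zeros((1, 1, 1, 2)), np.zeros((1, 1, 1)), "ang")
        assert np.isnan(compute_microstructure_map(wm, ff, "M").values[0, 0, 0])

    def test_unknown_metric_lists_available(self):
        ff = tiny_field()
        wm = compute_weight_maps([sub()], ff, "ang")
        with pytest.raises(KeyError, match="available.*M"):
            compute_microstructure_map(wm, ff, "nope")


class TestAlgebraicIdentities:
    """Fixel-aggregated and segment-aggregated routes must coincide."""

    @pytest.mark.parametrize("strategy", ["vol", "cfo", "ang"])
    def test_phantom_identities(self, bundle, grid, strategy):
        ff = bundle.fixel_field
        subs = split_tract(bundle.tracts["T1"], grid)
        wm = compute_weight_maps(subs, ff, strategy)
        # per-voxel fixel weights sum to total segment length in fixel voxels
        has_fixels = ff.fixel_count > 0
        np.testing.assert_allclose(
            wm.fixel_weights.sum(axis=-1)[has_fixels],
            wm.total_length[has_fixels],
            atol=1e-6,
        )
        # fixel-aggregated map == direct segment-level map
        m1 = compute_microstructure_map(wm, ff, "FVF").values
        m2 = segment_level_map(subs, ff, strategy, "FVF").values
        d = m1[~np.isnan(m1)] - m2[~np.isnan(m2)]
        assert m1.shape == m2.shape
        np.testing.assert_array_equal(np.isnan(m1), np.isnan(m2))
        assert np.max(np.abs(d)) < 1e-9
        # tsl mean == direct segment-level aggregate
        mm = compute_microstructure_map(wm, ff, "FVF")
        ts = tract_mean(mm, wm, "tsl")
        num = den = 0.0
        from unravel.core import relative_contribution, segment_metric
        for s in subs:
            slots, ori, frac = ff.voxel_fixels(s.voxel)
            if slots.size == 0:
                continue
            rc = relative_contribution(strategy, s.direction, ori, frac)
            num += s.length * segment_metric(rc, ff.metrics["FVF"][s.voxel][slots])
            den += s.length
        assert ts.mean == pytest.approx(num / den, abs=1e-9)

    @pytest.mark.parametrize("strategy", ["vol", "cfo", "ang"])
    def test_total_length_independent_of_strategy(self, bundle, grid, strategy):
        subs = split_tract(bundle.tracts["T2"], grid)
        ref = compute_weight_maps(subs, bundle.fixel_field, "vol").total_length
        got = compute_weight_maps(subs, bundle.fixel_field, strategy).total_length
        np.testing.assert_array_equal(ref, got)


class TestTractMean:
    def _two_voxel_setup(self):
        values = np.array([[0.8], [0.6]]).reshape(2, 1, 1)
        mm = MicrostructureMap(values, "M")
        w = np.array([3.0, 1.0]).reshape(2, 1, 1)
        wm = WeightMaps(w[..., None], w, "ang")
        return mm, wm

    def test_tsl_and_roi_hand_evaluated(self):
        mm, wm = self._two_voxel_setup()
        assert tract_mean(mm, wm, "tsl").mean == pytest.approx(0.75)
        assert tract_mean(mm, wm, "roi").mean == pytest.approx(0.7)

    def test_constant_map_conserved(self):
        values = np.full((2, 1, 1), 0.42)
        mm = MicrostructureMap(values, "M")
        w = np.array([3.0, 1.0]).reshape(2, 1, 1)
        wm = WeightMaps(w[..., None], w, "ang")
        for weighting in ("tsl", "roi"):
            assert tract_mean(mm, wm, weighting).mean == pytest.approx(0.42)

    def test_undefined_voxels_excluded(self):
        values = np.array([0.8, np.nan]).reshape(2, 1, 1)
        mm = MicrostructureMap(values, "M")
        w = np.array([1.0, 5.0]).reshape(2, 1, 1)
        wm = WeightMaps(w[..., None], w, "ang")
        assert tract_mean(mm, wm, "tsl").mean == pytest.approx(0.8)
        assert tract_mean(mm, wm, "tsl").n_voxels == 1

    def test_min_length_threshold(self):
        mm, wm = self._two_voxel_setup()
        ts = tract_mean(mm, wm, "roi", min_length=2.0)
        assert ts.mean == pytest.approx(0.8) and ts.n_voxels == 1

    def test_all_undefined_errors(self):
        mm = MicrostructureMap(np.full((1, 1, 1), np.nan), "M")
        wm = WeightMaps(np.zeros((1, 1, 1, 1)), np.zeros((1, 1, 1)), "ang")
        with pytest.raises(ValueError, match="no defined voxels"):
            tract_mean(mm, wm, "tsl")

    def test_mean_within_map_bounds(self, bundle, grid):
        ff = bundle.fixel_field
        subs = split_tract(bundle.tracts["T3"], grid)
        wm = compute_weight_maps(subs, ff, "ang")
        mm = compute_microstructure_map(wm, ff, "FA")
        lo, hi = np.nanmin(mm.values), np.nanmax(mm.values)
        for weighting in ("tsl", "roi"):
            assert lo - 1e-12 <= tract_mean(mm, wm, weighting).mean <= hi + 1e-12


class TestStreamlineProfile:
    def test_homogeneous_region_constant(self, bundle):
        ff = bundle.fixel_field
        # streamline confined to a single-fixel stretch of T1 (outside crossings)
        sl = np.column_stack([np.linspace(26.0, 34.0, 9),
                              np.full(9, 41.0), np.zeros(9)])
        prof = streamline_profile(sl, ff, "ang", "FVF")
        assert len(prof) > 0
        np.testing.assert_allclose(prof["FVF"], 0.70, atol=1e-12)
        np.testing.assert_allclose(prof["alpha_0"], 1.0, atol=1e-12)
        assert prof["alpha_1"].isna().all()

    def test_single_to_crossing_transition(self, bundle):
        """Alpha goes from a 1-entry to a 2-entry normalized vector."""
        ff = bundle.fixel_field
        sl = bundle.tracts["T1"].streamlines[25]
        prof = streamline_profile(sl, ff, "ang", "FVF")
        k1 = prof[prof["alpha_1"].isna() & prof["alpha_0"].notna()]
        k2 = prof[prof["alpha_1"].notna()]
        assert len(k1) > 0 and len(k2) > 0
        np.testing.assert_allclose(k1["alpha_0"], 1.0, atol=1e-12)
        np.testing.assert_allclose(k2["alpha_0"] + k2["alpha_1"], 1.0, atol=1e-9)

    def test_duplicate_points_ignored(self, bundle):
        ff = bundle.fixel_field
        sl = bundle.tracts["T1"].streamlines[0]
        dup = np.repeat(sl, 2, axis=0)
        p1 = streamline_profile(sl, ff, "cfo", "FA")
        p2 = streamline_profile(dup, ff, "cfo", "FA")
        pd.testing.assert_frame_equal(p1, p2)

    def test_out_of_volume_streamline_empty(self, bundle):
        ff = bundle.fixel_field
        sl = np.array([[500.0, 500.0, 500.0], [510.0, 500.0, 500.0]])
        prof = streamline_profile(sl, ff, "ang", "FA")
        assert prof.empty


class TestScanRescan:
    def test_identity(self):
        ch, m, sd = scan_rescan_stats([0.5, 0.6], [0.5, 0.6])
        np.testing.assert_array_equal(ch, [0.0, 0.0])
        assert m == 0.0

    def test_hand_evaluated_symmetric_change(self):
        ch, m, sd = scan_rescan_stats([1.0], [1.1])
        assert ch[0] == pytest.approx(100 * 0.1 / 1.05, abs=1e-9)
        assert np.isnan(sd)  # undefined for a single pair

    def test_antisymmetry(self):
        a, b = [0.4, 0.5, 0.62], [0.45, 0.48, 0.7]
        ch1, m1, _ = scan_rescan_stats(a, b)
        ch2, m2, _ = scan_rescan_stats(b, a)
        np.testing.assert_allclose(ch1, -ch2, atol=1e-12)
        assert m1 == pytest.approx(-m2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            scan_rescan_stats([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            scan_rescan_stats([1.0, 0.0], [1.0, 1.0])


class TestContaminationOrdering:
    def test_ang_at_most_vol_error(self, bundle, grid):
        """Angular weighting is less contaminated by crossings than vol."""
        ff = bundle.fixel_field
        errs = {}
        for strategy in ("vol", "cfo", "ang"):
            devs = []
            for name, truth in (("T1", 0.70), ("T2", 0.66)):
                subs = split_tract(bundle.tracts[name], grid)
                wm = compute_weight_maps(subs, ff, strategy)
                mm = compute_microstructure_map(wm, ff, "FVF")
                devs.append(abs(tract_mean(mm, wm, "tsl").mean - truth))
            errs[strategy] = np.mean(devs)
        assert errs["ang"] <= errs["vol"]
        assert errs["cfo"] <= errs["vol"]

    def test_vol_roi_underestimates_high_fvf_tract(self, bundle, grid):
        """In crossings vol mixes in the lower-FVF vertical tracts."""
        ff = bundle.fixel_field
        subs = split_tract(bundle.tracts["T1"], grid)
        wm = compute_weight_maps(subs, ff, "vol")
        mm = compute_microstructure_map(wm, ff, "FVF")
        assert tract_mean(mm, wm, "roi").mean < 0.70
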