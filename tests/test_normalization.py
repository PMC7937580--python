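import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vqfunc import LungMask, UptakeVolume, candidate_sequence, converge_peak
from vqfunc.normalization import ConvergenceError

from conftest import naive_candidate_loop, random_uptake_sample


def _pair(values, mask=None):
    values = np.asarray(values, dtype=float)
    aff = np.diag([4.0, 4.0, 4.0, 1.0])
    vol = UptakeVolume(values=values, affine=aff, modality="ventilation")
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return vol, LungMask(values=mask, affine=aff)


class TestCandidateSequence:
    def test_hand_computed_guard_case(self):
        # [1,1,1,1,1,100]: x = 17.5, population sd = sqrt(1361.25), so the
        # first candidate 17.5 + 4*36.895... = 165.08 exceeds the maximum and
        # the guard keeps the original maximum as the peak.
        records, reduced, peak = candidate_sequence([1, 1, 1, 1, 1, 100])
        assert records[0].mean == pytest.approx(17.5)
        assert records[0].sd == pytest.approx(np.sqrt(1361.25))
        assert records[0].candidate_peak == pytest.approx(17.5 + 4 * np.sqrt(1361.25))
        assert records[0].z is None
        assert not reduced and peak == 100.0 and len(records) == 1

    def test_hand_computed_iterating_case(self):
        # 96 ones + 4 tens: x = 1.36, population variance
        # (96*0.36^2 + 4*8.64^2)/100 = 3.1104, candidate = 1.36 + 4*sqrt(3.1104)
        # = 8.4145 < 0.99*10, so iteration drops the tens and converges to 1.
        values = [1.0] * 96 + [10.0] * 4
        records, reduced, peak = candidate_sequence(values)
        assert records[0].candidate_peak == pytest.approx(1.36 + 4 * np.sqrt(3.1104))
        assert reduced and peak == pytest.approx(1.0)
        assert records[1].candidate_peak == pytest.approx(1.0)
        assert records[-1].z is not None and records[-1].z > 0.99
        assert [r.retained_count for r in records[1:]] == [96] * (len(records) - 1)

    def test_all_equal_terminates_via_guard(self):
        records, reduced, peak = candidate_sequence([5.0] * 20)
        assert not reduced and peak == 5.0 and len(records) == 1

    def test_fewer_than_two_values(self):
        with pytest.raises(ValueError, match="at least 2"):
            candidate_sequence([1.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            candidate_sequence([1.0, np.inf])

    def test_standard_normal_large_sample_decreasing_and_fast(self):
        # shifted to stay non-negative; candidates must strictly decrease
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(100_000) + 10.0
        records, reduced, peak = candidate_sequence(vals)
        cands = [r.candidate_peak for r in records]
        assert reduced
        assert all(b < a for a, b in zip(cands, cands[1:]))
        assert len(records) <= 10

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_reference_loop_exactly(self, seed):
        vals = random_uptake_sample(np.random.default_rng(seed))
        records, reduced, peak = candidate_sequence(vals)
        ref_cands, ref_zs, ref_reduced, ref_peak = naive_candidate_loop(vals)
        assert reduced == ref_reduced
        assert peak == ref_peak
        assert [r.candidate_peak for r in records] == ref_cands
        assert [r.z for r in records[1:]] == ref_zs

    def test_sigma_multiplier_override_disables_reduction(self):
        vals = random_uptake_sample(np.random.default_rng(3), outlier_fraction=0.02)
        _, reduced_default, _ = candidate_sequence(vals)
        _, reduced_high, peak_high = candidate_sequence(vals, sigma_multiplier=1000.0)
        assert reduced_default
        assert not reduced_high and peak_high == vals.max()

    def test_iteration_cap_raises(self):
        with pytest.raises(ConvergenceError):
            vals = random_uptake_sample(np.random.default_rng(4), outlier_fraction=0.02)
            candidate_sequence(vals, max_iterations=1)


class TestConvergePeak:
    def test_uniform_lung_guard(self):
        vol, mask = _pair(np.full((6, 6, 6), 5.0))
        res = converge_peak(vol, mask)
        assert not res.reduction_applied
        assert res.peak_intensity == 5.0
        assert res.normalized_volume_fraction == 0.0
        np.testing.assert_array_equal(res.normalized_values, vol.values)

    def test_hotspots_clipped_to_peak_exactly(self):
        rng = np.random.default_rng(8)
        values = rng.lognormal(0, 0.2, (12, 12, 12))
        hot_idx = (np.array([1, 3, 5, 7, 9]), np.array([2, 4, 6, 8, 10]), np.array([3, 3, 3, 3, 3]))
        values[hot_idx] = 50.0 * values.mean()
        vol, mask = _pair(values)
        res = converge_peak(vol, mask)
        assert res.reduction_applied
        assert res.peak_intensity < 2.0 * np.partition(values.ravel(), -6)[-6]
        # all 5 hotspot voxels clipped (the upper background tail may add a few)
        assert np.all(res.clipped_mask[hot_idx])
        assert res.normalized_voxel_count >= 5
        assert res.normalized_volume_fraction == pytest.approx(
            res.normalized_voxel_count / 12**3
        )
        # clipped voxels sit exactly at the peak; everything else untouched
        diff = res.normalized_values != vol.values
        assert diff.sum() == res.normalized_voxel_count
        assert np.all(res.normalized_values[diff] == res.peak_intensity)
        assert np.all(vol.values[diff] > res.peak_intensity)
        # z sequence climbs above the convergence cutoff
        zs = [r.z for r in res.iterations[1:]]
        assert len(res.iterations) >= 2 and zs[-1] > 0.99

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(9)
        values = rng.lognormal(0, 0.3, (10, 10, 10))
        values[0, 0, 0] = 100 * values.mean()
        vol, mask = _pair(values)
        res = converge_peak(vol, mask)
        assert res.reduction_applied
        vol2 = UptakeVolume(values=res.normalized_values, affine=vol.affine,
                            modality="ventilation")
        res2 = converge_peak(vol2, mask)
        assert not res2.reduction_applied
        assert res2.peak_intensity == res.peak_intensity
        np.testing.assert_array_equal(res2.normalized_values, res.normalized_values)

    def test_outside_mask_untouched(self):
        rng = np.random.default_rng(10)
        values = rng.lognormal(0, 0.3, (10, 10, 10))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        values[5, 5, 5] = 100 * values.mean()
        values[0, 0, 0] = 500 * values.mean()  # extreme voxel outside the lung
        vol, m = _pair(values, mask)
        res = converge_peak(vol, m)
        assert res.normalized_values[0, 0, 0] == values[0, 0, 0]
        assert res.original_max == pytest.approx(values[5, 5, 5])

    def test_geometry_checked_first(self):
        vol, _ = _pair(np.ones((4, 4, 4)))
        bad_mask = LungMask(values=np.ones((4, 4, 5)), affine=vol.affine)
        with pytest.raises(Exception, match="geometry|shape"):
            converge_peak(vol, bad_mask)

    def test_singleton_mask_rejected(self):
        values = np.ones((4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        vol, m = _pair(values, mask)
        with pytest.raises(ValueError, match="at least 2"):
            converge_peak(vol, m)


class TestProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_convergence_and_termination(self, seed):
        vals = random_uptake_sample(np.random.default_rng(seed), n=2000)
        records, reduced, peak = candidate_sequence(vals)
        cands = [r.candidate_peak for r in records]
        assert all(b <= a for a, b in zip(cands, cands[1:]))
        assert all(r.z <= 1.0 for r in records if r.z is not None)
        assert len(records) <= 100
        assert peak <= vals.max()
        assert (peak == vals.max()) == (not reduced)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           scale=st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False))
    def test_scale_equivariance(self, seed, scale):
        vals = random_uptake_sample(np.random.default_rng(seed), n=1500,
                                    outlier_fraction=0.02)
        rec1, red1, peak1 = candidate_sequence(vals)
        rec2, red2, peak2 = candidate_sequence(vals * scale)
        assert red1 == red2
        assert len(rec1) == len(rec2)
        assert peak2 == pytest.approx(peak1 * scale, rel=1e-9)
        for a, b in zip(rec1[1:], rec2[1:]):
            assert b.z == pytest.approx(a.z, rel=1e-9)
            assert b.retained_count == a.retained_count
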