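"""TBR normalization and TTP / late-slope parametric maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliorad import (
    CohortSpec,
    DynamicVolume,
    FrameSchedule,
    Mask,
    Volume,
    compute_slope_map,
    compute_tbr,
    compute_ttp_map,
    generate_subject,
    ttp_category,
)
from gliorad.kinetics import (
    KineticComputationError,
    NormalizationError,
    TTP_CATEGORY_LABELS,
    static_average,
    tbr_dynamic,
    ttp_category_label,
)

from oracles import naive_slope_per_hour, naive_ttp

SPACING = (2.0, 2.0, 2.0)


def _bg_mask(shape, n=64):
    m = np.zeros(shape, dtype=bool)
    m.ravel()[:n] = True
    return Mask(m, SPACING, "background")


def _dyn_from_tac(tac, schedule, shape=(4, 4, 4)):
    values = np.broadcast_to(np.asarray(tac), shape + (len(tac),)).copy()
    return DynamicVolume(values, SPACING, schedule)


class TestTBR:
    def test_constant_volume_normalized_by_background_mean(self):
        vol = Volume(np.full((8, 8, 8), 4.0), SPACING)
        bg = _bg_mask((8, 8, 8))
        vol.values[bg.values] = 2.0
        tbr = compute_tbr(vol, bg)
        assert np.allclose(tbr.values[~bg.values], 2.0)

    def test_background_equals_volume_gives_unity(self, rng):
        vol = Volume(np.full((8, 8, 8), 3.7), SPACING)
        tbr = compute_tbr(vol, _bg_mask((8, 8, 8)))
        assert np.allclose(tbr.values, 1.0)

    @given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance_and_unit_background_mean(self, scale, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.5, 5.0, size=(6, 6, 6))
        bg = _bg_mask((6, 6, 6))
        t1 = compute_tbr(Volume(values, SPACING), bg)
        t2 = compute_tbr(Volume(values * scale, SPACING), bg)
        np.testing.assert_allclose(t1.values, t2.values, rtol=1e-10)
        assert t1.values[bg.values].mean() == pytest.approx(1.0)

    def test_empty_or_nonpositive_background_rejected(self):
        vol = Volume(np.ones((8, 8, 8)), SPACING)
        with pytest.raises(NormalizationError):
            compute_tbr(vol, Mask(np.zeros((8, 8, 8), bool), SPACING, "background"))
        neg = Volume(-np.ones((8, 8, 8)), SPACING)
        with pytest.raises(NormalizationError):
            compute_tbr(neg, _bg_mask((8, 8, 8)))

    def test_dynamic_tbr_flattens_background_tac(self, fet_schedule, rng):
        values = rng.uniform(1.0, 2.0, size=(6, 6, 6, 16))
        dyn = DynamicVolume(values, SPACING, fet_schedule)
        bg = _bg_mask((6, 6, 6))
        norm = tbr_dynamic(dyn, bg)
        for i in range(16):
            assert norm.values[..., i][bg.values].mean() == pytest.approx(1.0)


class TestTTP:
    def test_peak_at_7p5_minutes(self, fet_schedule):
        mids = fet_schedule.midpoints_min()
        tac = -np.abs(mids - 7.5)  # peak exactly at the 7.5-min midpoint
        ttp = compute_ttp_map(_dyn_from_tac(tac, fet_schedule))
        assert np.all(ttp.values == 7.5)
        assert ttp_category_label(7.5) == "5-10 min"

    def test_strictly_increasing_tac_gets_final_midpoint(self, fet_schedule):
        tac = np.linspace(0.0, 1.0, 16)
        ttp = compute_ttp_map(_dyn_from_tac(tac, fet_schedule))
        assert np.all(ttp.values == 35.0)
        assert ttp_category_label(35.0) == "30-40 min"

    def test_tie_broken_toward_earliest_frame(self, fet_schedule):
        mids = fet_schedule.midpoints_min()
        tac = np.zeros(16)
        tac[mids == 12.5] = 5.0
        tac[mids == 25.0] = 5.0
        ttp = compute_ttp_map(_dyn_from_tac(tac, fet_schedule))
        assert np.all(ttp.values == 12.5)

    def test_blood_pool_frames_excluded(self, fet_schedule):
        tac = np.zeros(16)
        tac[0] = 100.0  # huge early blood-pool signal, midpoint < 3 min
        tac[13] = 1.0   # true tissue peak at 17.5 min
        ttp = compute_ttp_map(_dyn_from_tac(tac, fet_schedule))
        assert np.all(ttp.values == 17.5)

    def test_restrict_mask_sets_invalid_sentinel(self, fet_schedule):
        dyn = _dyn_from_tac(np.linspace(0, 1, 16), fet_schedule)
        restrict = np.zeros((4, 4, 4), dtype=bool)
        restrict[0, 0, 0] = True
        ttp = compute_ttp_map(dyn, Mask(restrict, SPACING, "t2_whole_tumor"))
        assert ttp.values[0, 0, 0] == 35.0
        assert np.isnan(ttp.values[1, 1, 1])

    def test_short_schedule_rejected(self):
        sched = FrameSchedule.from_durations([60.0, 60.0])
        with pytest.raises(KineticComputationError):
            compute_ttp_map(_dyn_from_tac([1.0, 2.0], sched))


class TestSlope:
    def test_exact_linear_tac_recovered(self, fet_schedule):
        t_hours = fet_schedule.midpoints_min() / 60.0
        tac = 2.0 + 0.6 * t_hours
        slope = compute_slope_map(_dyn_from_tac(tac, fet_schedule))
        np.testing.assert_allclose(slope.values, 0.6, rtol=1e-10)

    def test_constant_tac_zero_slope(self, fet_schedule):
        slope = compute_slope_map(_dyn_from_tac(np.full(16, 3.0), fet_schedule))
        np.testing.assert_allclose(slope.values, 0.0, atol=1e-12)

    def test_linearity_in_tac(self, fet_schedule, rng):
        tac = rng.random(16)
        s1 = compute_slope_map(_dyn_from_tac(tac, fet_schedule)).values
        s3 = compute_slope_map(_dyn_from_tac(3.0 * tac, fet_schedule)).values
        np.testing.assert_allclose(s3, 3.0 * s1, rtol=1e-10)


class TestOracleEquivalence:
    def test_ttp_and_slope_match_per_voxel_loop(self, fet_schedule, rng):
        dyn = DynamicVolume(rng.uniform(0, 5, size=(6, 6, 6, 16)), SPACING, fet_schedule)
        mids = fet_schedule.midpoints_min()
        ttp = compute_ttp_map(dyn).values
        slope = compute_slope_map(dyn).values
        for idx in np.ndindex(6, 6, 6):
            tac = dyn.values[idx]
            assert ttp[idx] == naive_ttp(tac, mids)
            assert slope[idx] == pytest.approx(naive_slope_per_hour(tac, mids), rel=1e-9)


class TestCategories:
    @pytest.mark.parametrize("ttp,label", [(4.0, "<5 min"), (35.0, "30-40 min"),
                                           (5.0, "<5 min"), (10.5, "10-15 min")])
    def test_examples(self, ttp, label):
        assert ttp_category_label(ttp) == label

    def test_six_eligible_midpoints_map_to_six_distinct_categories(self, fet_schedule):
        mids = fet_schedule.midpoints_min()
        eligible = mids[mids > 3.0]
        cats = [ttp_category(t) for t in eligible]
        assert sorted(cats) == list(range(6))
        assert len(TTP_CATEGORY_LABELS) == 6

    @pytest.mark.parametrize("bad", [0.0, -1.0, 40.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            ttp_category(bad)


class TestStaticAverages:
    def test_window_average_is_duration_weighted(self, fet_schedule):
        # constant 1 in 20-30 min frame, constant 3 in 30-40 min frame
        tac = np.zeros(16)
        tac[-2] = 1.0
        tac[-1] = 3.0
        avg = static_average(_dyn_from_tac(tac, fet_schedule), (20, 40))
        assert np.allclose(avg.values, 2.0)  # equal 10-min durations

    def test_empty_window_rejected(self, fet_schedule):
        with pytest.raises(KineticComputationError):
            static_average(_dyn_from_tac(np.ones(16), fet_schedule), (41, 42))


class TestGeneratorKineticContract:
    """Noise-free phantoms must satisfy the class-conditional kinetic signatures."""

    @pytest.mark.parametrize("label,ttp_ok,slope_sign", [
        ("IDH_wildtype", lambda t: t < 15.0, -1),
        ("IDH_mutant", lambda t: 30.0 < t <= 40.0, +1),
    ])
    def test_rim_voxels_follow_class_signature(self, noisefree_spec, label, ttp_ok, slope_sign):
        subj = generate_subject(noisefree_spec, label, subject_seed=0)
        ttp = compute_ttp_map(subj.dynamic_fet).values
        slope = compute_slope_map(subj.dynamic_fet).values
        # active rim = tumor voxels outside the necrotic core: reconstruct from
        # contrast structure (rim has the maximal TSPO amplitude for wild-type);
        # use the confining minus edema geometry via the truth mask instead
        rim = _rim_mask(noisefree_spec, subj)
        assert rim.sum() > 100
        assert np.all([ttp_ok(t) for t in ttp[rim]])
        assert np.all(np.sign(slope[rim]) == slope_sign)


def _rim_mask(spec, subj):
    """Recover the active-rim compartment of a noise-free phantom from its
    dynamic amplitude (rim amplitude is the class maximum by construction)."""
    dyn = subj.dynamic_fet.values
    amp = dyn.max(axis=-1) - dyn[..., 0]
    peak = amp.max()
    return amp > 0.75 * peak
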