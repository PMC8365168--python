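import dataclasses

import numpy as np
import pytest

from whistlechain.io_tracks import hz_to_semitones
from whistlechain.synthetic_data import (ChainPlan, GeneratorParams,
                                         ValidationError, constant_plan,
                                         drifting_plan,
                                         generate_chain_dataset,
                                         generate_whistle_set,
                                         initial_set_params,
                                         interpolate_params)


class TestGenerateWhistleSet:
    def test_same_seed_bitwise_identical(self):
        params = GeneratorParams(n_whistles=4)
        s1, t1 = generate_whistle_set(params, seed=99)
        s2, t2 = generate_whistle_set(params, seed=99)
        for w1, w2 in zip(s1, s2):
            assert np.array_equal(w1.pitch.values, w2.pitch.values,
                                  equal_nan=True)
            assert np.array_equal(w1.intensity.values, w2.intensity.values)
        assert t1.records == t2.records
        assert t1.block_sequences == t2.block_sequences

    def test_different_seeds_differ(self):
        params = GeneratorParams(n_whistles=4)
        s1, _ = generate_whistle_set(params, seed=1)
        s2, _ = generate_whistle_set(params, seed=2)
        assert not np.array_equal(s1.whistles[0].pitch.values,
                                  s2.whistles[0].pitch.values, equal_nan=True)

    def test_zero_noise_targets_on_scale(self):
        params = GeneratorParams(n_whistles=8, n_pitch_levels=2,
                                 level_jitter_sd=0.0, pitch_noise_sd=0.0)
        _, truth = generate_whistle_set(params, seed=3)
        levels = params.scale_levels()
        for rec in truth.records:
            for v in rec["target_values_st"]:
                assert np.min(np.abs(levels - v)) < 1e-9

    def test_jittered_targets_near_scale(self):
        params = GeneratorParams(n_whistles=8, n_pitch_levels=2,
                                 level_jitter_sd=0.1, pitch_noise_sd=0.0)
        _, truth = generate_whistle_set(params, seed=4)
        levels = params.scale_levels()
        devs = [np.min(np.abs(levels - v)) for rec in truth.records
                for v in rec["target_values_st"]]
        assert max(devs) < 0.5
        assert np.mean(devs) < 0.3

    def test_truth_segments_match_track_layout(self):
        params = GeneratorParams(n_whistles=5, pitch_noise_sd=0.0,
                                 level_jitter_sd=0.0)
        wset, truth = generate_whistle_set(params, seed=5)
        by_id = {w.whistle_id: w for w in wset}
        for rec in truth.records:
            pitch = by_id[rec["whistle_id"]].pitch.values
            seg = pitch[rec["start_sample"]:rec["end_sample"]]
            assert np.all(np.isfinite(seg))
            assert seg[0] == pytest.approx(rec["onset_st"], abs=1e-9)

    def test_pitch_respects_instrument_bounds(self):
        params = GeneratorParams(n_whistles=10, pitch_noise_sd=0.4,
                                 level_jitter_sd=0.8, n_pitch_levels=0)
        wset, _ = generate_whistle_set(params, seed=6)
        lo = hz_to_semitones(params.pitch_floor_hz)
        hi = hz_to_semitones(params.pitch_ceiling_hz)
        for w in wset:
            finite = w.pitch.values[np.isfinite(w.pitch.values)]
            assert finite.min() >= lo and finite.max() <= hi

    def test_onset_interval_scale_recovered(self):
        # all-horizontal blocks share one feasible onset window, so the
        # reflected random walk's mean absolute step is the raw scale
        params = GeneratorParams(n_whistles=150, n_pitch_levels=0,
                                 onset_interval_scale_st=2.0,
                                 segments_per_whistle_mean=4.0,
                                 contour_mixture={"horizontal": 1.0})
        _, truth = generate_whistle_set(params, seed=7)
        diffs = []
        frame = truth.frame()
        for _, grp in frame.groupby("whistle_id"):
            onsets = grp.sort_values("segment_index")["onset_st"].to_numpy()
            diffs.extend(np.abs(np.diff(onsets)))
        assert len(diffs) > 300
        assert np.mean(diffs) == pytest.approx(2.0, rel=0.10)

    @pytest.mark.parametrize("conc", [0.0, 1.0, 2.2])
    def test_block_entropy_matches_target(self, conc):
        params = GeneratorParams(n_whistles=60, n_block_types=5,
                                 block_reuse_concentration=conc,
                                 segments_per_whistle_mean=4.0)
        _, truth = generate_whistle_set(params, seed=8)
        w = np.exp(-conc * np.arange(5))
        p = w / w.sum()
        expected = float(-(p * np.log2(p)).sum())
        assert truth.label_entropy_bits == pytest.approx(expected, abs=0.2)

    @pytest.mark.parametrize("kwargs", [
        {"n_whistles": 0},
        {"n_pitch_levels": -1},
        {"pitch_noise_sd": -0.1},
        {"mean_segment_duration_s": 0.0},
        {"contour_mixture": {"ascending": 0.7}},        # not a prob. vector
        {"contour_mixture": {"zigzag": 1.0}},           # unknown label
        {"n_pitch_levels": 12, "level_jitter_sd": 2.0},  # levels would smear
        {"pitch_floor_hz": 2400.0},                      # window too narrow
    ])
    def test_infeasible_params_rejected(self, kwargs):
        params = GeneratorParams(**kwargs)
        with pytest.raises(ValidationError):
            generate_whistle_set(params, seed=0)


class TestInterpolation:
    def test_endpoints_and_midpoint(self):
        plan = drifting_plan()
        start, end = plan.start_params, plan.end_params
        p0 = interpolate_params(start, end, 0.0)
        p1 = interpolate_params(start, end, 1.0)
        assert p0.n_pitch_levels == start.n_pitch_levels
        assert p1.n_pitch_levels == end.n_pitch_levels
        assert p0.block_reuse_concentration == pytest.approx(
            start.block_reuse_concentration)
        mid = interpolate_params(start, end, 0.5)
        assert mid.block_reuse_concentration == pytest.approx(
            (start.block_reuse_concentration + end.block_reuse_concentration)
            / 2)
        assert sum(mid.contour_mixture.values()) == pytest.approx(1.0)
        assert mid.seed is None

    def test_integer_fields_rounded(self):
        a = GeneratorParams(n_block_types=4)
        b = GeneratorParams(n_block_types=9)
        assert interpolate_params(a, b, 0.5).n_block_types in (6, 7)
        assert isinstance(interpolate_params(a, b, 0.3).n_whistles, int)


class TestChainDataset:
    def test_structure_and_determinism(self):
        plan = constant_plan(GeneratorParams(n_whistles=2), n_generations=3,
                             n_chains=2)
        ds1, truths1 = generate_chain_dataset(plan, seed=11)
        ds2, _ = generate_chain_dataset(plan, seed=11)
        assert sorted(ds1.chains) == ["chain1", "chain2"]
        for sets in ds1.chains.values():
            assert [s.generation for s in sets] == [1, 2, 3]
        assert set(truths1) == {(c, g) for c in ("chain1", "chain2")
                                for g in (1, 2, 3)}
        for s1, s2 in zip(ds1.sets(), ds2.sets()):
            for w1, w2 in zip(s1, s2):
                assert np.array_equal(w1.pitch.values, w2.pitch.values,
                                      equal_nan=True)

    def test_chains_are_independent(self):
        plan = constant_plan(GeneratorParams(n_whistles=2), n_generations=2,
                             n_chains=2)
        ds, _ = generate_chain_dataset(plan, seed=12)
        a = ds.chains["chain1"][0].whistles[0].pitch.values
        b = ds.chains["chain2"][0].whistles[0].pitch.values
        assert a.shape != b.shape or not np.array_equal(a, b, equal_nan=True)

    def test_presets_validate(self):
        drifting_plan().validate()
        constant_plan().validate()
        initial_set_params().validate()

    def test_too_few_generations_rejected(self):
        plan = ChainPlan(start_params=GeneratorParams(),
                         end_params=GeneratorParams(), n_generations=1)
        with pytest.raises(ValidationError):
            generate_chain_dataset(plan, seed=0)

    def test_drift_is_monotone_in_generation(self):
        plan = drifting_plan(n_generations=5, n_chains=1)
        _, truths = generate_chain_dataset(plan, seed=13)
        levels = [len(truths[("chain1", g)].scale_levels) for g in range(1, 6)]
        assert levels == sorted(levels)
        assert levels[0] == 2 and levels[-1] == 5
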