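"""Segmentation engine: noise-profile estimation, recursive splitting,
edge correction, and tiling/determinism invariants."""

import numpy as np
import pytest

from ecbs.config import RunConfig
from ecbs.maxt import ProbeSeries
from ecbs.segmentation import (
    ArrayNoiseProfile,
    edge_correct,
    find_change_points,
    pre_segment_and_estimate,
)

NULL_PROFILE = ArrayNoiseProfile(0.0, 3.0, 0, 0)


def _series(values):
    return ProbeSeries(np.asarray(values, dtype=float))


class TestPreSegmentation:
    def test_pure_noise_moments(self, rng):
        """Averaged over independent 2000-probe arrays so the +/-0.1 and
        +/-0.2 windows exceed four Monte-Carlo standard errors."""
        profs = [
            pre_segment_and_estimate([_series(rng.normal(size=2000))])
            for _ in range(6)
        ]
        assert np.mean([p.sk for p in profs]) == pytest.approx(0.0, abs=0.1)
        assert np.mean([p.ku for p in profs]) == pytest.approx(3.0, abs=0.2)

    def test_shift_removed_before_moment_estimation(self, rng):
        """A large copy-number shift inflates naive whole-array kurtosis;
        pre-segmentation subtracts it so the noise moments survive."""
        sks, kus, naive_kus = [], [], []
        for _ in range(6):
            noise = rng.normal(size=2000)
            shifted = noise.copy()
            shifted[800:1100] += 2.5
            naive_d = shifted - shifted.mean()
            naive_kus.append(np.mean(naive_d**4) / np.mean(naive_d**2) ** 2)
            prof = pre_segment_and_estimate([_series(shifted)])
            sks.append(prof.sk)
            kus.append(prof.ku)
            assert prof.n_probes_used <= 2000
        # the naive estimate is visibly biased; the corrected one is not
        assert np.mean(naive_kus) > 3.25
        assert np.mean(sks) == pytest.approx(0.0, abs=0.1)
        assert np.mean(kus) == pytest.approx(3.0, abs=0.2)

    def test_constant_array_falls_back(self, caplog):
        prof = pre_segment_and_estimate([_series(np.zeros(500))])
        assert (prof.sk, prof.ku) == (0.0, 3.0)

    def test_profile_clamped_to_grid(self, rng):
        """Extremely heavy-tailed arrays clamp to the table ranges."""
        x = rng.standard_t(df=3, size=3000)  # kurtosis far above 5.6
        prof = pre_segment_and_estimate([_series(x)])
        assert -1.0 <= prof.sk <= 1.0
        assert 2.6 <= prof.ku <= 5.6


class TestEdgeCorrection:
    def test_true_boundary_retained(self, rng):
        values = np.concatenate([rng.normal(0, 0.2, 60), rng.normal(2, 0.2, 60)])
        assert edge_correct(_series(values), [60]) == [60]

    def test_equal_mean_join_dropped(self, rng):
        """Circular joining of two equal-mean ends can propose a boundary
        with no real shift across it; the t-test removes it."""
        values = rng.normal(0, 0.2, 120)
        assert edge_correct(_series(values), [60]) == []

    def test_all_failing_rejects_split(self, rng):
        values = rng.normal(0, 0.2, 120)
        assert edge_correct(_series(values), [40, 80]) == []

    def test_unverifiable_tiny_window_dropped(self, rng):
        values = rng.normal(0, 0.2, 60)
        values[:1] += 5.0
        assert 1 not in edge_correct(_series(values), [1])


class TestFindChangePoints:
    def test_noiseless_piecewise_exact(self, tiny_model):
        values = [0.0] * 49 + [2.0] * 20 + [-2.0] * 10 + [2.0] * 20 + [0.0] * 51
        segset = find_change_points(
            _series(values), NULL_PROFILE, tiny_model, RunConfig(seed=1)
        )
        assert segset.boundaries == [49, 69, 79, 99]
        assert len(segset.records) == 5

    def test_segments_tile_the_series(self, tiny_model, rng):
        values = rng.normal(size=300)
        values[100:160] += 1.5
        segset = find_change_points(
            _series(values), NULL_PROFILE, tiny_model, RunConfig(seed=2)
        )
        assert segset.records[0].start_index == 1
        assert segset.records[-1].end_index == 300
        assert sum(r.n_probes for r in segset.records) == 300
        for a, b in zip(segset.records[:-1], segset.records[1:]):
            assert b.start_index == a.end_index + 1

    def test_deterministic_given_seed(self, tiny_model, rng):
        values = rng.normal(size=220)
        values[50:90] += 1.0
        cfg = RunConfig(seed=3)
        a = find_change_points(_series(values), NULL_PROFILE, tiny_model, cfg,
                               np.random.default_rng(3))
        b = find_change_points(_series(values), NULL_PROFILE, tiny_model, cfg,
                               np.random.default_rng(3))
        assert a.boundaries == b.boundaries
        assert [r.p_value for r in a.records] == [r.p_value for r in b.records]

    def test_null_series_usually_unsplit(self, tiny_model):
        splits = 0
        for seed in range(30):
            values = np.random.default_rng(seed).normal(size=250)
            segset = find_change_points(
                _series(values), NULL_PROFILE, tiny_model, RunConfig(seed=seed)
            )
            splits += len(segset.records) > 1
        assert splits <= 3  # alpha = 0.01 with binomial slack

    def test_detection_monotone_in_amplitude(self, tiny_model):
        """Detection rate of an embedded segment never falls as the
        aberration amplitude grows."""
        rates = []
        for c in (1.0, 2.0, 3.0, 4.0):
            hits = 0
            for seed in range(25):
                rng = np.random.default_rng(10_000 + seed)
                values = rng.normal(size=250)
                values[100:130] += c
                segset = find_change_points(
                    _series(values), NULL_PROFILE, tiny_model,
                    RunConfig(seed=seed),
                )
                found = segset.boundaries
                hits += any(abs(b - 100) <= 2 for b in found) and any(
                    abs(b - 130) <= 2 for b in found
                )
            rates.append(hits / 25)
        assert all(b >= a - 0.08 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0.9

    def test_segment_array_shares_one_profile(self, tiny_model, rng):
        """The sample-level driver estimates the noise profile once from
        all chromosomes and segments each with it."""
        from ecbs.segmentation import segment_array

        chrom1 = ProbeSeries(rng.normal(size=600), sample_id="s", chrom="1")
        vals = rng.normal(size=400)
        vals[100:300] += 2.0
        chrom2 = ProbeSeries(vals, sample_id="s", chrom="2")
        segsets, profile = segment_array([chrom1, chrom2], tiny_model,
                                         RunConfig(seed=8))
        assert len(segsets) == 2
        assert profile.n_probes_used <= 1000
        assert abs(profile.sk) <= 1.0
        # the strong aberration on chrom2 is found
        assert any(abs(b - 100) <= 2 for b in segsets[1].boundaries)
        assert any(abs(b - 300) <= 2 for b in segsets[1].boundaries)

    def test_degenerate_subsegment_is_terminal(self, tiny_model):
        values = np.concatenate([np.zeros(120), np.random.default_rng(0).normal(2, 0.1, 120)])
        segset = find_change_points(
            _series(values), NULL_PROFILE, tiny_model, RunConfig(seed=4)
        )
        assert sum(r.n_probes for r in segset.records) == 240
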