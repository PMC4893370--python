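"""Feature families: hand-computed oracles, naive-loop equivalence, and the
structural laws of the 2N+3 descriptor."""

import dataclasses

import numpy as np
import pytest

from conftest import make_partition, naive_bm, naive_bs, random_partition
from srtoct.features import (BlockSpec, FeatureConfig, blockwise_mscan_features,
                             blockwise_speckle_features, extract_features,
                             feature_names, locate_rpe, normalize_profile,
                             partition_blocks, profile_crest_and_sum,
                             segments_from_names, speckle_variance_feature,
                             spectrogram_features)
from srtoct.io import MScan
from srtoct.preprocess import PulseTrain
from srtoct.synth import simulate_mscan


# ---------------------------------------------------------------------------
# Blockwise features: hand arithmetic and loop oracles


def test_blockwise_mscan_hand_example():
    """B'_2 = [[0,2],[0,2]] has mean 1 and sample s.d. sqrt(4/3)."""
    part = make_partition(np.zeros((2, 2)),
                          [np.ones((2, 2)), np.array([[0.0, 2.0], [0.0, 2.0]])])
    u = blockwise_mscan_features(part)
    sd = np.sqrt(4.0 / 3.0)  # 1.1547
    np.testing.assert_allclose(u, [0.0, sd, sd], rtol=1e-12)


def test_blockwise_speckle_hand_example():
    """Columns (1,1) and (3,3): R = (1,3), sample variance 2."""
    part = make_partition(np.zeros((2, 2)), [np.array([[1.0, 3.0], [1.0, 3.0]])])
    u = blockwise_speckle_features(part)
    np.testing.assert_allclose(u, [2.0, 2.0], rtol=1e-12)


def test_all_blocks_equal_reference_gives_zeros():
    ref = np.random.default_rng(0).gamma(2.0, 3.0, size=(5, 6))
    part = make_partition(ref, [ref.copy() for _ in range(4)])
    assert np.allclose(blockwise_mscan_features(part), 0.0)
    assert np.allclose(blockwise_speckle_features(part), 0.0)


@pytest.mark.parametrize("seed", range(5))
def test_blockwise_features_match_naive_loops(seed):
    rng = np.random.default_rng(seed)
    part = random_partition(rng)
    np.testing.assert_allclose(blockwise_mscan_features(part), naive_bm(part),
                               rtol=1e-12)
    np.testing.assert_allclose(blockwise_speckle_features(part), naive_bs(part),
                               rtol=1e-12)


def test_gradient_needs_two_analysis_blocks():
    part = make_partition(np.zeros((2, 2)), [np.ones((2, 2))])
    with pytest.raises(ValueError, match="two analysis blocks"):
        blockwise_mscan_features(part)


def test_shift_invariance_of_reference_subtracted_features(cropped_pos, reduced):
    """Adding a constant to every pixel leaves u_bm unchanged: the offset
    cancels in the reference subtraction.  (The rms-based u_bs is nonlinear
    in an additive offset, so no such exact law holds for it.)"""
    mscan, pulses = cropped_pos
    spec = reduced.feature.block
    p1 = partition_blocks(mscan, pulses, spec)
    shifted = mscan.with_data(mscan.data.astype(np.float64) + 37.0)
    p2 = partition_blocks(shifted, pulses,
                          dataclasses.replace(spec, rpe_center_row=p1.row_start
                                              + spec.block_height // 2))
    np.testing.assert_allclose(blockwise_mscan_features(p2),
                               blockwise_mscan_features(p1), rtol=1e-5, atol=1e-6)


# ---------------------------------------------------------------------------
# RPE localisation and partition geometry


def test_locate_rpe_on_synthetic_band(pos_sample, reduced):
    truth = pos_sample.truth
    row = locate_rpe(pos_sample.mscan, reduced.feature.block.block_height)
    assert abs(row - truth.rpe_center_row) <= truth.rpe_band_halfwidth


def test_locate_rpe_tie_breaks_to_smallest_row():
    data = np.ones((20, 10))
    data[8] = 5.0
    data[13] = 5.0
    assert locate_rpe(MScan(data=data, ascan_rate=1e3), block_height=4) == 8


def test_locate_rpe_clamps_near_edges():
    data = np.ones((600, 10))
    data[3] = 100.0
    assert locate_rpe(MScan(data=data, ascan_rate=1e3), block_height=300) == 150
    data2 = np.ones((600, 10))
    data2[590] = 100.0
    assert locate_rpe(MScan(data=data2, ascan_rate=1e3), block_height=300) == 450


def test_partition_geometry(cropped_pos, reduced):
    mscan, pulses = cropped_pos
    spec = reduced.feature.block
    part = partition_blocks(mscan, pulses, spec)
    assert part.n_blocks == 2 * pulses.n_pulses  # 60 for 30 pulses
    ref = part.reference
    assert ref.col_stop == pulses.onsets_columns[0]
    assert ref.col_stop - ref.col_start == spec.block_len
    period = pulses.period_columns
    for blk in part.blocks:
        assert blk.col_stop - blk.col_start == spec.block_len
        assert blk.data.shape == (spec.block_height, spec.block_len)
        assert blk.col_stop <= mscan.n_time
    # within-period blocks disjoint; cross-period overlap bounded
    by_onset = {int(o): [b for b in part.blocks if b.col_start in
                         (o, o + spec.block_len)] for o in pulses.onsets_columns}
    for onset, pair in by_onset.items():
        if len(pair) == 2:
            assert pair[0].col_stop <= pair[1].col_start
            assert pair[0].contains_pulse and not pair[1].contains_pulse
            overlap = pair[1].col_stop - (onset + period)
            assert overlap <= 2 * spec.block_len - period


def test_partition_rejects_thin_margin(cropped_pos, reduced):
    mscan, pulses = cropped_pos
    late = PulseTrain(onsets_columns=pulses.onsets_columns - 80,
                      onsets_seconds=pulses.onsets_seconds,
                      pulse_rate=pulses.pulse_rate)
    with pytest.raises(ValueError, match="margin"):
        partition_blocks(mscan, late, reduced.feature.block)


def test_single_pulse_partition_smallest_case():
    rng = np.random.default_rng(4)
    mscan = MScan(data=rng.gamma(2.0, 5.0, (30, 100)), ascan_rate=1e4)
    pulses = PulseTrain(onsets_columns=[20], onsets_seconds=[0.002], pulse_rate=100)
    spec = BlockSpec(block_len=20, block_height=10, rpe_center_row=15)
    part = partition_blocks(mscan, pulses, spec)
    assert part.n_blocks == 3  # reference + pulse block + inter-pulse block
    fv = extract_features(mscan, pulses, FeatureConfig(
        block=spec, sv_ma_window=50, stft_window=16, stft_hop=2))
    assert fv.values.size == 2 * 3 + 3


# ---------------------------------------------------------------------------
# Whole-scan features


def test_speckle_variance_constant_raster_is_zero():
    mscan = MScan(data=np.full((10, 200), 3.0), ascan_rate=1e4)
    assert speckle_variance_feature(mscan, ma_window=20) == 0


def test_speckle_variance_null_rate_is_small(cropped_neg):
    mscan, pulses = cropped_neg
    count = speckle_variance_feature(mscan, ma_window=pulses.period_columns)
    assert count / mscan.n_time < 0.01


def test_speckle_variance_separates_matched_pairs(reduced):
    """Positive scans count strictly more exceedances than matched negatives."""
    from srtoct.synth import SimulationConfig
    wins = 0
    for seed in range(20):
        base = SimulationConfig(depth_px=150, seed=700 + seed, ascan_rate=8750.0,
                                duration=0.1, n_pulses=10, lead_in_s=0.01)
        pos = simulate_mscan(base)
        neg = simulate_mscan(dataclasses.replace(base, burst_amplitude=0.0))
        w = round(base.ascan_rate / base.pulse_rate)
        if (speckle_variance_feature(pos.mscan, ma_window=w)
                > speckle_variance_feature(neg.mscan, ma_window=w)):
            wins += 1
    assert wins == 20


def test_normalized_profile_attains_bounds():
    rng = np.random.default_rng(8)
    z = normalize_profile(rng.normal(size=50) * 40.0 - 300.0)
    assert z.min() == 0.0 and z.max() == 1.0
    assert np.all((z >= 0) & (z <= 1))


def test_crest_and_sum_hand_example():
    """Z-hat = (0,1,0,0): rms = 0.5, crest = 2, sum = 1."""
    crest, total = profile_crest_and_sum(np.array([0.0, 1.0, 0.0, 0.0]))
    assert crest == pytest.approx(2.0, rel=1e-12)
    assert total == pytest.approx(1.0, rel=1e-12)
    # affine-transformed raw profile normalizes back to the same Z-hat
    zhat = normalize_profile(np.array([0.0, 1.0, 0.0, 0.0]) * 7.5 - 120.0)
    np.testing.assert_allclose(zhat, [0.0, 1.0, 0.0, 0.0], atol=1e-12)


def test_crest_factor_at_least_one(cropped_pos, cropped_neg, reduced):
    for mscan, _ in (cropped_pos, cropped_neg):
        crest, _ = spectrogram_features(mscan, reduced.feature)
        assert crest >= 1.0


def test_degenerate_profile_conventions():
    crest, total = profile_crest_and_sum(np.zeros(10))
    assert (crest, total) == (1.0, 0.0)
    assert np.array_equal(normalize_profile(np.full(10, 3.3)), np.zeros(10))


def test_spectrogram_requires_long_enough_scan(reduced):
    mscan = MScan(data=np.ones((10, 20)), ascan_rate=1e4)
    with pytest.raises(ValueError, match="STFT"):
        spectrogram_features(mscan, reduced.feature)


# ---------------------------------------------------------------------------
# Assembly


def test_descriptor_length_law_and_segments(cropped_pos, reduced):
    fv = extract_features(*cropped_pos, reduced.feature)
    assert fv.n_blocks == 60
    u = fv.values
    assert u.size == 2 * fv.n_blocks + 3 == 123
    # concatenation slices reassemble the vector exactly
    segs = fv.segments
    np.testing.assert_array_equal(
        np.concatenate([u[segs[f]] for f in ("bm", "bs", "sv", "sp")]), u)
    assert fv.names[:2] == ["bm_000", "bm_001"]
    assert fv.names[-3:] == ["sv", "sp_crest", "sp_sum"]
    assert fv.u_sv == int(fv.u_sv) >= 0


def test_segments_from_names_roundtrip():
    names = feature_names(4)
    segs = segments_from_names(names)
    assert [len(segs[f]) for f in ("bm", "bs", "sv", "sp")] == [4, 4, 1, 2]
    with pytest.raises(ValueError, match="family"):
        segments_from_names(["bogus"])
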