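"""Shared fixtures: reduced-scale simulated scans, preprocessed versions.

Simulation-based tests run at the reduced acquisition scale (17.5 kHz,
300 depth pixels, 175-column pulse period) which preserves the block-count
arithmetic of the clinical geometry while keeping each scan cheap to
generate.  Heavy fixtures are session-scoped so they are simulated once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from srtoct import presets, synth
from srtoct.features import Block, BlockPartition
from srtoct.pipeline import preprocess_sample


@pytest.fixture(scope="session")
def reduced():
    return presets.reduced_scale()


@pytest.fixture(scope="session")
def pos_sample(reduced):
    """One positive (strong-burst) reduced-scale sample."""
    return synth.simulate_mscan(dataclasses.replace(reduced.simulation, seed=101))


@pytest.fixture(scope="session")
def neg_sample(reduced):
    """One negative (no-burst) reduced-scale sample."""
    return synth.simulate_mscan(
        dataclasses.replace(reduced.simulation, burst_amplitude=0.0, seed=102))


@pytest.fixture(scope="session")
def cropped_pos(reduced, pos_sample):
    """The positive sample preprocessed: (cropped scan, pulse train)."""
    return preprocess_sample(pos_sample.mscan, pos_sample.trace,
                             pre_margin=reduced.pre_margin, correct_motion=False)


@pytest.fixture(scope="session")
def cropped_neg(reduced, neg_sample):
    return preprocess_sample(neg_sample.mscan, neg_sample.trace,
                             pre_margin=reduced.pre_margin, correct_motion=False)


def make_partition(reference: np.ndarray, blocks: list[np.ndarray]) -> BlockPartition:
    """Assemble a BlockPartition directly from arrays (for oracle tests)."""
    ref = np.asarray(reference, dtype=np.float64)
    t = ref.shape[1]
    return BlockPartition(
        reference=Block(data=ref, col_start=0, col_stop=t, contains_pulse=False),
        blocks=[Block(data=np.asarray(b, dtype=np.float64),
                      col_start=(i + 1) * t, col_stop=(i + 2) * t,
                      contains_pulse=(i % 2 == 0))
                for i, b in enumerate(blocks)],
        row_start=0, row_stop=ref.shape[0])


def random_partition(rng: np.random.Generator, n_analysis: int = 7,
                     shape: tuple[int, int] = (6, 8)) -> BlockPartition:
    ref = rng.gamma(2.0, 3.0, size=shape)
    return make_partition(ref, [rng.gamma(2.0, 3.0, size=shape)
                                for _ in range(n_analysis)])


def naive_bm(partition: BlockPartition) -> np.ndarray:
    """Two-loop oracle for the blockwise M-Scan features."""
    ref = partition.reference.data
    L, T = ref.shape
    u1 = []
    for blk in partition.blocks:
        bp = blk.data - ref
        mu = sum(bp[l][t] for l in range(L) for t in range(T)) / (L * T)
        ss = sum((bp[l][t] - mu) ** 2 for l in range(L) for t in range(T))
        u1.append(np.sqrt(ss / (L * T - 1)))
    grad = max(u1[i + 1] - u1[i] for i in range(len(u1) - 1))
    return np.array(u1 + [grad])


def naive_bs(partition: BlockPartition) -> np.ndarray:
    """Loop oracle for the blockwise speckle (rms-variance) features."""

    def rms_variance(block: np.ndarray) -> float:
        L, T = block.shape
        R = [np.sqrt(sum(block[l][t] ** 2 for l in range(L)) / L) for t in range(T)]
        mean = sum(R) / T
        return sum((r - mean) ** 2 for r in R) / (T - 1)

    v0 = rms_variance(partition.reference.data)
    u1 = [rms_variance(b.data) - v0 for b in partition.blocks]
    return np.array(u1 + [max(u1)])


def pair_count_auc(scores, labels) -> float:
    """Mann-Whitney AUC oracle: exhaustive positive/negative pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)
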