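"""Ready-made parameter bundles for the clinical-scale and reduced-scale
acquisition geometries.

The full-scale preset mirrors the clinical system: 600 depth pixels at
70 kHz, 30 pulses at 100 Hz over 300 ms (700-column period, 353-column /
300-row blocks, Hamming window 189, hop 21).  The reduced preset shrinks the
time axis by an integer factor (default 4: 17.5 kHz, 175-column period,
88-column blocks) and halves the depth axis, preserving the block-count
arithmetic (N = 60, descriptor length 123) while cutting simulation and
feature-extraction cost by roughly an order of magnitude.  Simulation-based
studies in the test-suite and reproduction scripts run at the reduced scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import ModelConfig
from .features import BlockSpec, FeatureConfig
from .synth import SimulationConfig

__all__ = ["Preset", "full_scale", "reduced_scale"]


@dataclass
class Preset:
    """A coherent (simulation, feature, model) parameter bundle."""

    simulation: SimulationConfig
    feature: FeatureConfig
    model: ModelConfig

    @property
    def pre_margin(self) -> int:
        """Pre-train crop margin: one block length, for the reference block."""
        return self.feature.block.block_len


def full_scale(seed: int = 0) -> Preset:
    return Preset(
        simulation=SimulationConfig(seed=seed),
        feature=FeatureConfig(block=BlockSpec(block_len=353, block_height=300)),
        model=ModelConfig(seed=seed),
    )


def reduced_scale(factor: int = 4, seed: int = 0) -> Preset:
    """Time axis shrunk by ``factor``, depth halved; geometry otherwise intact."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rate = 70_000.0 / factor
    block_len = round(353 / factor)
    stft_window = max(8, round(189 / factor))
    sim = SimulationConfig(depth_px=300, ascan_rate=rate, seed=seed)
    feat = FeatureConfig(
        block=BlockSpec(block_len=block_len, block_height=150),
        stft_window=stft_window, stft_hop=max(1, stft_window // 9))
    return Preset(simulation=sim, feature=feat,
                  model=ModelConfig(seed=seed))
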