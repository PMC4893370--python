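"""Synthetic M-Scan generator for selective retina therapy (SRT) monitoring.

Generates labeled depth x time OCT intensity rasters that emulate what a
Fourier-domain OCT system records while an SRT pulse train is applied to the
retina: a layered depth-reflectivity profile with a bright retinal pigment
epithelium (RPE) band, fully developed multiplicative speckle, a train of
laser pulses (default 30 at 100 Hz), and — for positive outcomes — transient
high-frequency intensity variations confined to rows around the RPE and
synchronized with the pulse onsets.  These variations stand in for the
microbubble activity that marks successful RPE cell rupture.

The generator is a statistical phenomenology, not a coherent OCT forward
model: no phase, no point-spread function, no B-scan geometry.  Its purpose
is to give every downstream stage (motion correction, pulse detection,
feature extraction, classification) a ground truth it can be tested against.
All randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MScan, PulseTrace, write_mscan, write_trace

__all__ = ["SimulationConfig", "SimulatedSample", "simulate_mscan",
           "iter_dataset", "simulate_dataset", "write_dataset"]


@dataclass
class SimulationConfig:
    """Parameters of one simulated SRT M-Scan acquisition.

    The defaults mirror the clinical acquisition geometry: 600 depth pixels,
    70 kHz A-Scan rate, a 300 ms pulse-train window holding 30 pulses at
    100 Hz, and a photodetector trace sampled at 1 MHz.  ``lead_in_s`` of
    pre-train recording precedes the first pulse so that a laser-free
    reference block is always available.

    Parameters
    ----------
    burst_amplitude
        Dimensionless effect size of the microbubble signal, >= 0.  Pixels in
        ``burst_rows`` are multiplied by ``1 + burst_amplitude * |N(0,1)|``
        (independently per pixel) for ``burst_duration`` seconds after each
        pulse onset.  0 produces a scan statistically identical to an
        untreated (negative) one; the default 2.0 is a strong, clearly
        separable effect.
    burst_pulses
        If set, only the first ``burst_pulses`` pulses produce bursts
        (emulates effects confined to the early part of the train); None
        means every pulse does.
    speckle_model
        ``"exponential-intensity"`` draws per-pixel intensity as
        mean * Exp(1) (fully developed speckle; mean equals standard
        deviation); ``"rayleigh-amplitude"`` draws amplitude-scale pixels as
        mean * Rayleigh normalized to unit mean.
    static_speckle
        Power fraction (0..1) of the speckle field that is frozen in time:
        stationary scatterers produce a speckle pattern shared by all
        A-Scans, and only the remaining fraction decorrelates from column to
        column.  The per-pixel marginal is unchanged.  0 gives fully
        independent columns; the default 0.5 leaves enough shared texture
        for cross-correlation motion correction to lock onto.
    motion_jitter_px
        Bound on the integer random-walk axial shift (circular per-column
        row shift), so motion correction can invert it exactly.  0 disables
        jitter.  The walk takes a +/-1-row step with probability
        ``motion_step_prob`` per column: bulk axial motion (breathing,
        pulse, tremor) is slow compared to the A-Scan rate, so steps are
        sparse.
    """

    depth_px: int = 600
    ascan_rate: float = 70_000.0
    duration: float = 0.3
    pulse_rate: float = 100.0
    n_pulses: int = 30
    lead_in_s: float = 0.02
    rpe_center_row: int | None = None
    rpe_band_halfwidth: int | None = None
    layer_profile: np.ndarray | None = None
    speckle_model: str = "exponential-intensity"
    static_speckle: float = 0.5
    burst_amplitude: float = 2.0
    burst_duration: float = 0.003
    burst_rows: tuple[int, int] | None = None
    burst_pulses: int | None = None
    motion_jitter_px: int = 0
    motion_step_prob: float = 0.005
    trace_sample_rate: float = 1e6
    pulse_width_s: float = 250e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_px < 2:
            raise ValueError("depth_px must be >= 2")
        if self.burst_amplitude < 0:
            raise ValueError("burst_amplitude must be >= 0")
        if self.motion_jitter_px < 0:
            raise ValueError("motion_jitter_px must be >= 0")
        if self.speckle_model not in ("exponential-intensity", "rayleigh-amplitude"):
            raise ValueError(f"unknown speckle_model {self.speckle_model!r}")
        if not 0.0 <= self.static_speckle <= 1.0:
            raise ValueError("static_speckle must lie in [0, 1]")
        if self.n_pulses / self.pulse_rate > self.duration + 1e-12:
            raise ValueError(
                f"{self.n_pulses} pulses at {self.pulse_rate} Hz do not fit in "
                f"a {self.duration} s train window")
        if self.rpe_center_row is None:
            self.rpe_center_row = self.depth_px // 2
        if self.rpe_band_halfwidth is None:
            self.rpe_band_halfwidth = max(3, self.depth_px // 75)
        if self.burst_rows is None:
            hw = 4 * self.rpe_band_halfwidth
            self.burst_rows = (self.rpe_center_row - hw, self.rpe_center_row + hw)
        lo, hi = self.burst_rows
        if not (0 <= lo < hi <= self.depth_px):
            raise ValueError(
                f"burst_rows {self.burst_rows} outside depth range [0, {self.depth_px})")
        if not (0 <= self.rpe_center_row < self.depth_px):
            raise ValueError("rpe_center_row outside depth range")

    @property
    def n_columns(self) -> int:
        """Total raster width: lead-in plus the pulse-train window."""
        return int(round((self.lead_in_s + self.duration) * self.ascan_rate))

    @property
    def label(self) -> int:
        return int(self.burst_amplitude > 0)

    def pulse_onset_times(self) -> np.ndarray:
        """Pulse onset times in seconds from the start of the recording."""
        return self.lead_in_s + np.arange(self.n_pulses) / self.pulse_rate

    def default_layer_profile(self) -> np.ndarray:
        """Mean reflectivity per depth row: background, inner layers, RPE.

        A smooth low-reflectivity retina with a few broad inner bands and one
        dominant Gaussian band at the RPE (the brightest reflector, ~20x the
        background), which is what the RPE locator relies on.
        """
        rows = np.arange(self.depth_px, dtype=np.float64)
        profile = np.full(self.depth_px, 5.0)
        c, hw = self.rpe_center_row, self.rpe_band_halfwidth
        # inner retinal layers: broad, dimmer bands above the RPE
        for offset, amp, width in ((-0.45, 6.0, 0.08), (-0.25, 9.0, 0.05), (-0.12, 7.0, 0.04)):
            profile += amp * np.exp(-0.5 * ((rows - (c + offset * self.depth_px))
                                            / (width * self.depth_px)) ** 2)
        profile += 100.0 * np.exp(-0.5 * ((rows - c) / hw) ** 2)
        return profile


@dataclass
class SimulatedSample:
    """One simulated acquisition: raster, photodetector trace, outcome label.

    ``truth`` snapshots the generating configuration (including the injected
    motion jitter) so tests can compare recovered quantities to ground truth.
    """

    mscan: MScan
    trace: PulseTrace
    label: int
    truth: SimulationConfig
    jitter: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


def _speckle(rng: np.random.Generator, profile: np.ndarray, n_cols: int,
             model: str, static_fraction: float) -> np.ndarray:
    """Speckle raster: fully developed speckle with a frozen component.

    The underlying complex field mixes a per-row static pattern (power
    fraction ``static_fraction``) with per-pixel dynamic noise, so |g|^2 is
    Exp(1) marginally while columns share the static texture.
    """
    shape = (profile.size, n_cols)
    a, b = np.sqrt(static_fraction), np.sqrt(1.0 - static_fraction)
    re0, im0 = rng.standard_normal((2, profile.size, 1))
    re, im = rng.standard_normal((2,) + shape)
    power = 0.5 * ((a * re0 + b * re) ** 2 + (a * im0 + b * im) ** 2)
    if model == "exponential-intensity":
        return profile[:, None] * power
    # amplitude-scale raster: Rayleigh magnitude normalized to unit mean
    return profile[:, None] * np.sqrt(power) * (2.0 / np.sqrt(np.pi))


def simulate_mscan(config: SimulationConfig) -> SimulatedSample:
    """Generate one M-Scan, its photodetector trace and its outcome label.

    Positive samples (``burst_amplitude > 0``) carry a multiplicative
    high-frequency burst in ``burst_rows`` for ``burst_duration`` after each
    pulse onset; the burst factor ``1 + a*|N(0,1)|`` raises both the mean and
    the variance of the affected pixels, mimicking the hyper-reflective,
    rapidly decorrelating microbubble signal.  Two calls with the same config
    (same seed) return bit-identical rasters.
    """
    rng = np.random.default_rng(config.seed)
    profile = (np.asarray(config.layer_profile, dtype=np.float64)
               if config.layer_profile is not None else config.default_layer_profile())
    if profile.size != config.depth_px:
        raise ValueError("layer_profile length must equal depth_px")

    n_cols = config.n_columns
    raster = _speckle(rng, profile, n_cols, config.speckle_model,
                      config.static_speckle)

    onsets = config.pulse_onset_times()
    if config.burst_amplitude > 0:
        lo, hi = config.burst_rows
        burst_cols = max(1, int(round(config.burst_duration * config.ascan_rate)))
        n_burst = config.n_pulses if config.burst_pulses is None else min(
            config.burst_pulses, config.n_pulses)
        for t0 in onsets[:n_burst]:
            c0 = int(round(t0 * config.ascan_rate))
            c1 = min(c0 + burst_cols, n_cols)
            mod = 1.0 + config.burst_amplitude * np.abs(
                rng.standard_normal((hi - lo, c1 - c0)))
            raster[lo:hi, c0:c1] *= mod

    jitter = np.zeros(n_cols, dtype=np.int64)
    if config.motion_jitter_px > 0:
        steps = (rng.choice([-1, 1], size=n_cols)
                 * (rng.random(n_cols) < config.motion_step_prob))
        steps[0] = 0
        jitter = np.clip(np.cumsum(steps), -config.motion_jitter_px,
                         config.motion_jitter_px)
        # circular per-column shift, exactly invertible by motion correction
        rows = np.arange(config.depth_px)[:, None]
        raster = raster[(rows - jitter[None, :]) % config.depth_px,
                        np.arange(n_cols)[None, :]]

    n_trace = int(round((config.lead_in_s + config.duration) * config.trace_sample_rate))
    trace = 0.01 * rng.standard_normal(n_trace)
    width = max(1, int(round(config.pulse_width_s * config.trace_sample_rate)))
    for t0 in onsets:
        s0 = int(round(t0 * config.trace_sample_rate))
        trace[s0:s0 + width] += 1.0

    mscan = MScan(data=raster.astype(np.float32), ascan_rate=config.ascan_rate,
                  id=f"sim-{config.seed}")
    return SimulatedSample(
        mscan=mscan,
        trace=PulseTrace(samples=trace, sample_rate=config.trace_sample_rate,
                         id=f"sim-{config.seed}"),
        label=config.label,
        truth=config,
        jitter=jitter,
    )


def _child_seeds(master_seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(master_seed)
    return np.array([s.generate_state(1)[0] % (2**31) for s in ss.spawn(n)])


def iter_dataset(n_pos: int, n_neg: int, config: SimulationConfig | None = None,
                 seed: int = 0):
    """Yield ``n_pos`` positive then ``n_neg`` negative simulated samples.

    Per-sample seeds are derived deterministically from ``seed``; negatives
    are the same configuration with ``burst_amplitude`` forced to 0.  Use this
    generator form when rasters should not all be held in memory at once.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("sample counts must be >= 0")
    if config is None:
        config = SimulationConfig()
    if n_pos > 0 and config.burst_amplitude <= 0:
        raise ValueError("positive samples require burst_amplitude > 0")
    seeds = _child_seeds(seed, n_pos + n_neg)
    for i, s in enumerate(seeds):
        amp = config.burst_amplitude if i < n_pos else 0.0
        cfg = replace(config, burst_amplitude=amp, seed=int(s))
        sample = simulate_mscan(cfg)
        sample.mscan.id = f"sim-{i:03d}-s{s}"
        sample.trace.id = sample.mscan.id
        yield sample


def simulate_dataset(n_pos: int, n_neg: int, config: SimulationConfig | None = None,
                     seed: int = 0) -> list[SimulatedSample]:
    """Materialized form of :func:`iter_dataset`."""
    return list(iter_dataset(n_pos, n_neg, config, seed))


def write_dataset(samples, out_dir: str | Path) -> Path:
    """Write samples to ``out_dir`` and return the manifest CSV path.

    Manifest columns: path, trace_path, label, seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in samples:
        raster_path = out_dir / f"{sample.mscan.id}.tif"
        trace_path = out_dir / f"{sample.mscan.id}.trace.csv"
        write_mscan(sample.mscan, raster_path)
        write_trace(sample.trace, trace_path)
        rows.append({"path": raster_path.name, "trace_path": trace_path.name,
                     "label": sample.label, "seed": sample.truth.seed})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
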