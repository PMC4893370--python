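"""Preprocessing of M-Scans: axial motion correction, laser-pulse detection
from the photodetector trace, cropping to the pulse-train window, and
temporal subsetting for early/late-signal analysis.

All operations are pure slicing/shifting of intensities — no resampling, no
filtering — so they are lossless and, for the circular motion correction,
exactly invertible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import MScan, PulseTrace

__all__ = ["PulseTrain", "correct_axial_motion", "detect_pulses",
           "crop_to_pulse_train", "temporal_subset", "SEGMENTS"]

logger = logging.getLogger(__name__)

SEGMENTS = ("start", "middle", "end", "start+middle")


@dataclass
class PulseTrain:
    """Detected laser-pulse onsets, in M-Scan columns and in seconds.

    Onsets are strictly increasing; for a nominal train the spacing between
    successive onsets is one pulse period (A-Scan rate / pulse rate) within
    about 10%.
    """

    onsets_columns: np.ndarray
    onsets_seconds: np.ndarray
    pulse_rate: float

    def __post_init__(self) -> None:
        cols = np.asarray(self.onsets_columns, dtype=np.int64)
        if cols.size == 0:
            raise ValueError("pulse train has no onsets")
        if cols.size > 1 and not (np.diff(cols) > 0).all():
            raise ValueError("pulse onsets must be strictly increasing")
        self.onsets_columns = cols
        self.onsets_seconds = np.asarray(self.onsets_seconds, dtype=np.float64)

    @property
    def n_pulses(self) -> int:
        return int(self.onsets_columns.size)

    @property
    def period_columns(self) -> int:
        """Median spacing between onsets, in columns."""
        if self.n_pulses < 2:
            raise ValueError("need >= 2 onsets to estimate the period")
        return int(round(float(np.median(np.diff(self.onsets_columns)))))

    def shifted(self, offset_columns: int, ascan_rate: float) -> "PulseTrain":
        """Re-index onsets into a frame whose column 0 is ``offset_columns``."""
        cols = self.onsets_columns - offset_columns
        return PulseTrain(onsets_columns=cols, onsets_seconds=cols / ascan_rate,
                          pulse_rate=self.pulse_rate)


def correct_axial_motion(mscan: MScan, reference_column: int = 0,
                         max_lag: int | None = None,
                         smooth_window: int = 9) -> tuple[MScan, np.ndarray]:
    """Align every A-Scan to a reference A-Scan by circular cross-correlation.

    For each column the circular lag (bounded to ``max_lag``, default L/4)
    maximizing its cross-correlation with the reference column is found, and
    the column is rolled by the negated lag.  A column identical to the
    reference shifted down by k therefore receives shift -k; the returned
    vector holds the applied shifts (reference column: 0).  Correlation is
    computed on mean-subtracted log-scale A-Scans (log compresses the
    heavy-tailed speckle so every depth row contributes, instead of a few
    bright RPE rows dominating).  Because axial motion is slow compared to
    the A-Scan rate, per-column lag estimates are median-filtered over
    ``smooth_window`` columns to suppress isolated speckle-induced outliers
    (1 disables).  Columns that are all zero have undefined correlation;
    their shift is set to 0 with a warning.

    Returns the corrected scan and the applied per-column shifts.
    """
    L, T = mscan.data.shape
    if not 0 <= reference_column < T:
        raise ValueError(f"reference_column {reference_column} outside [0, {T})")
    if max_lag is None:
        max_lag = L // 4
    max_lag = min(max_lag, (L - 1) // 2)

    zero_cols = ~mscan.data.any(axis=0)
    if zero_cols.any():
        logger.warning("%d all-zero columns: motion shift undefined, set to 0",
                       int(zero_cols.sum()))
    data = np.log1p(mscan.data.astype(np.float64))
    ref = data[:, reference_column] - data[:, reference_column].mean()
    cols = data - data.mean(axis=0, keepdims=True)

    # circular cross-correlation via FFT: C[s, t] = sum_l col[l, t] * ref[(l - s) mod L]
    F = np.fft.rfft(cols, axis=0)
    C = np.fft.irfft(F * np.conj(np.fft.rfft(ref))[:, None], n=L, axis=0)

    allowed = np.r_[0:max_lag + 1, L - max_lag:L] if max_lag > 0 else np.array([0])
    best = allowed[np.argmax(C[allowed, :], axis=0)]
    lags = np.where(best > L // 2, best - L, best).astype(np.int64)
    lags[zero_cols] = 0
    if smooth_window > 1 and T > 1:
        lags = ndimage.median_filter(lags, size=min(smooth_window, T), mode="nearest")
    lags[reference_column] = 0

    rows = np.arange(L)[:, None]
    corrected = mscan.data[(rows + lags[None, :]) % L, np.arange(T)[None, :]]
    return mscan.with_data(corrected), -lags


def detect_pulses(trace: PulseTrace, ascan_rate: float,
                  expected_n_pulses: int | None = None,
                  hysteresis_fraction: float = 0.1) -> PulseTrain:
    """Locate laser-pulse onsets in the photodetector trace.

    Onsets are rising-edge crossings of the midpoint between the trace
    minimum and maximum, with a hysteresis band of ``hysteresis_fraction`` of
    the range: after an onset, the signal must fall below the lower band edge
    before another onset can fire.  Onset times are mapped to M-Scan columns
    via ``round(time * ascan_rate)``.
    """
    s = trace.samples
    lo_v, hi_v = float(s.min()), float(s.max())
    rng = hi_v - lo_v
    mid = 0.5 * (lo_v + hi_v)
    high = mid + 0.5 * hysteresis_fraction * rng
    low = mid - 0.5 * hysteresis_fraction * rng

    if rng <= 0:
        raise ValueError("flat photodetector trace: no pulses found")
    candidates = np.flatnonzero((s[1:] > high) & (s[:-1] <= high)) + 1
    onsets = []
    last = None
    for idx in candidates:
        if last is None or s[last:idx].min() < low:
            onsets.append(int(idx))
            last = idx
    if not onsets:
        raise ValueError("no pulses found in photodetector trace")
    onsets = np.asarray(onsets, dtype=np.int64)
    if expected_n_pulses is not None and onsets.size != expected_n_pulses:
        logger.warning("detected %d pulses, expected %d", onsets.size, expected_n_pulses)

    times = onsets / trace.sample_rate
    if onsets.size > 1:
        pulse_rate = 1.0 / float(np.median(np.diff(times)))
    else:
        pulse_rate = float("nan")
    cols = np.round(times * ascan_rate).astype(np.int64)
    return PulseTrain(onsets_columns=cols, onsets_seconds=times, pulse_rate=pulse_rate)


def crop_to_pulse_train(mscan: MScan, pulses: PulseTrain, duration_s: float = 0.3,
                        pre_margin: int = 353) -> tuple[MScan, PulseTrain]:
    """Crop the scan to the pulse-train window plus a pre-train margin.

    The window spans ``pre_margin`` columns before the first onset (kept for
    the laser-free reference block) followed by ``round(duration_s *
    ascan_rate)`` columns of pulse train, so a 70 kHz scan cropped to a
    300 ms train yields 21000 train columns after the margin.  If the scan
    ends before the window does, the crop is clipped with a warning.  Pure
    slicing: intensities are preserved; onsets are re-indexed to the cropped
    frame (first onset lands at column ``pre_margin``).  Cropping an
    already-cropped scan with the same parameters is the identity.
    """
    if pre_margin < 0:
        raise ValueError("pre_margin must be >= 0")
    first = int(pulses.onsets_columns[0])
    start = first - pre_margin
    if start < 0:
        raise ValueError(
            f"first pulse onset at column {first} leaves no room for a "
            f"{pre_margin}-column pre-train margin; use pre_margin <= {first}")
    end = first + int(round(duration_s * mscan.ascan_rate))
    if end > mscan.n_time:
        logger.warning("pulse-train window extends past the scan end "
                       "(%d > %d); clipping", end, mscan.n_time)
        end = mscan.n_time
    cropped = mscan.with_data(mscan.data[:, start:end])
    return cropped, pulses.shifted(start, mscan.ascan_rate)


def segment_column_range(pulses: PulseTrain, ascan_rate: float, segment: str,
                         segment_s: float = 0.1) -> tuple[int, int]:
    """Column range of a temporal segment of the pulse-train window.

    The train window (from the first onset) is divided into three
    ``segment_s`` pieces: "start", "middle", "end"; "start+middle" is their
    first two combined.  The three 100 ms ranges partition the 300 ms train
    window exactly.
    """
    if segment not in SEGMENTS:
        raise ValueError(f"segment must be one of {SEGMENTS}, got {segment!r}")
    first = int(pulses.onsets_columns[0])
    w = int(round(segment_s * ascan_rate))
    index = {"start": (0, 1), "middle": (1, 2), "end": (2, 3), "start+middle": (0, 2)}[segment]
    return first + index[0] * w, first + index[1] * w


def temporal_subset(mscan: MScan, pulses: PulseTrain, segment: str,
                    pre_margin: int = 353, segment_s: float = 0.1
                    ) -> tuple[MScan, PulseTrain]:
    """Extract one temporal segment of a cropped scan, with its own margin.

    Returns the segment's sub-raster prefixed by ``pre_margin`` columns (the
    reference-block margin immediately preceding the segment's first pulse)
    and the pulses falling inside the segment, re-indexed to the sub-raster.
    """
    c0, c1 = segment_column_range(pulses, mscan.ascan_rate, segment, segment_s)
    if c1 > mscan.n_time:
        raise ValueError(f"segment {segment!r} columns [{c0}, {c1}) exceed scan "
                         f"width {mscan.n_time}")
    mask = (pulses.onsets_columns >= c0) & (pulses.onsets_columns < c1)
    if not mask.any():
        raise ValueError(f"segment {segment!r} contains no pulse onsets")
    start = c0 - pre_margin
    if start < 0:
        raise ValueError(f"segment {segment!r} leaves no room for a "
                         f"{pre_margin}-column margin")
    sub = mscan.with_data(mscan.data[:, start:c1], id_suffix=f"[{segment}]")
    seg_pulses = PulseTrain(
        onsets_columns=pulses.onsets_columns[mask] - start,
        onsets_seconds=(pulses.onsets_columns[mask] - start) / mscan.ascan_rate,
        pulse_rate=pulses.pulse_rate)
    return sub, seg_pulses
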