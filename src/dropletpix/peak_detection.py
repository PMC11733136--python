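"""Streaming peak detection with a drift-free adaptive baseline.

The detector keeps a moving average of the most recent samples that were
classified as baseline; samples inside an open peak are deliberately kept
out of that average so a train of pulses cannot drag the baseline upward.
A peak opens when the signal exceeds ``baseline + k * SD`` over the moving
window and closes when the signal drops back below that same threshold.
Peaks that fall within a configurable group time are assembled into one
per-droplet signature (ordered per-laser magnitudes).

The detector is a true streaming state machine: feeding a trace in chunks
of any size yields byte-identical results to a single pass.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np

from .synthetic_data import DropletRecord
from .trace import Trace

__all__ = [
    "DetectorConfig",
    "Peak",
    "DropletSignature",
    "PeakDetector",
    "detect_peaks",
    "group_peaks",
    "detector_score",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tuning knobs for the streaming detector.

    ``threshold_multiple`` is the unitless ``k`` in
    ``threshold = baseline + k * SD``; the SD is taken over the samples in
    the moving baseline window (set ``sd_of_mean=True`` to use the standard
    error of the window mean instead).
    """

    baseline_window: int = 200
    threshold_multiple: float = 5.0
    group_time: float = 0.005
    min_peak_samples: int = 2
    expected_peaks_per_droplet: int = 3
    sd_of_mean: bool = False
    # debounce: consecutive below-threshold samples required to close a
    # peak; 1 closes on the first return below threshold
    min_below_to_close: int = 1
    # ablation switch: include in-peak samples in the baseline average.
    # Exists only so drift immunity can be demonstrated against its absence.
    include_peaks_in_baseline: bool = False

    def __post_init__(self) -> None:
        if self.baseline_window < 2:
            raise ValueError("baseline_window must be >= 2")
        if self.threshold_multiple <= 0:
            raise ValueError("threshold_multiple must be > 0")
        if self.group_time <= 0:
            raise ValueError("group_time must be > 0")
        if self.min_peak_samples < 1:
            raise ValueError("min_peak_samples must be >= 1")
        if self.min_below_to_close < 1:
            raise ValueError("min_below_to_close must be >= 1")
        if self.expected_peaks_per_droplet not in (1, 3):
            raise ValueError("expected_peaks_per_droplet must be 1 or 3")


@dataclass(frozen=True)
class Peak:
    """One detected threshold crossing."""

    start_time: float
    end_time: float
    magnitude: float
    baseline_at_entry: float

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("peak end_time must exceed start_time")
        if self.magnitude <= 0:
            raise ValueError("peak magnitude must be > 0")


@dataclass(frozen=True)
class DropletSignature:
    """Ordered per-laser peak magnitudes for one droplet transit.

    ``droplet_time`` is the start of the first peak in the group.  When
    fewer than the expected number of peaks were found the missing channels
    are zero-padded and ``complete`` is False.
    """

    droplet_time: float
    magnitudes: tuple[float, ...]
    complete: bool

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.magnitudes):
            raise ValueError("signature magnitudes must be >= 0")


class PeakDetector:
    """Incremental peak detector over a uniformly sampled stream.

    Feed samples with :meth:`process`; call :meth:`finalize` at end of
    stream to flush a still-open peak.  The first ``baseline_window``
    samples are unconditionally treated as baseline (warm-up), so no peak
    can open before the moving average is populated.
    """

    def __init__(self, cfg: DetectorConfig, dt: float) -> None:
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.cfg = cfg
        self.dt = dt
        self._window: deque[float] = deque(maxlen=cfg.baseline_window)
        self._sum = 0.0
        self._sumsq = 0.0
        self._n_seen = 0
        self._in_peak = False
        self._peak_start = 0.0
        self._peak_max = -np.inf
        self._peak_samples = 0
        self._peak_baseline = 0.0
        self._peak_threshold = 0.0
        self._below_count = 0
        self._below_since = 0.0
        self._last_time = 0.0
        self.peaks: list[Peak] = []

    # -- baseline bookkeeping ------------------------------------------------

    def _push_baseline(self, value: float) -> None:
        if len(self._window) == self._window.maxlen:
            old = self._window[0]
            self._sum -= old
            self._sumsq -= old * old
        self._window.append(value)
        self._sum += value
        self._sumsq += value * value

    @property
    def baseline(self) -> float:
        """Current moving-average baseline estimate."""
        if not self._window:
            return 0.0
        return self._sum / len(self._window)

    @property
    def baseline_sd(self) -> float:
        n = len(self._window)
        if n < 2:
            return 0.0
        mean = self._sum / n
        var = max(self._sumsq / n - mean * mean, 0.0)
        sd = sqrt(var)
        if self.cfg.sd_of_mean:
            sd /= sqrt(n)
        return sd

    @property
    def threshold(self) -> float:
        return self.baseline + self.cfg.threshold_multiple * self.baseline_sd

    # -- streaming interface -------------------------------------------------

    def process(self, times: Sequence[float], values: Sequence[float]) -> None:
        """Consume the next chunk of the stream (chunk size is arbitrary)."""
        cfg = self.cfg
        for t, v in zip(times, values):
            self._last_time = t
            if self._n_seen < cfg.baseline_window:
                # warm-up: unconditionally baseline
                self._push_baseline(v)
                self._n_seen += 1
                continue
            self._n_seen += 1
            if self._in_peak:
                # threshold frozen at entry; baseline window untouched unless
                # the ablation switch is set
                if cfg.include_peaks_in_baseline:
                    self._push_baseline(v)
                if v > self._peak_max:
                    self._peak_max = v
                self._peak_samples += 1
                if v <= self._peak_threshold:
                    if self._below_count == 0:
                        self._below_since = t
                    self._below_count += 1
                    if self._below_count >= cfg.min_below_to_close:
                        self._close_peak(self._below_since)
                else:
                    self._below_count = 0
                continue
            if v > self.threshold:
                self._in_peak = True
                self._peak_start = t
                self._peak_max = v
                self._peak_samples = 1
                self._peak_baseline = self.baseline
                self._peak_threshold = self.threshold
                self._below_count = 0
                if cfg.include_peaks_in_baseline:
                    self._push_baseline(v)
            else:
                self._push_baseline(v)

    def _close_peak(self, end_time: float) -> None:
        self._in_peak = False
        if self._peak_samples >= self.cfg.min_peak_samples:
            magnitude = self._peak_max - self._peak_baseline
            if magnitude > 0:
                self.peaks.append(
                    Peak(self._peak_start, end_time, magnitude, self._peak_baseline)
                )

    def finalize(self) -> list[Peak]:
        """Close any open peak at the last sample and return all peaks."""
        if self._in_peak:
            # end-of-stream: close at the last seen sample
            end = self._last_time
            if end <= self._peak_start:
                end = self._peak_start + self.dt
            self._close_peak(end)
        return self.peaks


def detect_peaks(trace: Trace, cfg: DetectorConfig) -> list[Peak]:
    """Run the streaming detector over a whole trace in one pass."""
    if trace.n_samples <= cfg.baseline_window:
        raise ValueError(
            f"trace has {trace.n_samples} samples; need more than the "
            f"baseline window ({cfg.baseline_window}) to warm up"
        )
    trace.require_uniform()
    det = PeakDetector(cfg, trace.dt)
    det.process(trace.time, trace.signal)
    return det.finalize()


def group_peaks(peaks: Sequence[Peak], cfg: DetectorConfig) -> list[DropletSignature]:
    """Greedily group peaks into per-droplet signatures.

    A group opens at the first ungrouped peak and absorbs every following
    peak whose start time lies within ``group_time`` of the group's first
    peak start.  Groups with a peak count different from
    ``expected_peaks_per_droplet`` are flagged incomplete; missing channels
    are zero-padded, surplus peaks beyond the expected count are dropped.
    """
    expected = cfg.expected_peaks_per_droplet
    signatures: list[DropletSignature] = []
    ordered = sorted(peaks, key=lambda p: p.start_time)
    i = 0
    while i < len(ordered):
        first = ordered[i]
        group = [first]
        j = i + 1
        while j < len(ordered) and ordered[j].start_time - first.start_time <= cfg.group_time:
            group.append(ordered[j])
            j += 1
        mags = [p.magnitude for p in group[:expected]]
        complete = len(group) == expected
        while len(mags) < expected:
            mags.append(0.0)
        signatures.append(DropletSignature(first.start_time, tuple(mags), complete))
        i = j
    return signatures


def detector_score(
    signatures: Sequence[DropletSignature],
    ground_truth: Sequence[DropletRecord],
    group_time: float,
) -> tuple[float, float, float]:
    """Score detected signatures against generator ground truth.

    A signature matches a true droplet when its droplet time lies within
    ``group_time`` of the droplet's first pulse time; matching is greedy
    one-to-one in time order.  Returns ``(recall, precision,
    magnitude_rmse)`` where the RMSE is over the channels of matched
    complete signatures (NaN when nothing matched).
    """
    sigs = sorted(signatures, key=lambda s: s.droplet_time)
    truth = sorted(ground_truth, key=lambda r: r.start_time)
    matches: list[tuple[DropletSignature, DropletRecord]] = []
    ti = 0
    for sig in sigs:
        while ti < len(truth) and truth[ti].start_time < sig.droplet_time - group_time:
            ti += 1
        if ti < len(truth) and abs(truth[ti].start_time - sig.droplet_time) <= group_time:
            matches.append((sig, truth[ti]))
            ti += 1
    recall = len(matches) / len(truth) if truth else 1.0
    precision = len(matches) / len(sigs) if sigs else (1.0 if not truth else 0.0)
    errs = [
        m - h
        for sig, rec in matches
        if sig.complete
        for m, h in zip(sig.magnitudes, rec.pulse_heights)
    ]
    rmse = float(np.sqrt(np.mean(np.square(errs)))) if errs else float("nan")
    return recall, precision, rmse
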