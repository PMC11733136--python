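"""Synthetic photodetector signals and droplet populations.

Everything the downstream modules would normally receive from hardware is
generated here: raw voltage traces with pulses riding on a noisy (optionally
drifting) baseline, and mixed multi-group droplet populations in which each
droplet transit produces three pulses — one per laser excitation point —
collected on a single detector stream.  All generators are deterministic
given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trace import Trace

__all__ = [
    "Pulse",
    "TraceSpec",
    "GroupSpec",
    "PopulationSpec",
    "DropletRecord",
    "make_trace",
    "make_population_traces",
    "make_stream_trace",
]

PULSES_PER_DROPLET = 3  # one pulse per laser excitation point


@dataclass(frozen=True)
class Pulse:
    """One Gaussian pulse: ``height * exp(-(t - center)^2 / (2 width_sd^2))``."""

    center_time: float
    height: float
    width_sd: float

    def __post_init__(self) -> None:
        if self.width_sd <= 0:
            raise ValueError(f"pulse width_sd must be > 0, got {self.width_sd}")


@dataclass(frozen=True)
class TraceSpec:
    """Recipe for one synthetic voltage trace.

    The generated signal is
    ``baseline_level + baseline_drift_rate * t + N(0, noise_sd) + sum(pulses)``
    sampled at ``sample_rate`` for ``duration`` seconds.
    """

    sample_rate: float
    duration: float
    baseline_level: float = 0.0
    baseline_drift_rate: float = 0.0
    noise_sd: float = 0.0
    pulses: tuple[Pulse, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        pulses = tuple(
            p if isinstance(p, Pulse) else Pulse(*p) for p in self.pulses
        )
        object.__setattr__(self, "pulses", pulses)

    def baseline_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Noise-free, pulse-free baseline value(s) at time ``t``."""
        return self.baseline_level + self.baseline_drift_rate * np.asarray(t)


@dataclass(frozen=True)
class GroupSpec:
    """One droplet population group: per-channel mean pulse heights and CV."""

    mean_magnitudes: tuple[float, float, float]
    cv: float = 0.0

    def __post_init__(self) -> None:
        mags = tuple(float(m) for m in self.mean_magnitudes)
        if len(mags) != PULSES_PER_DROPLET:
            raise ValueError(
                f"mean_magnitudes must have {PULSES_PER_DROPLET} entries"
            )
        if any(m < 0 for m in mags):
            raise ValueError(f"group means must be non-negative, got {mags}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        object.__setattr__(self, "mean_magnitudes", mags)


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a mixed droplet population collected on one stream.

    Each droplet contributes exactly three pulses separated by
    ``transit_spacing``; consecutive droplets start ``inter_droplet_gap``
    apart.  ``transit_spacing`` must be strictly smaller than
    ``inter_droplet_gap`` so the three pulses of one droplet can be grouped
    before the next droplet arrives.
    """

    groups: tuple[GroupSpec, ...]
    droplets_per_group: int
    transit_spacing: float
    inter_droplet_gap: float
    sample_rate: float = 10_000.0
    baseline_level: float = 0.1
    baseline_drift_rate: float = 0.0
    noise_sd: float = 0.01
    pulse_width_sd: float = 4e-4
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        groups = tuple(
            g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in self.groups
        )
        object.__setattr__(self, "groups", groups)
        if self.droplets_per_group < 0:
            raise ValueError("droplets_per_group must be >= 0")
        if self.transit_spacing <= 0:
            raise ValueError("transit_spacing must be > 0")
        if self.transit_spacing >= self.inter_droplet_gap:
            raise ValueError(
                "transit_spacing must be < inter_droplet_gap "
                f"({self.transit_spacing} >= {self.inter_droplet_gap}); "
                "droplet peak groups would be inseparable"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pulse_width_sd <= 0:
            raise ValueError("pulse_width_sd must be > 0")

    @property
    def n_droplets(self) -> int:
        return len(self.groups) * self.droplets_per_group


@dataclass(frozen=True)
class DropletRecord:
    """Ground truth for one generated droplet."""

    droplet_id: int
    group_id: int
    pulse_times: tuple[float, float, float]
    pulse_heights: tuple[float, float, float]

    @property
    def start_time(self) -> float:
        return self.pulse_times[0]


def make_trace(spec: TraceSpec) -> Trace:
    """Render a :class:`TraceSpec` into a sampled trace.

    Deterministic: equal specs (including seed) produce bit-identical traces.
    """
    n = int(round(spec.sample_rate * spec.duration))
    if n < 1:
        raise ValueError("spec yields an empty trace")
    t = np.arange(n, dtype=float) / spec.sample_rate
    signal = np.full(n, float(spec.baseline_level))
    signal += spec.baseline_drift_rate * t
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signal += rng.normal(0.0, spec.noise_sd, size=n)
    for p in spec.pulses:
        # evaluate only within +/- 6 sigma; contribution beyond is < 2e-8
        lo = np.searchsorted(t, p.center_time - 6 * p.width_sd)
        hi = np.searchsorted(t, p.center_time + 6 * p.width_sd)
        window = t[lo:hi]
        signal[lo:hi] += p.height * np.exp(
            -0.5 * ((window - p.center_time) / p.width_sd) ** 2
        )
    return Trace(t, signal)


def make_population_traces(
    spec: PopulationSpec,
) -> tuple[Trace, list[DropletRecord]]:
    """Generate one concatenated trace for a mixed droplet population.

    Every droplet contributes exactly three pulses whose heights are drawn
    from its group's per-channel distribution (Gaussian, sd = cv * mean,
    clipped at zero).  Ground truth is returned for scoring detectors and
    classifiers.
    """
    rng = np.random.default_rng(spec.seed)
    group_ids = np.repeat(np.arange(len(spec.groups)), spec.droplets_per_group)
    if spec.shuffle:
        rng.shuffle(group_ids)
    return make_stream_trace(spec, group_ids)


def make_stream_trace(
    spec: PopulationSpec, group_sequence: Sequence[int]
) -> tuple[Trace, list[DropletRecord]]:
    """Generate a trace for an explicit droplet arrival sequence.

    ``group_sequence[i]`` is the group of the i-th arriving droplet;
    timing, noise, and height statistics come from ``spec``
    (``droplets_per_group`` is ignored on this path).
    """
    rng = np.random.default_rng(spec.seed)
    n_droplets = len(group_sequence)

    # lead-in before the first droplet gives the detector room to warm up
    lead_in = spec.inter_droplet_gap
    pulses: list[Pulse] = []
    records: list[DropletRecord] = []
    for droplet_id, gid in enumerate(group_sequence):
        group = spec.groups[gid]
        t0 = lead_in + droplet_id * spec.inter_droplet_gap
        times = tuple(t0 + i * spec.transit_spacing for i in range(PULSES_PER_DROPLET))
        heights = []
        for mean in group.mean_magnitudes:
            h = mean if group.cv == 0 else rng.normal(mean, group.cv * mean)
            heights.append(max(float(h), 0.0))
        heights = tuple(heights)
        for tc, h in zip(times, heights):
            pulses.append(Pulse(tc, h, spec.pulse_width_sd))
        records.append(DropletRecord(droplet_id, int(gid), times, heights))

    duration = lead_in + max(n_droplets, 1) * spec.inter_droplet_gap
    trace_spec = TraceSpec(
        sample_rate=spec.sample_rate,
        duration=duration,
        baseline_level=spec.baseline_level,
        baseline_drift_rate=spec.baseline_drift_rate,
        noise_sd=spec.noise_sd,
        pulses=tuple(pulses),
        # decorrelate the noise stream from the height draws above
        seed=spec.seed + 1,
    )
    return make_trace(trace_spec), records
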