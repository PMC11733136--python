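"""End-to-end stochastic stand-in for the droplet pixel-array hardware.

One run plays the full chain: a mixed droplet stream is generated as a
synthetic detector trace, sensed by the streaming peak detector, classified
onto the 8-color palette, sorted against an instruction list (the sorter
waits for the next needed color; everything else goes to waste), pushed
through the serpentine anchor FIFO, and read back out as a pixel grid.
Fault injection covers the three failure modes the hardware exhibits:
nonspecific selection, skipping an anchor, and double occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .classification import (
    PALETTE,
    ClassifierModel,
    classify,
    fit_thresholds,
)
from .peak_detection import (
    DetectorConfig,
    DropletSignature,
    detect_peaks,
    group_peaks,
)
from .pixel_compiler import AnchorArray, PixelGrid, replay_instructions
from .synthetic_data import GroupSpec, PopulationSpec, make_stream_trace

__all__ = [
    "WorkflowConfig",
    "DropletEvent",
    "Mismatch",
    "RunLog",
    "IncompleteRunError",
    "default_group_specs",
    "default_classifier",
    "run",
    "verify",
    "run_symbol_library",
]

# default low/high per-channel pulse magnitudes (volts) for the 8 groups
DEFAULT_LOW_V = 0.2
DEFAULT_HIGH_V = 1.2


def default_group_specs(
    low_v: float = DEFAULT_LOW_V, high_v: float = DEFAULT_HIGH_V, cv: float = 0.02
) -> tuple[GroupSpec, ...]:
    """One droplet group per palette color, ordered by palette index."""
    return tuple(
        GroupSpec(
            tuple(high_v if lvl else low_v for lvl in color.levels), cv=cv
        )
        for color in PALETTE
    )


def default_classifier(
    low_v: float = DEFAULT_LOW_V, high_v: float = DEFAULT_HIGH_V
) -> ClassifierModel:
    return fit_thresholds([low_v] * 3, [high_v] * 3)


@dataclass(frozen=True)
class WorkflowConfig:
    """Everything one simulated pixel-array run needs."""

    instructions: tuple[int, ...]
    grid_height: int = 5
    grid_width: int = 5
    group_specs: tuple[GroupSpec, ...] = field(default_factory=default_group_specs)
    classifier: ClassifierModel = field(default_factory=default_classifier)
    detector: DetectorConfig = field(
        default_factory=lambda: DetectorConfig(
            baseline_window=100, threshold_multiple=5.0, group_time=0.008
        )
    )
    sample_rate: float = 10_000.0
    baseline_level: float = 0.1
    noise_sd: float = 0.01
    pulse_width_sd: float = 3e-4
    transit_spacing: float = 0.003
    inter_droplet_gap: float = 0.015
    nonspecific_sort_prob: float = 0.0
    anchor_skip_prob: float = 0.0
    double_occupancy_prob: float = 0.0
    max_sort_rate: float = 80.0  # droplets/s, sorter throughput cap
    stream_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        instructions = tuple(int(i) for i in self.instructions)
        object.__setattr__(self, "instructions", instructions)
        if any(not 0 <= i < len(PALETTE) for i in instructions):
            raise ValueError("instructions must be palette indices 0-7")
        if len(instructions) > self.grid_height * self.grid_width:
            raise ValueError("more instructions than anchors")
        for name in ("nonspecific_sort_prob", "anchor_skip_prob",
                     "double_occupancy_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.max_sort_rate <= 0:
            raise ValueError("max_sort_rate must be > 0")

    @property
    def effective_stream_length(self) -> int:
        if self.stream_length is not None:
            return self.stream_length
        # ~ n_groups candidates per fulfilled instruction, plus slack
        return 16 * max(len(self.instructions), 1) + 64


@dataclass(frozen=True)
class DropletEvent:
    """One candidate droplet as seen by the sorter."""

    time: float
    true_group: Optional[int]          # ground truth; None for a false detection
    signature: DropletSignature
    color: Optional[int]               # classified palette index; None = unknown
    deflected: bool
    instruction_index: Optional[int]   # which instruction this sort fulfilled
    anchor_event: Optional[str]        # "anchored" | "skipped" | "double"
    sort_time: Optional[float]         # actuation time (rate-cap adjusted)


@dataclass(frozen=True)
class Mismatch:
    position: tuple[int, int]
    expected: int
    observed: int
    instruction_index: Optional[int]


@dataclass(frozen=True)
class RunLog:
    config: WorkflowConfig
    events: tuple[DropletEvent, ...]
    final_grid: PixelGrid
    target_grid: PixelGrid
    mismatches: tuple[Mismatch, ...]
    n_droplets_consumed: int

    @property
    def clean(self) -> bool:
        return not self.mismatches

    @property
    def sort_times(self) -> list[float]:
        return [e.sort_time for e in self.events if e.sort_time is not None]


class IncompleteRunError(RuntimeError):
    """Raised when the droplet stream runs out before the instructions do."""

    def __init__(self, fulfilled: int, total: int, consumed: int) -> None:
        super().__init__(
            f"droplet stream exhausted after {consumed} droplets with only "
            f"{fulfilled}/{total} instructions fulfilled"
        )
        self.fulfilled = fulfilled
        self.total = total
        self.consumed = consumed


def verify(grid: PixelGrid, target: PixelGrid) -> list[Mismatch]:
    """Cell-by-cell comparison; empty iff the grids are identical."""
    if (grid.height, grid.width) != (target.height, target.width):
        raise ValueError(
            f"grid {grid.height}x{grid.width} vs target "
            f"{target.height}x{target.width}: dimension mismatch"
        )
    out = []
    for r in range(grid.height):
        for c in range(grid.width):
            if grid.cells[r, c] != target.cells[r, c]:
                out.append(
                    Mismatch((r, c), int(target.cells[r, c]),
                             int(grid.cells[r, c]), None)
                )
    return out


def _sense_stream(
    config: WorkflowConfig, rng: np.random.Generator
) -> tuple[list[tuple[float, Optional[int], DropletSignature, Optional[int]]], int]:
    """Generate, detect, and classify one droplet stream.

    Returns (candidates, n_generated) where each candidate is
    (droplet_time, true_group, signature, classified_color).
    """
    n = config.effective_stream_length
    group_sequence = rng.integers(0, len(config.group_specs), size=n)
    spec = PopulationSpec(
        groups=config.group_specs,
        droplets_per_group=0,  # unused on the explicit-sequence path
        transit_spacing=config.transit_spacing,
        inter_droplet_gap=config.inter_droplet_gap,
        sample_rate=config.sample_rate,
        baseline_level=config.baseline_level,
        noise_sd=config.noise_sd,
        pulse_width_sd=config.pulse_width_sd,
        seed=int(rng.integers(0, 2**31)),
    )
    trace, truth = make_stream_trace(spec, group_sequence)
    peaks = detect_peaks(trace, config.detector)
    signatures = group_peaks(peaks, config.detector)

    # attach ground truth by time proximity (scoring metadata only; the
    # sorter itself never sees it)
    truth_times = np.array([r.start_time for r in truth])
    candidates = []
    for sig in signatures:
        true_group: Optional[int] = None
        if len(truth_times):
            i = int(np.argmin(np.abs(truth_times - sig.droplet_time)))
            if abs(truth_times[i] - sig.droplet_time) <= config.detector.group_time:
                true_group = truth[i].group_id
        color = classify(sig, config.classifier)
        candidates.append(
            (sig.droplet_time, true_group, sig,
             color.index if color is not None else None)
        )
    return candidates, n


def run(config: WorkflowConfig) -> RunLog:
    """Execute one simulated sort-and-anchor run against an instruction list.

    The sorter walks the stream in time order and deflects a droplet iff
    its classified color matches the next unfulfilled instruction (or a
    nonspecific-sort fault fires).  Deflected droplets pass to the anchor
    array, where skip and double-occupancy faults may corrupt the FIFO.
    """
    rng = np.random.default_rng(config.seed)
    candidates, n_generated = _sense_stream(config, rng)

    array = AnchorArray(
        n_anchors=config.grid_height * config.grid_width,
        height=config.grid_height,
        width=config.grid_width,
    )
    instructions = config.instructions
    pending = 0
    min_interval = 1.0 / config.max_sort_rate
    last_sort: Optional[float] = None
    events: list[DropletEvent] = []
    consumed = 0

    for droplet_time, true_group, sig, color in candidates:
        if pending >= len(instructions):
            break
        consumed += 1
        u_sort = rng.random()
        u_anchor = rng.random()
        wanted = instructions[pending]
        nonspecific = u_sort < config.nonspecific_sort_prob
        deflect = color is not None and (color == wanted or nonspecific)
        if not deflect:
            events.append(
                DropletEvent(droplet_time, true_group, sig, color,
                             False, None, None, None)
            )
            continue
        sort_time = droplet_time
        if last_sort is not None:
            sort_time = max(sort_time, last_sort + min_interval)
        last_sort = sort_time
        if u_anchor < config.anchor_skip_prob:
            anchor_event = "skipped"  # droplet misses the anchor chain entirely
        elif u_anchor < config.anchor_skip_prob + config.double_occupancy_prob and array.occupancy:
            # two droplets on one anchor: the newcomer shares (and visually
            # dominates) the entrance anchor instead of knocking the chain
            anchor_event = "double"
            array.occupancy[0] = (color, pending)
        else:
            anchor_event = "anchored"
            array.push((color, pending))
        events.append(
            DropletEvent(droplet_time, true_group, sig, color,
                         True, pending, anchor_event, sort_time)
        )
        pending += 1

    if pending < len(instructions):
        raise IncompleteRunError(pending, len(instructions), consumed)

    color_grid = array.to_grid(key=lambda d: d[0])
    # instruction index per cell (-1 for empty anchors); not a PixelGrid
    # because instruction indices exceed the palette range
    from .pixel_compiler import serpentine_map

    provenance = np.full((config.grid_height, config.grid_width), -1, dtype=np.int64)
    for pos0, (r, c) in enumerate(
        serpentine_map(config.grid_height, config.grid_width)
    ):
        if pos0 < len(array.occupancy):
            provenance[r, c] = array.occupancy[pos0][1]
    target = replay_instructions(
        list(instructions), config.grid_height, config.grid_width
    )
    final = (
        PixelGrid(color_grid.cells)
        if color_grid.cells.min() >= 0
        else color_grid
    )
    mismatches = [
        replace(
            m,
            instruction_index=(
                int(provenance[m.position]) if provenance[m.position] >= 0 else None
            ),
        )
        for m in verify(final, target)
    ]
    return RunLog(
        config=config,
        events=tuple(events),
        final_grid=final,
        target_grid=target,
        mismatches=tuple(mismatches),
        n_droplets_consumed=consumed,
    )


def run_symbol_library(
    symbols: dict[str, PixelGrid], config: WorkflowConfig
) -> dict[str, RunLog]:
    """One fault-free-style run per symbol pattern; all must verify clean.

    Each pattern must use a two-color sub-palette (black/white).  Raises
    an aggregate error naming every symbol whose run did not verify.
    """
    from .pixel_compiler import compile_instructions

    logs: dict[str, RunLog] = {}
    failed: list[str] = []
    for i, (name, grid) in enumerate(sorted(symbols.items())):
        used = set(np.unique(grid.cells))
        if len(used) > 2:
            raise ValueError(
                f"symbol {name!r} uses {len(used)} colors; expected a "
                "two-color sub-palette"
            )
        cfg = replace(
            config,
            instructions=tuple(compile_instructions(grid)),
            grid_height=grid.height,
            grid_width=grid.width,
            seed=config.seed + i,
        )
        log = run(cfg)
        logs[name] = log
        if not log.clean:
            failed.append(name)
    if failed:
        raise RuntimeError(
            f"{len(failed)} symbol(s) failed verification: {failed}"
        )
    return logs
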