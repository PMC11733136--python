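"""Empirically parameterized surrogates for the droplet hardware components.

Each model reproduces a characterized operating envelope: the droplet
generator's flow-to-(diameter, rate) response, Poisson single-cell loading,
the picoinjector's pressure-to-volume-change curve, the sorter's three
voltage/flow regimes, and the anchor trapping outcome bands.  Only the
printed envelope endpoints are empirical; the response surfaces between
them are calibrated monotone interpolants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GenerationEnvelope",
    "predict_generation",
    "poisson_pmf",
    "encapsulation_stats",
    "simulate_encapsulation",
    "od_to_cells",
    "OD_CONVERSION_FACTORS",
    "PicoinjectionModel",
    "picoinjection_volume_change",
    "SortingRegime",
    "SortingRegimeMap",
    "classify_sorting",
    "AnchorOutcome",
    "AnchorOutcomeModel",
    "anchor_outcome",
]


# --------------------------------------------------------------------------
# Droplet generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerationEnvelope:
    """Operating envelope of the droplet generator.

    The flow rectangle maps onto the diameter and rate ranges through
    power-law interpolants: both extremes of each output range are attained
    on the domain boundary and never exceeded.  Diameter decreases with oil
    flow and increases with water flow; rate increases with both.
    """

    oil_flow_range: tuple[float, float] = (4.16, 166.7)      # uL/min
    water_flow_range: tuple[float, float] = (0.2, 16.66)     # uL/min
    diameter_range: tuple[float, float] = (95.0, 176.0)      # um
    rate_range: tuple[float, float] = (4.0, 368.0)           # Hz
    diameter_exponent: float = 1.0
    rate_exponent: float = 1.0

    def __post_init__(self) -> None:
        for name in ("oil_flow_range", "water_flow_range",
                     "diameter_range", "rate_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lo < hi, got {(lo, hi)}")
        if self.diameter_exponent <= 0 or self.rate_exponent <= 0:
            raise ValueError("surrogate exponents must be > 0")


def _log_unit(x: float, lo: float, hi: float) -> float:
    return math.log(x / lo) / math.log(hi / lo)


def predict_generation(
    oil_flow: float, water_flow: float, env: GenerationEnvelope | None = None
) -> tuple[float, float]:
    """Predict (diameter um, rate Hz) for an in-envelope flow pair.

    Out-of-envelope flows raise with the violated bound named; outside the
    characterized rectangle the device either failed to make monodisperse
    droplets or broke outright, so no prediction is meaningful there.
    """
    env = env or GenerationEnvelope()
    o_lo, o_hi = env.oil_flow_range
    w_lo, w_hi = env.water_flow_range
    if not o_lo <= oil_flow <= o_hi:
        raise ValueError(
            f"oil_flow {oil_flow} uL/min outside envelope [{o_lo}, {o_hi}]"
        )
    if not w_lo <= water_flow <= w_hi:
        raise ValueError(
            f"water_flow {water_flow} uL/min outside envelope [{w_lo}, {w_hi}]"
        )
    u = _log_unit(oil_flow, o_lo, o_hi)     # 0 at min oil, 1 at max oil
    v = _log_unit(water_flow, w_lo, w_hi)   # 0 at min water, 1 at max water

    # diameter: largest at (min oil, max water), smallest at (max oil, min water)
    d_lo, d_hi = env.diameter_range
    td = (((1.0 - u) + v) / 2.0) ** env.diameter_exponent
    diameter = d_lo + (d_hi - d_lo) * td

    # rate: smallest at (min, min), largest at (max, max); log interpolation
    r_lo, r_hi = env.rate_range
    tr = ((u + v) / 2.0) ** env.rate_exponent
    rate = r_lo * (r_hi / r_lo) ** tr
    return float(diameter), float(rate)


# --------------------------------------------------------------------------
# Poisson single-cell loading
# --------------------------------------------------------------------------

#: cells per (mL * OD unit) for supported species
OD_CONVERSION_FACTORS: dict[str, float] = {
    "e_coli": 2.88e8,
    "s_cerevisiae": 1e7,
}


def poisson_pmf(lam: float, k: int | np.ndarray) -> float | np.ndarray:
    """P(exactly k cells in a droplet) under Poisson loading."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    out = stats.poisson.pmf(k, lam)
    return float(out) if np.isscalar(k) else out


def encapsulation_stats(lam: float) -> tuple[float, float, float]:
    """(P(empty), P(single), P(single | occupied)) at loading rate ``lam``.

    The single fraction of occupied droplets is ``P(1) / (1 - P(0))``;
    it is defined as 0 at lambda = 0 (no droplet is ever occupied).
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    p0 = math.exp(-lam)
    p1 = lam * p0
    single_of_occupied = 0.0 if lam == 0 else p1 / (1.0 - p0)
    return p0, p1, single_of_occupied


def simulate_encapsulation(lam: float, n_droplets: int, seed: int = 0) -> np.ndarray:
    """Monte-Carlo draw of cells-per-droplet counts for ``n_droplets``."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if n_droplets < 0:
        raise ValueError("n_droplets must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(lam, size=n_droplets)


def od_to_cells(od: float, volume_ml: float, species: str) -> float:
    """Convert optical density to a cell count for a known species."""
    if od < 0:
        raise ValueError(f"OD must be >= 0, got {od}")
    if volume_ml < 0:
        raise ValueError(f"volume must be >= 0, got {volume_ml}")
    key = species.strip().lower().replace(" ", "_").replace(".", "")
    if key not in OD_CONVERSION_FACTORS:
        raise ValueError(
            f"unknown species {species!r}; known: {sorted(OD_CONVERSION_FACTORS)}"
        )
    return od * volume_ml * OD_CONVERSION_FACTORS[key]


# --------------------------------------------------------------------------
# Picoinjection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PicoinjectionModel:
    """Pressure-to-volume-change map for the picoinjector.

    Pressure is normalized to [-1, +1] around the equilibrium point; the
    characterized volume change runs from -3% (below equilibrium, fluid
    withdrawn) to +50%.  Piecewise linear through (0, 0), strictly monotone.
    Operates at roughly 100 Hz (metadata, enforced by the simulator).
    """

    min_volume_change: float = -0.03
    max_volume_change: float = 0.50
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if not self.min_volume_change < 0 < self.max_volume_change:
            raise ValueError(
                "volume-change endpoints must bracket 0 (equilibrium)"
            )


def picoinjection_volume_change(
    pressure: float, model: PicoinjectionModel | None = None
) -> float:
    """Fractional droplet volume change at a normalized injection pressure."""
    model = model or PicoinjectionModel()
    if not -1.0 <= pressure <= 1.0:
        raise ValueError(f"normalized pressure must be in [-1, 1], got {pressure}")
    if pressure >= 0:
        return pressure * model.max_volume_change
    return -pressure * model.min_volume_change


# --------------------------------------------------------------------------
# Droplet sorting regimes
# --------------------------------------------------------------------------

class SortingRegime(str, enum.Enum):
    NO_DEFLECTION = "no_deflection"
    SORTED = "sorted"
    FAILURE = "failure"


@dataclass(frozen=True)
class SortingRegimeMap:
    """Voltage/flow operating map of the droplet sorter.

    Anchored at the characterized 1 mL/hr bracket: below 100 V no
    deflection, above 400 V droplet failure (trapping and uncontrolled
    coalescence at the electrode).  Boundaries scale linearly with flow
    rate — a faster droplet needs proportionally more force to deflect.
    The drive waveform (1.2 kV, 45 kHz sine, selectively actuated) is
    carried as metadata.
    """

    reference_flow: float = 1.0            # mL/hr
    no_deflection_below: float = 100.0     # V at reference flow
    failure_above: float = 400.0           # V at reference flow
    waveform_amplitude_kv: float = 1.2
    waveform_frequency_khz: float = 45.0
    max_rate_per_s: float = 80.0

    def __post_init__(self) -> None:
        if self.reference_flow <= 0:
            raise ValueError("reference_flow must be > 0")
        if not 0 < self.no_deflection_below < self.failure_above:
            raise ValueError(
                "need 0 < no_deflection_below < failure_above"
            )

    def boundaries(self, flow_rate: float) -> tuple[float, float]:
        """(lower, upper) voltage boundaries at ``flow_rate`` mL/hr."""
        if flow_rate <= 0:
            raise ValueError(f"flow_rate must be > 0, got {flow_rate}")
        scale = flow_rate / self.reference_flow
        return self.no_deflection_below * scale, self.failure_above * scale


def classify_sorting(
    flow_rate: float, voltage: float, regime_map: SortingRegimeMap | None = None
) -> SortingRegime:
    """Classify a (flow, voltage) operating point into one of three regimes."""
    regime_map = regime_map or SortingRegimeMap()
    if voltage < 0:
        raise ValueError(f"voltage must be >= 0, got {voltage}")
    lower, upper = regime_map.boundaries(flow_rate)
    if voltage < lower:
        return SortingRegime.NO_DEFLECTION
    if voltage > upper:
        return SortingRegime.FAILURE
    return SortingRegime.SORTED


# --------------------------------------------------------------------------
# Anchor trapping outcome
# --------------------------------------------------------------------------

class AnchorOutcome(str, enum.Enum):
    STUCK = "stuck"                    # flow too slow: droplet never leaves
    TRAP_AND_KNOCK = "trap_and_knock"  # correct band: trapped until knocked
    PASS = "pass"                      # flow too fast: droplet skips the anchor


@dataclass(frozen=True)
class AnchorOutcomeModel:
    """Ordered partition of a normalized flow axis into trapping outcomes."""

    stuck_below: float = 0.5
    pass_above: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.stuck_below < self.pass_above:
            raise ValueError("need 0 <= stuck_below < pass_above")


def anchor_outcome(
    flow_param: float, model: AnchorOutcomeModel | None = None
) -> AnchorOutcome:
    """Trapping outcome at a normalized flow parameter (1.0 = nominal)."""
    model = model or AnchorOutcomeModel()
    if flow_param < 0:
        raise ValueError(f"flow_param must be >= 0, got {flow_param}")
    if flow_param < model.stuck_below:
        return AnchorOutcome.STUCK
    if flow_param > model.pass_above:
        return AnchorOutcome.PASS
    return AnchorOutcome.TRAP_AND_KNOCK
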