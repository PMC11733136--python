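"""Uniformly sampled single-channel voltage time series.

The :class:`Trace` is the common currency between the synthetic signal
generator, the peak detector, and the CSV readers/writers: one stream of
photodetector voltage samples taken at a fixed rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Trace"]

# relative tolerance on sample spacing before a trace is declared non-uniform
_UNIFORMITY_RTOL = 1e-6


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled voltage time series.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing and uniformly spaced.
    signal
        Voltage at each sample, same length as ``time``.
    """

    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        if time.ndim != 1 or signal.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays")
        if time.shape != signal.shape:
            raise ValueError(
                f"time and signal lengths differ: {time.size} vs {signal.size}"
            )
        if time.size == 0:
            raise ValueError("trace must contain at least one sample")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "signal", signal)

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def dt(self) -> float:
        """Sample spacing in seconds (0.0 for a single-sample trace)."""
        if self.time.size < 2:
            return 0.0
        return float(self.time[1] - self.time[0])

    @property
    def sample_rate(self) -> float:
        dt = self.dt
        return float("inf") if dt == 0.0 else 1.0 / dt

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def is_uniform(self) -> bool:
        """True iff the sample spacing is constant to within rounding."""
        if self.time.size < 3:
            return True
        steps = np.diff(self.time)
        ref = steps[0]
        if ref <= 0:
            return False
        return bool(np.allclose(steps, ref, rtol=_UNIFORMITY_RTOL, atol=0.0))

    def require_uniform(self) -> None:
        if not self.is_uniform():
            raise ValueError("trace is not uniformly sampled")

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_samples
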