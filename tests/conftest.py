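from __future__ import annotations

import numpy as np
import pytest

from dropletpix.classification import PALETTE
from dropletpix.synthetic_data import GroupSpec, PopulationSpec


def palette_group_specs(low_v: float = 0.2, high_v: float = 1.2, cv: float = 0.05):
    """One droplet group per palette color (low/high per-channel means)."""
    return tuple(
        GroupSpec(tuple(high_v if lvl else low_v for lvl in c.levels), cv=cv)
        for c in PALETTE
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eight_group_spec():
    """Balanced 8-group population, 50 droplets each, CV 5%, SNR >= 20."""
    return PopulationSpec(
        groups=palette_group_specs(),
        droplets_per_group=50,
        transit_spacing=0.003,
        inter_droplet_gap=0.015,
        sample_rate=10_000.0,
        baseline_level=0.1,
        noise_sd=0.01,
        pulse_width_sd=3e-4,
        seed=42,
    )


def match_signatures_to_truth(signatures, truth, tolerance):
    """Greedy one-to-one time matching; returns [(signature, record), ...]."""
    sigs = sorted(signatures, key=lambda s: s.droplet_time)
    recs = sorted(truth, key=lambda r: r.start_time)
    out = []
    ti = 0
    for sig in sigs:
        while ti < len(recs) and recs[ti].start_time < sig.droplet_time - tolerance:
            ti += 1
        if ti < len(recs) and abs(recs[ti].start_time - sig.droplet_time) <= tolerance:
            out.append((sig, recs[ti]))
            ti += 1
    return out
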