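"""Shared fixtures: small seeded simulations reused across test modules.

Session scope keeps the expensive simulations (LFP sessions, spike trains)
to one instance each; every fixture is fully determined by its hard-coded
seed, so the suite is reproducible run to run.
"""
from __future__ import annotations

import numpy as np
import pytest

import corticode as cc


@pytest.fixture(scope="session")
def site_map():
    return cc.generate_site_map(seed=7)


@pytest.fixture(scope="session")
def long_tone_recording(site_map):
    """Four test frequencies x 2 repeats (8 min) with planted high-gamma effects."""
    sched = cc.generate_long_tone_protocol(
        [12000.0, 22000.0, 32000.0, 50000.0], repeats=2, seed=3
    )
    return cc.simulate_lfp_session(site_map, sched, seed=3)


@pytest.fixture(scope="session")
def null_long_tone_recording(site_map):
    """Same protocol with all effect amplitudes zero and no bursts."""
    sched = cc.generate_long_tone_protocol([12000.0, 22000.0], repeats=1, seed=5)
    effects = cc.LfpEffects(aep_amplitude_uv=0.0, sustained_amplitude_uv=0.0)
    return cc.simulate_lfp_session(site_map, sched, effects=effects, seed=5)


@pytest.fixture(scope="session")
def spike_trains(site_map):
    """Full 18 x 7 characterization protocol, 10 repeats per condition."""
    sched = cc.generate_tone_burst_protocol(repeats=10, seed=11)
    return cc.simulate_spike_trains(site_map, sched, seed=11)


@pytest.fixture(scope="session")
def characterizations(spike_trains):
    from corticode.unit_characterization import characterize_sites

    return characterize_sites(spike_trains)
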