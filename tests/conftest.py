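"""Shared fixtures: small deterministic cohorts and evoked-builder helpers."""

import numpy as np
import pytest

from vepltp import SimulationConfig, simulate_cohort
from vepltp.preprocess import Evoked, preprocess_recording
from vepltp.erp import measure_participant
from vepltp.simulate import BLOCKS, standard_montage


def make_evoked(wave: np.ndarray, sampling_rate: float = 1000.0,
                t0_ms: float = 0.0, n_channels: int = 1,
                positions: np.ndarray | None = None,
                block: str = "pre", condition: str = "tetanized") -> Evoked:
    """Single- or multi-channel Evoked wrapping a given waveform."""
    wave = np.atleast_2d(wave)
    if wave.shape[0] == 1 and n_channels > 1:
        wave = np.repeat(wave, n_channels, axis=0)
    times = t0_ms + np.arange(wave.shape[1]) * 1000.0 / sampling_rate
    if positions is None:
        positions = np.tile([[-0.75, -0.5]], (wave.shape[0], 1))
    return Evoked(data=wave, times=times, sampling_rate=sampling_rate,
                  block=block, condition=condition, n_epochs_averaged=1,
                  channel_labels=[f"ch{i}" for i in range(wave.shape[0])],
                  channel_positions=positions)


@pytest.fixture(scope="session")
def montage32():
    return standard_montage(32)


@pytest.fixture(scope="session")
def noiseless_cohort_measurements():
    """Three noiseless participants (one per genotype) pushed through the
    full chain: simulate -> preprocess -> quantify.  Session-scoped because
    the continuous-EEG path is the expensive part of the suite."""
    cfg = SimulationConfig(noise_sd=0.0, n_presentations=30, seed=7,
                           group_sizes=(1, 1, 1))
    cohort = simulate_cohort(cfg)
    out = []
    for profile in cohort.profiles:
        evokeds = {}
        for block in BLOCKS:
            rec = cohort.recording(profile, block)
            evs, _ = preprocess_recording(rec, profile.tetanized_orientation)
            evokeds.update(evs)
        meas, scores = measure_participant(evokeds, profile.id)
        out.append((profile, meas, scores))
    return out
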