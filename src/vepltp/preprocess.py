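"""EEG preprocessing chain for the sensory-LTP paradigm.

Fixed stage order (deviating from it is a configuration violation):
common-average re-reference -> zero-phase Butterworth band-pass ->
epoching -> baseline correction -> artifact rejection -> block averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .simulate import Recording, ORIENTATIONS, BLOCKS

logger = logging.getLogger(__name__)

CHAIN_ORDER = ("rereference", "filter", "segment", "baseline", "reject", "average")

CONDITIONS = ("tetanized", "non_tetanized")


@dataclass
class PreprocessParams:
    low_hz: float = 0.1
    high_hz: float = 30.0
    poles: int = 3
    window_ms: tuple[float, float] = (-100.0, 500.0)
    reject_limit_uv: float = 150.0

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("cutoffs must satisfy 0 < low < high")
        if self.high_hz >= sampling_rate / 2:
            raise ValueError("high cutoff must be below Nyquist")
        if self.reject_limit_uv < 0:
            raise ValueError("rejection limit must be positive")


@dataclass
class Epochs:
    """Epochs x channels x time, with per-epoch keep flags.

    ``times`` is in ms relative to stimulus onset; the window is half-open
    [-100, 500) so an epoch at 1 kHz has exactly 600 samples with the onset
    sample included on the post-stimulus side.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    block: str
    condition: str
    kept: np.ndarray
    channel_labels: list[str]
    channel_positions: np.ndarray

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept]


@dataclass
class Evoked:
    """Average of the kept epochs of one block x condition cell."""

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    block: str
    condition: str
    n_epochs_averaged: int
    channel_labels: list[str]
    channel_positions: np.ndarray


def rereference_common_average(recording: Recording) -> Recording:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if recording.data.shape[0] < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return replace(recording, data=data)


def bandpass_filter(recording: Recording, low_hz: float = 0.1,
                    high_hz: float = 30.0, poles: int = 3) -> Recording:
    """Bidirectional (zero-phase) Butterworth band-pass.

    The three-pole design is applied forward and backward, which doubles the
    attenuation and cancels the phase response.  Reflection padding spans
    three time constants of the low cutoff (clamped to the data length) so
    that the slow high-pass transient settles inside the discarded pad.
    """
    fs = recording.sampling_rate
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError("cutoffs must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(poles, [low_hz, high_hz], btype="bandpass", fs=fs,
                        output="sos")
    padlen = min(recording.data.shape[-1] - 1, int(round(3 * fs / low_hz)))
    data = signal.sosfiltfilt(sos, recording.data, axis=-1, padtype="odd",
                              padlen=padlen)
    return replace(recording, data=data)


def segment(recording: Recording, tetanized_orientation: str,
            window_ms: tuple[float, float] = (-100.0, 500.0)) -> dict[tuple[str, str], Epochs]:
    """Cut epochs around every marker, grouped by block x condition.

    Markers too close to a recording edge are dropped with a logged warning
    rather than raising.  Orientation maps to tetanized/non-tetanized via
    the participant's tetanized orientation.
    """
    if tetanized_orientation not in ORIENTATIONS:
        raise ValueError("unknown tetanized orientation")
    fs = recording.sampling_rate
    start = int(round(window_ms[0] * fs / 1000.0))
    stop = int(round(window_ms[1] * fs / 1000.0))
    n_time = stop - start
    times = (np.arange(start, stop)) * 1000.0 / fs
    n_samples = recording.data.shape[1]

    grouped: dict[tuple[str, str], list[np.ndarray]] = {}
    n_dropped = 0
    for m in recording.markers:
        a, b = m.sample_index + start, m.sample_index + stop
        if a < 0 or b > n_samples:
            n_dropped += 1
            continue
        cond = ("tetanized" if m.orientation == tetanized_orientation
                else "non_tetanized")
        grouped.setdefault((m.block, cond), []).append(recording.data[:, a:b])
    if n_dropped:
        msg = f"dropped {n_dropped} epoch(s) too close to the recording edge"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    out = {}
    for key, chunks in grouped.items():
        data = np.stack(chunks)
        out[key] = Epochs(
            data=data, times=times, sampling_rate=fs, block=key[0],
            condition=key[1], kept=np.ones(len(chunks), dtype=bool),
            channel_labels=recording.channel_labels,
            channel_positions=recording.channel_positions)
        assert out[key].data.shape[2] == n_time
    return out


def baseline_correct(epochs: Epochs) -> Epochs:
    """Subtract each epoch's per-channel mean over the prestimulus interval."""
    pre = epochs.times < 0
    if not pre.any():
        raise ValueError("no prestimulus samples to baseline against")
    base = epochs.data[:, :, pre].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def reject_artifacts(epochs: Epochs,
                     peak_to_peak_limit_uv: float = 150.0) -> tuple[Epochs, dict]:
    """Flag epochs whose worst-channel peak-to-peak amplitude exceeds the limit.

    Returns the epochs with an updated keep mask plus a per-cell report.
    Rejecting everything is legal but loudly reported.
    """
    if peak_to_peak_limit_uv < 0:
        raise ValueError("limit must be non-negative")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    ok = ptp.max(axis=1) <= peak_to_peak_limit_uv
    kept = epochs.kept & ok
    report = {
        "block": epochs.block,
        "condition": epochs.condition,
        "n_epochs": int(epochs.n_epochs),
        "n_rejected": int(epochs.n_epochs - kept.sum()),
        "limit_uv": float(peak_to_peak_limit_uv),
        "all_rejected": bool(kept.sum() == 0),
    }
    if report["all_rejected"]:
        logger.warning("all %d epochs rejected in %s/%s", epochs.n_epochs,
                       epochs.block, epochs.condition)
    return replace(epochs, kept=kept), report


def regress_out_eog(epochs: Epochs, eog_channel: int) -> Epochs:
    """Optional ocular correction: regress a designated EOG-like channel out
    of every other channel, epoch by epoch."""
    data = epochs.data.copy()
    for e in range(data.shape[0]):
        eog = data[e, eog_channel]
        denom = float(eog @ eog)
        if denom == 0:
            continue
        beta = data[e] @ eog / denom
        beta[eog_channel] = 0.0
        data[e] -= beta[:, None] * eog[None, :]
    return replace(epochs, data=data)


def average_epochs(epochs: Epochs) -> Evoked:
    """Arithmetic mean over kept epochs."""
    n_kept = int(epochs.kept.sum())
    if n_kept == 0:
        raise ValueError(
            f"no epochs kept in {epochs.block}/{epochs.condition}")
    return Evoked(
        data=epochs.kept_data().mean(axis=0), times=epochs.times,
        sampling_rate=epochs.sampling_rate, block=epochs.block,
        condition=epochs.condition, n_epochs_averaged=n_kept,
        channel_labels=epochs.channel_labels,
        channel_positions=epochs.channel_positions)


def preprocess_recording(recording: Recording, tetanized_orientation: str,
                         params: PreprocessParams | None = None,
                         ) -> tuple[dict[tuple[str, str], Evoked], list[dict]]:
    """Run the full fixed-order chain on one continuous recording.

    Returns evoked responses keyed by (block, condition) together with the
    per-cell artifact-rejection report.
    """
    params = params if params is not None else PreprocessParams()
    params.validate(recording.sampling_rate)
    rec = rereference_common_average(recording)
    rec = bandpass_filter(rec, params.low_hz, params.high_hz, params.poles)
    cells = segment(rec, tetanized_orientation, params.window_ms)
    evokeds, reports = {}, []
    for key in sorted(cells, key=lambda k: (BLOCKS.index(k[0]), k[1])):
        ep = baseline_correct(cells[key])
        ep, rep = reject_artifacts(ep, params.reject_limit_uv)
        reports.append(rep)
        evokeds[key] = average_epochs(ep)
    return evokeds, reports
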