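"""N170/P2 peak detection, the peak-anchored N1b window, posterior electrode
clusters, and early/late LTP scores.

The N1b is the stretch of the VEP from the N170 peak to the midpoint between
the N170 and P2 peaks.  LTP scores are pre-tetanus minus post-tetanus N1b
mean amplitude, so a potentiated (more negative) post-tetanus N1b yields a
positive score and an inverted response (depression) a negative one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Evoked, CONDITIONS
from .simulate import BLOCKS


@dataclass
class PeakMeasurement:
    latency_ms: float
    amplitude_uv: float
    at_edge: bool


@dataclass
class ComponentMeasurement:
    participant_id: str
    n170_latency_ms: float
    n170_amplitude_uv: float
    p2_latency_ms: float
    p2_amplitude_uv: float
    n1b_window_ms: tuple[float, float]
    cluster_channels: dict[str, list[str]]
    n1b_amplitudes: dict[tuple[str, str], float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class LTPScores:
    participant_id: str
    early_ltp: float
    late_ltp: float
    control_early: float
    control_late: float


def _cluster_mean(evoked: Evoked, channels: np.ndarray | list[int]) -> np.ndarray:
    channels = np.asarray(channels, dtype=int)
    if channels.size == 0:
        raise ValueError("empty channel cluster")
    return evoked.data[channels].mean(axis=0)


def _window_mask(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (times >= lo) & (times <= hi)


def detect_n170(evoked: Evoked, channels,
                search_window_ms: tuple[float, float] = (130.0, 220.0)
                ) -> PeakMeasurement:
    """Most negative point of the cluster-mean waveform in the search window.

    Ties break toward the earliest latency; a minimum sitting on a window
    edge is flagged rather than rejected.
    """
    wave = _cluster_mean(evoked, channels)
    mask = _window_mask(evoked.times, *search_window_ms)
    if not mask.any():
        raise ValueError("evoked does not cover the N170 search window")
    idx = np.flatnonzero(mask)
    k = idx[np.argmin(wave[idx])]
    return PeakMeasurement(float(evoked.times[k]), float(wave[k]),
                           at_edge=bool(k == idx[0] or k == idx[-1]))


def detect_p2(evoked: Evoked, channels, n170_latency_ms: float,
              search_end_ms: float = 320.0,
              offset_ms: float = 10.0) -> PeakMeasurement:
    """Most positive point between just after the N170 and ``search_end_ms``."""
    lo = n170_latency_ms + offset_ms
    if lo >= search_end_ms:
        raise ValueError("P2 window must start before it ends")
    wave = _cluster_mean(evoked, channels)
    mask = _window_mask(evoked.times, lo, search_end_ms)
    if not mask.any():
        raise ValueError("evoked does not cover the P2 search window")
    idx = np.flatnonzero(mask)
    k = idx[np.argmax(wave[idx])]
    return PeakMeasurement(float(evoked.times[k]), float(wave[k]),
                           at_edge=bool(k == idx[0] or k == idx[-1]))


def n1b_window(n170_latency_ms: float, p2_latency_ms: float,
               min_length_ms: float = 1.0) -> tuple[float, float]:
    """(N170 peak, midpoint of N170 and P2 peaks)."""
    if p2_latency_ms <= n170_latency_ms:
        raise ValueError("P2 must follow the N170")
    start = n170_latency_ms
    end = 0.5 * (n170_latency_ms + p2_latency_ms)
    if end - start < min_length_ms:
        raise ValueError("degenerate N1b window (peaks nearly coincide)")
    return (start, end)


def select_cluster(grand_mean: Evoked, k: int = 4,
                   window_ms: tuple[float, float] = (130.0, 220.0),
                   posterior_max_y: float = -0.1) -> dict[str, np.ndarray]:
    """Per-hemisphere posterior clusters: the k channels with the most
    negative mean amplitude in the N170 window of the all-condition grand
    mean.  Deterministic: ties resolve by channel order."""
    if k < 1:
        raise ValueError("cluster size must be >= 1")
    pos = grand_mean.channel_positions
    mask = _window_mask(grand_mean.times, *window_ms)
    score = grand_mean.data[:, mask].mean(axis=1)
    out = {}
    for hemi, sel in (("left", pos[:, 0] < 0), ("right", pos[:, 0] > 0)):
        cand = np.flatnonzero(sel & (pos[:, 1] < posterior_max_y))
        if cand.size < k:
            raise ValueError(
                f"only {cand.size} posterior channels in {hemi} hemisphere, "
                f"need {k}")
        order = cand[np.argsort(score[cand], kind="stable")]
        out[hemi] = order[:k]
    return out


def n1b_mean_amplitude(evoked: Evoked, window_ms: tuple[float, float],
                       channels) -> float:
    """Mean over cluster channels and samples inside [start, end] inclusive."""
    wave = _cluster_mean(evoked, channels)
    mask = _window_mask(evoked.times, *window_ms)
    if not mask.any():
        raise ValueError("N1b window contains no samples")
    return float(wave[mask].mean())


def compute_ltp_scores(pre_amp: float, early_amp: float, late_amp: float
                       ) -> tuple[float, float]:
    """(early, late) potentiation: pre minus post N1b amplitude.

    Positive = post-tetanus more negative = potentiation; negative =
    depression.
    """
    for v in (pre_amp, early_amp, late_amp):
        if not np.isfinite(v):
            raise ValueError("amplitudes must be finite")
    return (pre_amp - early_amp, pre_amp - late_amp)


def measure_participant(evokeds: dict[tuple[str, str], Evoked],
                        participant_id: str = "",
                        cluster_k: int = 4,
                        n170_window_ms: tuple[float, float] = (130.0, 220.0),
                        p2_end_ms: float = 320.0,
                        p2_offset_ms: float = 10.0,
                        ) -> tuple[ComponentMeasurement, LTPScores]:
    """Full component quantification for one participant.

    Clusters come from the grand mean over every block x condition cell;
    peaks are detected on the pre-tetanus cluster-mean waveform and the
    resulting N1b window is held fixed across blocks.  Both hemispheres'
    clusters are pooled for amplitude measurement; the identical computation
    on the non-tetanized condition is emitted as the specificity control.
    """
    needed = [(b, c) for b in BLOCKS for c in CONDITIONS]
    missing = [key for key in needed if key not in evokeds]
    if missing:
        raise ValueError(f"missing evoked cells: {missing}")

    ref = evokeds[needed[0]]
    grand = Evoked(
        data=np.mean([evokeds[key].data for key in needed], axis=0),
        times=ref.times, sampling_rate=ref.sampling_rate, block="all",
        condition="all", n_epochs_averaged=sum(
            evokeds[key].n_epochs_averaged for key in needed),
        channel_labels=ref.channel_labels,
        channel_positions=ref.channel_positions)

    clusters = select_cluster(grand, k=cluster_k, window_ms=n170_window_ms)
    pooled = np.concatenate([clusters["left"], clusters["right"]])

    pre = Evoked(
        data=0.5 * (evokeds[("pre", "tetanized")].data
                    + evokeds[("pre", "non_tetanized")].data),
        times=ref.times, sampling_rate=ref.sampling_rate, block="pre",
        condition="all",
        n_epochs_averaged=(evokeds[("pre", "tetanized")].n_epochs_averaged
                           + evokeds[("pre", "non_tetanized")].n_epochs_averaged),
        channel_labels=ref.channel_labels,
        channel_positions=ref.channel_positions)

    n170 = detect_n170(pre, pooled, n170_window_ms)
    p2 = detect_p2(pre, pooled, n170.latency_ms, p2_end_ms, p2_offset_ms)
    window = n1b_window(n170.latency_ms, p2.latency_ms)

    flags = []
    if n170.at_edge:
        flags.append("n170_edge_peak")
    if p2.at_edge:
        flags.append("p2_edge_peak")

    labels = ref.channel_labels
    meas = ComponentMeasurement(
        participant_id=participant_id,
        n170_latency_ms=n170.latency_ms, n170_amplitude_uv=n170.amplitude_uv,
        p2_latency_ms=p2.latency_ms, p2_amplitude_uv=p2.amplitude_uv,
        n1b_window_ms=window,
        cluster_channels={h: [labels[i] for i in idx]
                          for h, idx in clusters.items()},
        flags=flags)
    for key in needed:
        meas.n1b_amplitudes[key] = n1b_mean_amplitude(evokeds[key], window,
                                                      pooled)
    early, late = compute_ltp_scores(
        meas.n1b_amplitudes[("pre", "tetanized")],
        meas.n1b_amplitudes[("early_post", "tetanized")],
        meas.n1b_amplitudes[("late_post", "tetanized")])
    c_early, c_late = compute_ltp_scores(
        meas.n1b_amplitudes[("pre", "non_tetanized")],
        meas.n1b_amplitudes[("early_post", "non_tetanized")],
        meas.n1b_amplitudes[("late_post", "non_tetanized")])
    scores = LTPScores(participant_id, early, late, c_early, c_late)
    return meas, scores
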