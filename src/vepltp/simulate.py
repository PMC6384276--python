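"""Synthetic cohorts for the visual sensory-LTP paradigm.

The generator emits, per participant, three low-frequency stimulation blocks
(pre-tetanus, early post-tetanus, late post-tetanus) of 240 presentations per
grating orientation at 1,000 Hz on a 32-channel posterior-weighted montage.
The tetanus itself is not simulated; only its consequence -- a genotype-
dependent negative shift of the N1b segment of the VEP for the tetanized
orientation -- is injected into the post-tetanus blocks.

Sign convention: per-participant true effects (``true_early_ltp``,
``true_late_ltp``) are *waveform shifts* in microvolts, so a negative value
makes the N1b more negative (potentiation).  The downstream LTP *score*
(pre minus post) recovers the negated shift: a shift of -1.5 uV yields a
score of +1.5 uV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

GENOTYPES = ("Val/Val", "Val/Met", "Met/Met")
ORIENTATIONS = ("horizontal", "vertical")
BLOCKS = ("pre", "early_post", "late_post")
_BLOCK_CODE = {b: i for i, b in enumerate(BLOCKS)}


@dataclass
class EventMarker:
    """Stimulus onset: sample index plus orientation and block labels."""

    sample_index: int
    orientation: str
    block: str

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")


@dataclass
class Recording:
    """Continuous multi-channel EEG segment with stimulus markers.

    ``data`` is channels x samples in microvolts; ``channel_positions`` are
    schematic 2-D scalp coordinates (x: left-negative/right-positive,
    y: anterior-positive/posterior-negative, unit head radius).
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    channel_positions: np.ndarray
    markers: list[EventMarker]

    def validate(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("label count does not match channel count")
        idx = [m.sample_index for m in self.markers]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("markers must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= self.data.shape[1]):
            raise ValueError("marker outside the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ParticipantProfile:
    id: str
    genotype: str
    true_early_ltp: float
    true_late_ltp: float
    memory_score: float
    tetanized_orientation: str
    index: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.tetanized_orientation not in ORIENTATIONS:
            raise ValueError("unknown orientation")
        if not 0.0 <= self.memory_score <= 100.0:
            raise ValueError("memory_score must lie in [0, 100]")


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort.

    Genotype effects are N1b waveform shifts in microvolts (negative =
    potentiation); the late-block defaults make Met/Met homozygotes invert
    (depression).  ``participant_sd`` is the between-participant SD around
    the genotype mean, chosen to match the effect sizes implied by the
    strongest published pairwise contrast at the default group sizes.
    """

    group_sizes: tuple[int, int, int] = (10, 10, 8)
    genotype_late_effect: dict[str, float] = field(
        default_factory=lambda: {"Val/Val": -1.5, "Val/Met": -0.3, "Met/Met": 0.5})
    genotype_early_effect: dict[str, float] = field(
        default_factory=lambda: {"Val/Val": -1.0, "Val/Met": -0.1, "Met/Met": 0.2})
    participant_sd: float = 0.75
    target_memory_correlation: float = 0.44
    memory_mean: float = 75.0
    memory_sd: float = 10.0
    noise_sd: float = 2.0
    shared_noise_frac: float = 0.3
    n_channels: int = 32
    sampling_rate: float = 1000.0
    n_presentations: int = 240
    presentation_ms: float = 33.0
    isi_range_ms: tuple[float, float] = (1000.0, 1500.0)
    n170_latency_ms: float = 170.0
    n170_amp_uv: float = -4.0
    n170_width_ms: float = 25.0
    p2_latency_ms: float = 240.0
    p2_amp_uv: float = 3.0
    p2_width_ms: float = 40.0
    template_duration_ms: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("all group sizes must be >= 1")
        if not -1.0 < self.target_memory_correlation < 1.0:
            raise ValueError("target correlation must lie in (-1, 1)")
        if self.sampling_rate <= 2 * 30.0:
            raise ValueError("sampling rate must exceed twice the filter high-cut")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_presentations < 1:
            raise ValueError("need at least one presentation")

    @property
    def onset_interval_ms(self) -> tuple[float, float]:
        """Onset-to-onset interval: presentation plus jittered ISI."""
        lo, hi = self.isi_range_ms
        return (lo + self.presentation_ms, hi + self.presentation_ms)

    @property
    def n1b_window_ms(self) -> tuple[float, float]:
        """Canonical N1b window of the noiseless template (peak-anchored)."""
        return (self.n170_latency_ms,
                0.5 * (self.n170_latency_ms + self.p2_latency_ms))


# --------------------------------------------------------------------------
# montage and scalp topography


def standard_montage(n_channels: int = 32) -> tuple[list[str], np.ndarray]:
    """Schematic 2-D montage with labelled P7/P8 analogues.

    For 32 channels a conventional 10-20 style layout is returned; other
    counts (>= 16) get a front-to-back grid whose posterior-lateral pair is
    relabelled P7/P8 so that cluster selection has its anchors.
    """
    if n_channels == 32:
        layout = [
            ("Fp1", -0.25, 0.9), ("Fp2", 0.25, 0.9),
            ("AF3", -0.3, 0.7), ("AF4", 0.3, 0.7),
            ("F7", -0.75, 0.5), ("F3", -0.4, 0.5), ("Fz", 0.0, 0.5),
            ("F4", 0.4, 0.5), ("F8", 0.75, 0.5),
            ("FC5", -0.6, 0.3), ("FC1", -0.25, 0.3), ("FC2", 0.25, 0.3),
            ("FC6", 0.6, 0.3),
            ("T7", -0.85, 0.0), ("C3", -0.45, 0.0), ("Cz", 0.0, 0.0),
            ("C4", 0.45, 0.0), ("T8", 0.85, 0.0),
            ("CP5", -0.6, -0.3), ("CP1", -0.25, -0.3), ("CP2", 0.25, -0.3),
            ("CP6", 0.6, -0.3),
            ("P7", -0.75, -0.5), ("P3", -0.4, -0.5), ("Pz", 0.0, -0.5),
            ("P4", 0.4, -0.5), ("P8", 0.75, -0.5),
            ("PO3", -0.35, -0.7), ("PO4", 0.35, -0.7),
            ("O1", -0.3, -0.9), ("Oz", 0.0, -0.9), ("O2", 0.3, -0.9),
        ]
        labels = [name for name, _, _ in layout]
        pos = np.array([[x, y] for _, x, y in layout])
        return labels, pos
    if n_channels < 16:
        raise ValueError("montage needs at least 16 channels")
    n_rows = max(4, int(np.ceil(n_channels / 8)))
    rows = np.linspace(0.9, -0.9, n_rows)
    labels, coords = [], []
    i = 0
    per_row = int(np.ceil(n_channels / n_rows))
    for y in rows:
        for x in np.linspace(-0.75, 0.75, per_row):
            if i >= n_channels:
                break
            labels.append(f"CH{i + 1:02d}")
            coords.append([x, y])
            i += 1
    pos = np.array(coords)
    back = pos[:, 1] < -0.1
    left = np.where(back & (pos[:, 0] < 0))[0]
    right = np.where(back & (pos[:, 0] > 0))[0]
    labels[left[np.argmin(pos[left, 0])]] = "P7"
    labels[right[np.argmax(pos[right, 0])]] = "P8"
    return labels, pos


def posterior_topography(positions: np.ndarray, labels: list[str],
                         plateau_radius: float = 0.5,
                         falloff: float = 0.3) -> np.ndarray:
    """Per-channel VEP weights: flat-topped around P7/P8, Gaussian outside.

    The flat top guarantees that the channels a posterior cluster selects
    all carry the template at unit gain, so injected N1b shifts survive
    cluster averaging exactly.
    """
    anchors = [i for i, lab in enumerate(labels) if lab in ("P7", "P8")]
    if not anchors:
        raise ValueError("montage has no P7/P8 anchors")
    d = np.min(
        [np.hypot(*(positions - positions[a]).T) for a in anchors], axis=0)
    excess = np.clip(d - plateau_radius, 0.0, None)
    return np.exp(-0.5 * (excess / falloff) ** 2)


# --------------------------------------------------------------------------
# waveforms


def make_vep_template(n170_latency_ms: float, n170_amp_uv: float,
                      p2_latency_ms: float, p2_amp_uv: float,
                      duration_ms: float, sampling_rate: float,
                      n170_width_ms: float = 25.0,
                      p2_width_ms: float = 40.0) -> np.ndarray:
    """Parametric VEP: a negative N170 and a positive P2 Gaussian deflection."""
    if not 0 < n170_latency_ms < p2_latency_ms < duration_ms:
        raise ValueError("latencies must satisfy 0 < N170 < P2 < duration")
    if n170_amp_uv >= 0:
        raise ValueError("N170 amplitude must be negative")
    if p2_amp_uv <= 0:
        raise ValueError("P2 amplitude must be positive")
    n = int(round(duration_ms * sampling_rate / 1000.0))
    t = np.arange(n) * 1000.0 / sampling_rate
    wave = (n170_amp_uv * np.exp(-0.5 * ((t - n170_latency_ms) / n170_width_ms) ** 2)
            + p2_amp_uv * np.exp(-0.5 * ((t - p2_latency_ms) / p2_width_ms) ** 2))
    return wave


def n1b_bump(window_ms: tuple[float, float], duration_ms: float,
             sampling_rate: float, pad_ms: float = 5.0,
             taper_ms: float = 30.0) -> np.ndarray:
    """Unit flat-topped bump covering the N1b window.

    Value 1 on [start - pad, end + pad] with raised-cosine tapers outside;
    both the window mean and the window extremum of the injected effect then
    equal the injected amplitude, which makes noiseless recovery exact.
    """
    start, end = window_ms
    n = int(round(duration_ms * sampling_rate / 1000.0))
    t = np.arange(n) * 1000.0 / sampling_rate
    lo, hi = start - pad_ms, end + pad_ms
    bump = np.zeros(n)
    flat = (t >= lo) & (t <= hi)
    bump[flat] = 1.0
    rise = (t >= lo - taper_ms) & (t < lo)
    bump[rise] = 0.5 * (1 + np.cos(np.pi * (lo - t[rise]) / taper_ms))
    fall = (t > hi) & (t <= hi + taper_ms)
    bump[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - hi) / taper_ms))
    return bump


def pink_noise(n_samples: int, sampling_rate: float,
               rng: np.random.Generator, floor_hz: float = 1.0) -> np.ndarray:
    """Unit-RMS 1/f-power noise (flat below ``floor_hz``)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    amp = 1.0 / np.sqrt(np.maximum(freqs, floor_hz))
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n_samples)
    return x / x.std()


# --------------------------------------------------------------------------
# random-stream splitting
#
# All randomness descends from SimulationConfig.seed through fixed
# SeedSequence keys, so any participant/block can be regenerated in
# isolation:
#   (seed, 0)            cohort structure (deviations, counterbalancing)
#   (seed, 1)            memory scores
#   (seed, 2, i, b)      continuous EEG for participant i, block code b


def _cohort_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, 0)))


def _memory_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, 1)))


def _block_rng(seed: int, participant_index: int, block: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((seed, 2, participant_index, _BLOCK_CODE[block])))


# --------------------------------------------------------------------------
# block and cohort simulation


def simulate_block(profile: ParticipantProfile, block: str,
                   config: SimulationConfig) -> Recording:
    """One low-frequency stimulation block as a continuous recording.

    Each orientation is presented ``config.n_presentations`` times in a
    shuffled sequence with onset-to-onset intervals drawn uniformly from the
    configured range.  In post-tetanus blocks the tetanized orientation's
    N1b is shifted by the participant's true effect; the non-tetanized
    orientation is never touched.
    """
    if block not in BLOCKS:
        raise ValueError(f"unknown block {block!r}")
    config.validate()
    fs = config.sampling_rate
    rng = _block_rng(config.seed, profile.index, block)

    n_per = config.n_presentations
    orients = np.array([0] * n_per + [1] * n_per)
    rng.shuffle(orients)
    lo, hi = config.onset_interval_ms
    intervals = rng.uniform(lo, hi, size=2 * n_per)
    lead_in_ms = 500.0
    onsets_ms = lead_in_ms + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    onsets = np.round(onsets_ms * fs / 1000.0).astype(int)

    labels, positions = standard_montage(config.n_channels)
    weights = posterior_topography(positions, labels)
    # Signal topography is expressed in the common-average space (zero
    # spatial mean, unit gain on the posterior plateau) so that offline
    # re-referencing leaves the evoked response untouched; anterior
    # channels carry the physiologic polarity inversion.
    sig_weights = (weights - weights.mean()) / (1.0 - weights.mean())
    tmpl_len = int(round(config.template_duration_ms * fs / 1000.0))
    n_samples = onsets[-1] + tmpl_len + int(round(0.5 * fs))

    base = make_vep_template(
        config.n170_latency_ms, config.n170_amp_uv, config.p2_latency_ms,
        config.p2_amp_uv, config.template_duration_ms, fs,
        config.n170_width_ms, config.p2_width_ms)
    waves = {0: base.copy(), 1: base.copy()}
    if block != "pre":
        shift = (profile.true_early_ltp if block == "early_post"
                 else profile.true_late_ltp)
        bump = n1b_bump(config.n1b_window_ms, config.template_duration_ms, fs)
        tet = ORIENTATIONS.index(profile.tetanized_orientation)
        waves[tet] = waves[tet] + shift * bump

    n_ch = config.n_channels
    if config.noise_sd > 0:
        c = config.shared_noise_frac
        shared = pink_noise(n_samples, fs, rng)
        data = np.empty((n_ch, n_samples))
        for ch in range(n_ch):
            data[ch] = config.noise_sd * (
                np.sqrt(1 - c) * pink_noise(n_samples, fs, rng)
                + np.sqrt(c) * weights[ch] * shared)
    else:
        data = np.zeros((n_ch, n_samples))

    for onset, o in zip(onsets, orients):
        data[:, onset:onset + tmpl_len] += sig_weights[:, None] * waves[int(o)]

    markers = [EventMarker(int(s), ORIENTATIONS[int(o)], block)
               for s, o in zip(onsets, orients)]
    rec = Recording(data, fs, labels, positions, markers)
    rec.validate()
    return rec


def generate_memory_scores(values: np.ndarray, target_r: float,
                           rng: np.random.Generator | int,
                           mean: float = 75.0, sd: float = 10.0) -> np.ndarray:
    """Percent-correct scores correlated with ``values`` at ``target_r``.

    The standardized input is mixed with independent Gaussian noise so the
    population correlation equals the target, then mapped to the requested
    mean/SD and clipped to [0, 100].
    """
    values = np.asarray(values, dtype=float)
    if not -1.0 < target_r < 1.0:
        raise ValueError("target_r must lie strictly inside (-1, 1)")
    if values.size < 3:
        raise ValueError("need at least 3 values")
    if np.std(values) == 0:
        raise ValueError("input vector has zero variance")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    z = (values - values.mean()) / values.std()
    eps = rng.standard_normal(values.size)
    mixed = target_r * z + np.sqrt(1.0 - target_r ** 2) * eps
    return np.clip(mean + sd * mixed, 0.0, 100.0)


@dataclass
class CohortSim:
    """A simulated cohort: profiles plus lazy access to the recordings."""

    profiles: list[ParticipantProfile]
    config: SimulationConfig

    def recording(self, profile: ParticipantProfile, block: str) -> Recording:
        return simulate_block(profile, block, self.config)

    def iter_recordings(self) -> Iterator[tuple[ParticipantProfile, str, Recording]]:
        for p in self.profiles:
            for block in BLOCKS:
                yield p, block, self.recording(p, block)

    def participant_frame(self) -> pd.DataFrame:
        """Participant table with split memory subtest scores.

        The two WMS-style subtest percentages are emitted so that their mean
        reproduces the participant's memory index exactly.
        """
        rng = np.random.default_rng(
            np.random.SeedSequence((self.config.seed, 3)))
        rows = []
        for p in self.profiles:
            half_gap = rng.normal(0.0, 4.0)
            limit = min(p.memory_score, 100.0 - p.memory_score)
            half_gap = float(np.clip(half_gap, -limit, limit))
            rows.append({
                "participant_id": p.id,
                "genotype": p.genotype,
                "faces_pct": p.memory_score + half_gap,
                "family_pictures_pct": p.memory_score - half_gap,
                "tetanized_orientation": p.tetanized_orientation,
                "true_early_ltp": p.true_early_ltp,
                "true_late_ltp": p.true_late_ltp,
            })
        return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig | None = None) -> CohortSim:
    """Draw a cohort of participant profiles under the configured conditions.

    True effects are the genotype mean shift plus a Gaussian participant
    deviation; tetanized orientation is counterbalanced to within one
    participant; memory indices correlate with the late potentiation score
    (the negated late shift) at the configured target.
    """
    config = config if config is not None else SimulationConfig()
    config.validate()
    rng = _cohort_rng(config.seed)
    genotypes = [g for g, n in zip(GENOTYPES, config.group_sizes)
                 for _ in range(n)]
    n = len(genotypes)
    dev_early = rng.normal(0.0, config.participant_sd, size=n)
    dev_late = rng.normal(0.0, config.participant_sd, size=n)
    true_early = np.array([config.genotype_early_effect[g] for g in genotypes]) + dev_early
    true_late = np.array([config.genotype_late_effect[g] for g in genotypes]) + dev_late
    orient = [ORIENTATIONS[i % 2] for i in range(n)]
    perm = rng.permutation(n)
    orient = [orient[i] for i in perm]
    memory = generate_memory_scores(
        -true_late, config.target_memory_correlation, _memory_rng(config.seed),
        mean=config.memory_mean, sd=config.memory_sd)
    profiles = [
        ParticipantProfile(
            id=f"S{i + 1:02d}", genotype=genotypes[i],
            true_early_ltp=float(true_early[i]),
            true_late_ltp=float(true_late[i]),
            memory_score=float(memory[i]),
            tetanized_orientation=orient[i], index=i)
        for i in range(n)
    ]
    return CohortSim(profiles=profiles, config=config)


def simulate_ltp_table(config: SimulationConfig | None = None,
                       measurement_sd: float = 0.15) -> pd.DataFrame:
    """Participant-level LTP scores as the EEG pipeline would measure them.

    The score convention is pre minus post (positive = potentiation), i.e.
    the negated true shift, plus measurement noise standing for the residual
    error of block-averaged N1b amplitudes (default 0.15 uV, the scale left
    by averaging ~240 epochs of a few-microvolt background).  Used for
    statistics-level replication without paying for continuous EEG.
    """
    sim = simulate_cohort(config)
    cfg = sim.config
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 4)))
    rows = []
    for p in sim.profiles:
        rows.append({
            "participant_id": p.id,
            "genotype": p.genotype,
            "early_ltp": -p.true_early_ltp + rng.normal(0.0, measurement_sd),
            "late_ltp": -p.true_late_ltp + rng.normal(0.0, measurement_sd),
            "memory": p.memory_score,
        })
    return pd.DataFrame(rows)


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["group_sizes"] = list(d["group_sizes"])
    d["isi_range_ms"] = list(d["isi_range_ms"])
    return d
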