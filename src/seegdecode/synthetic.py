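"""Synthetic sEEG session generator with planted class-covariance structure.

Emulates a grasping experiment: cued 3 s move / 3 s rest trials, 30 cues per
hand, recorded on tens of depth-electrode contacts. The class signal is a
second-moment (covariance) difference of band-limited latent sources — beta
(12-30 Hz) power is suppressed and high-gamma (55-90 Hz) power enhanced during
movement, mixed into channels through a random matrix — which is exactly the
structure a covariance-based Riemannian decoder can exploit. Line noise at
50 Hz and harmonics, a minority of artifact channels, and anatomical labels
(some motor/central) are added so the QC stage has something to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

BETA_BAND = (12.0, 30.0)
HIGH_GAMMA_BAND = (55.0, 90.0)
LINE_FREQS = (50.0, 100.0, 150.0, 200.0)

# Destrieux-style anatomical labels; non-motor pool mirrors the mix of grey
# matter, white matter and unresolved locations typical of clinical sEEG.
_NON_MOTOR_LABELS = (
    "S_temporal_sup",
    "G_temp_sup-Lateral",
    "G_front_middle",
    "S_circular_insula_sup",
    "G_insular_short",
    "G_pariet_inf-Supramar",
    "G_oc-temp_med-Parahip",
    "G_hippocampus",
    "S_front_inf",
    "G_cingul-Post-dorsal",
    "white matter",
    "white matter",
    "Unknown",
)
_MOTOR_LABELS = (
    "G_precentral",
    "G_postcentral",
    "S_central",
    "G_and_S_paracentral",
    "S_precentral-inf-part",
)


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one synthetic recording session.

    Defaults follow the study protocol: 3 s move / 3 s rest blocks, 30 cues
    per hand per task, executed and imagined tasks run back to back, channel
    counts in the clinical 42-125 range, 1024 Hz sampling.
    """

    participant_id: str = "sub-01"
    n_channels: int = 64
    sampling_rate_hz: float = 1024.0
    n_trials_per_hand: int = 30
    trial_duration_s: float = 3.0
    rest_duration_s: float = 3.0
    snr_move: float = 4.0
    n_latent: int = 5
    line_noise_amp: float = 1.0
    n_bad_line_channels: int = 2
    n_bad_amp_channels: int = 1
    motor_label_fraction: float = 0.1
    seed: int = 0
    tasks: tuple[str, ...] = ("executed", "imagined")

    def __post_init__(self) -> None:
        if not (5 <= self.n_channels <= 256):
            raise ValueError("n_channels must be within [5, 256]")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.trial_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValueError("trial and rest durations must be positive")
        if self.n_trials_per_hand < 1:
            raise ValueError("n_trials_per_hand must be positive")
        if self.snr_move < 0:
            raise ValueError("snr_move must be nonnegative")
        if self.n_latent < 1:
            raise ValueError("n_latent must be positive")
        if self.line_noise_amp < 0:
            raise ValueError("line_noise_amp must be nonnegative")
        if self.n_bad_line_channels < 0 or self.n_bad_amp_channels < 0:
            raise ValueError("bad-channel counts must be nonnegative")
        if self.n_bad_line_channels + self.n_bad_amp_channels >= self.n_channels:
            raise ValueError("bad channels must not exhaust the montage")
        if not 0.0 <= self.motor_label_fraction <= 1.0:
            raise ValueError("motor_label_fraction must be in [0, 1]")
        if not self.tasks or any(t not in ("executed", "imagined") for t in self.tasks):
            raise ValueError("tasks must be a nonempty subset of {executed, imagined}")


@dataclass
class Recording:
    """Continuous multichannel signal with channel metadata."""

    data: np.ndarray  # (n_channels, n_samples), arbitrary microvolt-scale units
    sampling_rate_hz: float
    channel_names: list[str]
    anatomical_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n_ch = self.data.shape[0]
        if len(self.channel_names) != n_ch or len(self.anatomical_labels) != n_ch:
            raise ValueError("channel metadata length must equal n_channels")
        if len(set(self.channel_names)) != n_ch:
            raise ValueError("channel_names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick(self, indices: np.ndarray) -> "Recording":
        """Sub-recording restricted to the given channel indices."""
        idx = np.asarray(indices, dtype=int)
        return Recording(
            data=self.data[idx].copy(),
            sampling_rate_hz=self.sampling_rate_hz,
            channel_names=[self.channel_names[i] for i in idx],
            anatomical_labels=[self.anatomical_labels[i] for i in idx],
        )


class EventTable(pd.DataFrame):
    """Cue table: one row per move or rest event.

    Columns: onset_sample (int), condition ('move'/'rest'), hand
    ('left'/'right'/'none'), task ('executed'/'imagined').
    """

    _metadata: list[str] = []

    @property
    def _constructor(self):
        return EventTable

    def validate(self, n_trials_per_hand: int | None = None) -> None:
        onsets = self["onset_sample"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        cond = self["condition"].to_numpy()
        move_rows = self[cond == "move"]
        rest_rows = self[cond == "rest"]
        if not (move_rows["hand"].isin(["left", "right"])).all():
            raise ValueError("move events must have hand left/right")
        if not (rest_rows["hand"] == "none").all():
            raise ValueError("rest events must have hand 'none'")
        # every move is followed by a rest
        cond_seq = list(cond)
        for i, c in enumerate(cond_seq):
            if c == "move" and (i + 1 >= len(cond_seq) or cond_seq[i + 1] != "rest"):
                raise ValueError("every move event must be followed by a rest event")
        if n_trials_per_hand is not None:
            for task in self["task"].unique():
                sub = self[self["task"] == task]
                n_move = int((sub["condition"] == "move").sum())
                n_rest = int((sub["condition"] == "rest").sum())
                if n_move != 2 * n_trials_per_hand or n_rest != 2 * n_trials_per_hand:
                    raise ValueError("unexpected move/rest counts per task")


@dataclass
class GroundTruth:
    """What the generator planted, for oracle-style tests."""

    mixing: np.ndarray  # (n_channels, n_latent)
    latent_cov_move: np.ndarray  # (n_latent, n_latent) diagonal
    latent_cov_rest: np.ndarray
    bad_line_channels: np.ndarray  # channel indices
    bad_amp_channels: np.ndarray
    motor_channels: np.ndarray
    source_bands: list[str]  # 'beta' or 'high_gamma' per latent source
    sources: np.ndarray = field(repr=False, default=None)  # (n_latent, n_samples)
    move_mask: np.ndarray = field(repr=False, default=None)  # bool per sample


def _bandlimited_noise(rng: np.random.Generator, n_samples: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to `band` (zero-phase FIR)."""
    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band {band} exceeds Nyquist ({nyq} Hz)")
    x = rng.standard_normal(n_samples)
    numtaps = int(4 * fs / lo) | 1  # enough taps to resolve the low edge
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    y = signal.filtfilt(taps, [1.0], x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _build_schedule(config: SessionConfig, rng: np.random.Generator,
                    fs: float) -> tuple[pd.DataFrame, int]:
    """Randomized cue order per task; returns the event table and total samples."""
    pad_start = int(round(2.0 * fs))
    pad_end = int(round(1.0 * fs))
    n_trial = int(round(config.trial_duration_s * fs))
    n_rest = int(round(config.rest_duration_s * fs))

    rows = []
    cursor = pad_start
    for task in config.tasks:
        hands = ["left"] * config.n_trials_per_hand + ["right"] * config.n_trials_per_hand
        rng.shuffle(hands)
        for hand in hands:
            rows.append((cursor, "move", hand, task))
            cursor += n_trial
            rows.append((cursor, "rest", "none", task))
            cursor += n_rest
    total = cursor + pad_end
    events = pd.DataFrame(rows, columns=["onset_sample", "condition", "hand", "task"])
    return events, total


def generate_session(config: SessionConfig) -> tuple[Recording, EventTable, GroundTruth]:
    """Generate one synthetic session.

    Generative model:

    1. latent sources: ``n_latent`` band-limited Gaussian oscillators,
       alternately assigned to the beta and high-gamma bands, unit variance
       at rest;
    2. during move epochs the beta sources are scaled by
       ``1/sqrt(1 + snr_move)`` and high-gamma sources by
       ``sqrt(1 + snr_move)`` — an event-related desynchronization /
       synchronization pattern that leaves a rank-``n_latent`` difference
       between the move and rest latent covariances (none when snr_move=0);
    3. sources are mixed into channels through a random Gaussian matrix with
       column scale ``1/sqrt(n_latent)`` and unit-variance white sensor noise
       is added;
    4. 50/100/150/200 Hz sinusoidal line noise (random phase per channel and
       harmonic) at ``line_noise_amp`` is added to every channel;
    5. ``n_bad_line_channels`` get 10x line-noise amplitude,
       ``n_bad_amp_channels`` get their entire signal scaled 5x;
    6. anatomical labels are drawn from a built-in Destrieux-style list;
       a ``motor_label_fraction`` of channels get labels containing
       "motor" or "central".

    Same seed => bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    for band in (BETA_BAND, HIGH_GAMMA_BAND):
        if band[1] >= fs / 2:
            raise ValueError(
                f"sampling_rate_hz={fs} cannot represent the {band} Hz band")

    events_df, n_samples = _build_schedule(config, rng, fs)

    # move-epoch mask over the whole session
    n_trial = int(round(config.trial_duration_s * fs))
    move_mask = np.zeros(n_samples, dtype=bool)
    for onset in events_df.loc[events_df["condition"] == "move", "onset_sample"]:
        move_mask[onset:onset + n_trial] = True

    # latent sources with class-dependent gain
    source_bands = ["beta" if i % 2 == 0 else "high_gamma"
                    for i in range(config.n_latent)]
    beta_gain = 1.0 / np.sqrt(1.0 + config.snr_move)
    hg_gain = np.sqrt(1.0 + config.snr_move)
    sources = np.empty((config.n_latent, n_samples))
    var_move = np.ones(config.n_latent)
    for i, band_name in enumerate(source_bands):
        band = BETA_BAND if band_name == "beta" else HIGH_GAMMA_BAND
        s = _bandlimited_noise(rng, n_samples, fs, band)
        gain = beta_gain if band_name == "beta" else hg_gain
        s[move_mask] *= gain
        var_move[i] = gain ** 2
        sources[i] = s

    latent_cov_rest = np.eye(config.n_latent)
    latent_cov_move = np.diag(var_move)

    mixing = rng.standard_normal((config.n_channels, config.n_latent))
    mixing /= np.sqrt(config.n_latent)
    data = mixing @ sources
    data += rng.standard_normal(data.shape)  # unit-variance sensor noise

    # line noise, random phase per channel/harmonic
    t = np.arange(n_samples) / fs
    n_bad_line = config.n_bad_line_channels
    n_bad_amp = config.n_bad_amp_channels
    perm = rng.permutation(config.n_channels)
    bad_line = np.sort(perm[:n_bad_line])
    bad_amp = np.sort(perm[n_bad_line:n_bad_line + n_bad_amp])
    line_scale = np.ones(config.n_channels)
    line_scale[bad_line] = 10.0
    if config.line_noise_amp > 0 or n_bad_line > 0:
        base = max(config.line_noise_amp, 0.0)
        if base == 0.0 and n_bad_line > 0:
            base = 0.5  # bad line channels still need 50 Hz content to flag
        for f in LINE_FREQS:
            if f >= fs / 2:
                continue
            phases = rng.uniform(0, 2 * np.pi, config.n_channels)
            data += (base * line_scale)[:, None] * np.sin(
                2 * np.pi * f * t[None, :] + phases[:, None])
    data[bad_amp] *= 5.0

    # anatomical labels
    n_motor = int(round(config.motor_label_fraction * config.n_channels))
    motor_channels = np.sort(rng.permutation(config.n_channels)[:n_motor])
    labels = [
        _NON_MOTOR_LABELS[int(rng.integers(len(_NON_MOTOR_LABELS)))]
        for _ in range(config.n_channels)
    ]
    for ch in motor_channels:
        labels[ch] = _MOTOR_LABELS[int(rng.integers(len(_MOTOR_LABELS)))]

    names = [f"{config.participant_id}-ch{i:03d}" for i in range(config.n_channels)]
    recording = Recording(data=data, sampling_rate_hz=fs,
                          channel_names=names, anatomical_labels=labels)
    events = EventTable(events_df)
    events.validate(config.n_trials_per_hand)
    truth = GroundTruth(
        mixing=mixing,
        latent_cov_move=latent_cov_move,
        latent_cov_rest=latent_cov_rest,
        bad_line_channels=bad_line,
        bad_amp_channels=bad_amp,
        motor_channels=motor_channels,
        source_bands=source_bands,
        sources=sources,
        move_mask=move_mask,
    )
    return recording, events, truth


def generate_cohort(
    n_participants: int,
    base_seed: int,
    channel_range: tuple[int, int] = (42, 125),
    **config_overrides,
) -> list[tuple[SessionConfig, Recording, EventTable, GroundTruth]]:
    """Generate a cohort of sessions with per-participant channel counts.

    Channel counts are drawn uniformly from ``channel_range`` (default the
    clinical 42-125 contacts) and per-participant seeds derive
    deterministically from ``base_seed``. Extra keyword arguments override
    SessionConfig fields for every participant.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    rng = np.random.default_rng(base_seed)
    cohort = []
    for p in range(n_participants):
        n_ch = int(rng.integers(channel_range[0], channel_range[1] + 1))
        seed = int(rng.integers(2 ** 31))
        cfg_kwargs = dict(
            participant_id=f"sub-{p + 1:02d}",
            n_channels=n_ch,
            seed=seed,
        )
        cfg_kwargs.update(config_overrides)
        config = SessionConfig(**cfg_kwargs)
        rec, events, truth = generate_session(config)
        cohort.append((config, rec, events, truth))
    return cohort
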