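"""Filtering, Hilbert envelopes, and epoching.

Retained channels are detrended, demeaned and notch-filtered at 50 Hz and
harmonics up to 200 Hz (zero-phase FIR, via MNE). Band-limited amplitude
envelopes are the magnitude of the analytic signal of the band-passed data:
beta 12-30 Hz and high-gamma 55-90 Hz, the two canonical movement-related
bands (beta desynchronizes, high-gamma synchronizes during movement).
Envelopes are cut into fixed-length trials at cue onsets; left- and
right-hand trials are merged into a single movement class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from mne.filter import filter_data, notch_filter
from scipy import fft as sp_fft
from scipy import signal

from .synthetic import EventTable, Recording

#: band name -> (low, high) Hz
BANDS: dict[str, tuple[float, float]] = {
    "beta": (12.0, 30.0),
    "high_gamma": (55.0, 90.0),
}
NOTCH_FREQS = (50.0, 100.0, 150.0, 200.0)


@dataclass
class EpochSet:
    """Trials x channels x samples array with per-trial class labels."""

    data: np.ndarray  # (n_trials, n_channels, n_samples_per_trial)
    labels: np.ndarray  # 'move' / 'rest' per trial
    band: str  # 'beta', 'high_gamma' or 'beta_plus_high_gamma'
    sampling_rate_hz: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def binary_labels(self) -> np.ndarray:
        """move=1, rest=0."""
        return (self.labels == "move").astype(int)


def clean_filter(recording: Recording) -> Recording:
    """Detrend, demean, and notch out line noise and harmonics.

    Per channel: remove the linear trend (which also removes the mean), then
    zero-phase FIR band-stop at 50/100/150/200 Hz with +/-2 Hz notch width.
    Notches at or above Nyquist are skipped with a warning.
    """
    fs = recording.sampling_rate_hz
    data = signal.detrend(recording.data, axis=-1, type="linear")
    data -= data.mean(axis=-1, keepdims=True)

    freqs = [f for f in NOTCH_FREQS if f < fs / 2 - 2.0]
    if len(freqs) < len(NOTCH_FREQS):
        warnings.warn(
            f"sampling rate {fs} Hz too low for all notches; applying {freqs}")
    if freqs:
        data = notch_filter(
            data, Fs=fs, freqs=freqs, notch_widths=4.0,
            trans_bandwidth=2.0, phase="zero", fir_design="firwin",
            verbose="error",
        )
    return Recording(
        data=data,
        sampling_rate_hz=fs,
        channel_names=list(recording.channel_names),
        anatomical_labels=list(recording.anatomical_labels),
    )


def band_envelope(recording: Recording, band: str) -> Recording:
    """Band-pass then take the magnitude of the analytic signal.

    ``band`` is 'beta' (12-30 Hz) or 'high_gamma' (55-90 Hz). Output is
    nonnegative with the same shape as the input.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    fs = recording.sampling_rate_hz
    if hi >= fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist for fs={fs}")
    filtered = filter_data(
        recording.data, sfreq=fs, l_freq=lo, h_freq=hi,
        phase="zero", fir_design="firwin",
        l_trans_bandwidth=0.25 * lo, h_trans_bandwidth=0.25 * hi,
        verbose="error",
    )
    n = recording.n_samples
    nfast = sp_fft.next_fast_len(n)
    env = np.abs(signal.hilbert(filtered, N=nfast, axis=-1)[..., :n])
    return Recording(
        data=env,
        sampling_rate_hz=fs,
        channel_names=list(recording.channel_names),
        anatomical_labels=list(recording.anatomical_labels),
    )


def epoch(
    envelopes: Recording | dict[str, Recording],
    events: EventTable,
    band: str,
    trial_duration_s: float = 3.0,
    task: str | None = None,
) -> EpochSet:
    """Cut envelope recordings into per-cue trials.

    For ``band='beta_plus_high_gamma'`` pass a dict with both envelope
    recordings; the two are stacked along the channel axis (beta block first).
    Left- and right-hand move trials are merged into one movement class.
    Events whose window does not fit the recording are dropped with a warning.
    """
    if band == "beta_plus_high_gamma":
        if not isinstance(envelopes, dict):
            raise ValueError("beta_plus_high_gamma requires both envelope recordings")
        recs = [envelopes["beta"], envelopes["high_gamma"]]
    else:
        rec = envelopes[band] if isinstance(envelopes, dict) else envelopes
        recs = [rec]
    fs = recs[0].sampling_rate_hz
    n_keep = int(round(trial_duration_s * fs))

    ev = events if task is None else events[events["task"] == task]
    trials, labels = [], []
    n_dropped = 0
    for _, row in ev.iterrows():
        onset = int(row["onset_sample"])
        if onset < 0 or onset + n_keep > recs[0].n_samples:
            n_dropped += 1
            continue
        segs = [r.data[:, onset:onset + n_keep] for r in recs]
        trials.append(np.concatenate(segs, axis=0))
        labels.append("move" if row["condition"] == "move" else "rest")
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} events outside the recording")
    if not trials:
        raise ValueError("no events fall inside the recording")

    if band == "beta_plus_high_gamma":
        names = ([f"{n}_beta" for n in recs[0].channel_names]
                 + [f"{n}_hg" for n in recs[1].channel_names])
    else:
        names = list(recs[0].channel_names)
    return EpochSet(
        data=np.stack(trials),
        labels=np.asarray(labels),
        band=band,
        sampling_rate_hz=fs,
        channel_names=names,
    )
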