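"""Channel quality control: motor-label exclusion and noise flagging.

The analysis deliberately decodes from non-motor areas only, so any contact
whose anatomical label mentions "motor" or "central" (which also catches
precentral / postcentral / paracentral) is excluded first. Remaining channels
are screened for excess 50 Hz line-noise power and for abnormal overall
amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy import stats as sps

from .synthetic import Recording

#: one-sided z threshold for p < 0.05 under a normal assumption
_AMPLITUDE_Z = float(sps.norm.ppf(0.95))


@dataclass
class QCReport:
    """Outcome of channel QC on one recording."""

    excluded_motor: list[str]
    flagged_line_noise: list[str]
    flagged_amplitude: list[str]
    retained: list[str]

    def to_text(self) -> str:
        lines = ["channel\tstatus"]
        for name in self.excluded_motor:
            lines.append(f"{name}\texcluded:motor_label")
        for name in self.flagged_line_noise:
            lines.append(f"{name}\tflagged:line_noise")
        for name in self.flagged_amplitude:
            lines.append(f"{name}\tflagged:amplitude")
        for name in self.retained:
            lines.append(f"{name}\tretained")
        return "\n".join(lines) + "\n"


def exclude_motor_contacts(labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Split channel indices by the motor-label rule.

    A channel is removed when its anatomical label contains, case-
    insensitively, the substring "motor" or "central". Returns
    (kept_indices, removed_indices).
    """
    if len(labels) == 0:
        raise ValueError("empty label list")
    removed = [i for i, lab in enumerate(labels)
               if "motor" in lab.lower() or "central" in lab.lower()]
    kept = [i for i in range(len(labels)) if i not in set(removed)]
    return np.asarray(kept, dtype=int), np.asarray(removed, dtype=int)


def _line_band_power(recording: Recording, line_freq: float = 50.0,
                     half_width: float = 2.0) -> np.ndarray:
    """Per-channel Welch PSD integrated over line_freq +/- half_width."""
    fs = recording.sampling_rate_hz
    nperseg = min(int(4 * fs), recording.n_samples)
    freqs, psd = signal.welch(recording.data, fs=fs, nperseg=nperseg, axis=-1)
    band = (freqs >= line_freq - half_width) & (freqs <= line_freq + half_width)
    return np.trapezoid(psd[:, band], freqs[band], axis=-1)


def flag_line_noise(recording: Recording, line_freq: float = 50.0) -> list[str]:
    """Flag channels with excess 50 Hz band power.

    A channel is flagged when its 50 +/- 2 Hz Welch band power strictly
    exceeds Q3 + 2*IQR of the cross-channel power distribution — a robust
    upper fence on the line-noise contamination.
    """
    if recording.sampling_rate_hz <= 2.4 * line_freq:
        raise ValueError("sampling rate too low to resolve the line frequency")
    if recording.n_channels < 4:
        warnings.warn("fewer than 4 channels: IQR undefined, not flagging")
        return []
    power = _line_band_power(recording, line_freq)
    q1, q3 = np.percentile(power, [25, 75])
    fence = q3 + 2.0 * (q3 - q1)
    flagged = np.nonzero(power > fence)[0]
    return [recording.channel_names[i] for i in flagged]


def flag_amplitude_outliers(recording: Recording) -> list[str]:
    """Flag channels whose log mean-square amplitude is abnormally high.

    Per channel compute log(mean(signal^2)), z-score across channels (sample
    standard deviation), and flag one-sided p < 0.05 under a normal
    assumption (z > 1.6449).
    """
    if recording.n_channels < 2:
        raise ValueError("need at least 2 channels for amplitude screening")
    ms = np.mean(recording.data ** 2, axis=-1)
    if np.any(ms == 0):
        # silent channels carry no amplitude excess; exclude from the
        # distribution but never flag them here
        ms = np.where(ms == 0, np.nan, ms)
    with np.errstate(invalid="ignore"):
        logp = np.log(ms)
    mu = np.nanmean(logp)
    sd = np.nanstd(logp, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return []
    z = (logp - mu) / sd
    flagged = np.nonzero(z > _AMPLITUDE_Z)[0]
    return [recording.channel_names[i] for i in flagged]


def run_qc(recording: Recording) -> tuple[Recording, QCReport]:
    """Full QC pass: motor exclusion first, then noise flags on the rest.

    Returns the retained sub-recording and the report. Raises if no channel
    survives.
    """
    kept, removed = exclude_motor_contacts(recording.anatomical_labels)
    if kept.size == 0:
        raise ValueError("no channels remain after motor-label exclusion")
    motor_names = [recording.channel_names[i] for i in removed]
    sub = recording.pick(kept)

    line_names = flag_line_noise(sub) if sub.n_channels >= 4 else []
    amp_names = flag_amplitude_outliers(sub) if sub.n_channels >= 2 else []
    bad = set(line_names) | set(amp_names)
    retained_idx = [i for i, name in enumerate(sub.channel_names) if name not in bad]
    if not retained_idx:
        raise ValueError("no channels remain after noise flagging")
    retained = sub.pick(np.asarray(retained_idx))
    report = QCReport(
        excluded_motor=motor_names,
        flagged_line_noise=line_names,
        flagged_amplitude=sorted(set(amp_names) - set(line_names)),
        retained=list(retained.channel_names),
    )
    return retained, report
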