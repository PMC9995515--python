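"""Preprocessing: band-pass filtering, common-average re-referencing,
two-second epoching, and the two quantitative artifact criteria
(absolute-amplitude epoch rejection and >k-SD spectral-power exclusion).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import signal

from .recording import EpochSet, Recording

#: Zero-phase filtering applies the filter forward and backward, so the
#: effective attenuation is double this per-pass order. Order 8 puts a 60 Hz
#: line component at <10% of its input RMS through the 1-50 Hz band-pass.
FILTER_ORDER = 8

DEFAULT_AMPLITUDE_THRESHOLD_UV = 75.0
DEFAULT_SD_THRESHOLD = 3.0


def bandpass(recording: Recording, low: float = 1.0, high: float = 50.0) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Raises ValueError unless 0 < low < high < Nyquist.
    """
    nyquist = recording.sample_rate / 2.0
    if not 0 < low < high < nyquist:
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for sample rate "
            f"{recording.sample_rate} Hz"
        )
    sos = signal.butter(FILTER_ORDER, [low, high], btype="bandpass",
                        fs=recording.sample_rate, output="sos")
    return recording.with_data(signal.sosfiltfilt(sos, recording.data, axis=-1))


def rereference_car(recording: Recording) -> Recording:
    """Common average reference: subtract the instantaneous cross-channel mean."""
    if recording.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    return recording.with_data(recording.data - recording.data.mean(axis=0))


def make_epochs(recording: Recording, epoch_length: float = 2.0) -> EpochSet:
    """Slice into consecutive non-overlapping epochs; drop the trailing partial."""
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    n_per_epoch = int(round(epoch_length * recording.sample_rate))
    n_epochs = recording.n_samples // n_per_epoch
    if n_epochs < 1:
        raise ValueError(
            f"recording duration {recording.duration:.3f} s shorter than one "
            f"{epoch_length} s epoch"
        )
    trimmed = recording.data[:, : n_epochs * n_per_epoch]
    epochs = trimmed.reshape(recording.n_channels, n_epochs, n_per_epoch)
    return EpochSet(
        subject_id=recording.subject_id,
        group=recording.group,
        condition=recording.condition,
        sample_rate=recording.sample_rate,
        channel_labels=recording.channel_labels,
        epoch_length=epoch_length,
        epochs=np.ascontiguousarray(epochs.transpose(1, 0, 2)),
    )


def reject_amplitude(epochs: EpochSet,
                     threshold: float = DEFAULT_AMPLITUDE_THRESHOLD_UV) -> EpochSet:
    """Mark epochs whose absolute amplitude exceeds ``threshold`` on any channel.

    If every epoch is rejected the subject x condition is flagged excluded
    (``exclusion_flags['amplitude']``).
    """
    if threshold <= 0:
        raise ValueError("amplitude threshold must be positive")
    over = np.abs(epochs.epochs).max(axis=(1, 2)) > threshold
    rejected = epochs.rejected | over
    flags = dict(epochs.exclusion_flags)
    flags["amplitude"] = bool(rejected.all())
    return replace(epochs, rejected=rejected, exclusion_flags=flags)


def exclude_power_outliers(total_power: pd.DataFrame,
                           sd_threshold: float = DEFAULT_SD_THRESHOLD) -> pd.DataFrame:
    """Per-condition >k-SD spectral-power exclusion mask.

    ``total_power`` is tidy with columns subject_id, group, condition, power
    (total 1-50 Hz absolute power, channel-averaged). A subject x condition is
    excluded when its power deviates more than ``sd_threshold`` standard
    deviations from its group's mean for that condition; the exclusion is
    per-condition only. Returns the table with an added boolean ``included``
    column; the input is not modified.

    Raises ValueError when any group x condition has fewer than 3 subjects
    (the group SD is degenerate).
    """
    required = {"subject_id", "group", "condition", "power"}
    missing = required - set(total_power.columns)
    if missing:
        raise ValueError(f"total_power table missing columns: {sorted(missing)}")
    out = total_power.copy()
    out["included"] = True
    for (_, _), idx in out.groupby(["group", "condition"]).groups.items():
        vals = out.loc[idx, "power"].to_numpy(dtype=float)
        if len(vals) < 3:
            raise ValueError(
                "power-outlier exclusion needs >= 3 subjects per group x condition"
            )
        sd = vals.std(ddof=1)
        if sd == 0:
            continue  # identical powers: zero deviation, nobody excluded
        z = np.abs(vals - vals.mean()) / sd
        out.loc[idx, "included"] = z <= sd_threshold
    return out


def preprocess_recording(recording: Recording, *, low: float = 1.0,
                         high: float = 50.0, car: bool = True,
                         epoch_length: float = 2.0,
                         amp_threshold: float = DEFAULT_AMPLITUDE_THRESHOLD_UV) -> EpochSet:
    """Full per-recording chain: band-pass -> CAR -> epoch -> amplitude rejection."""
    rec = bandpass(recording, low, high)
    if car:
        rec = rereference_car(rec)
    return reject_amplitude(make_epochs(rec, epoch_length), amp_threshold)
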