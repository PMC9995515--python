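"""Spectral power features: per-epoch FFT power spectra, absolute and relative
band powers, eyes-closed/eyes-open reactivity, and channel averaging.

The per-epoch spectrum is a mean-removed, untapered periodogram scaled so that
the bins sum exactly to the epoch's (population) variance — Parseval holds per
realization, and a bin-centred sinusoid lands entirely in its own bin. A unit
amplitude sinusoid therefore carries 0.5 uV^2 in a single bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import ANALYSIS_HIGH_HZ, ANALYSIS_LOW_HZ, BandDefinition, DEFAULT_BANDS
from .recording import EpochSet


def epoch_psd(epoch: np.ndarray, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Power spectrum of one epoch.

    Parameters
    ----------
    epoch
        (n_channels, n_samples) or (n_samples,) array in microvolts.
    sample_rate
        Sampling rate in Hz. A 2 s epoch gives 0.5 Hz frequency resolution.

    Returns
    -------
    freqs, power
        ``freqs`` (n_bins,) in Hz and ``power`` (..., n_bins) in uV^2 per bin,
        with ``power.sum(-1)`` equal to the per-channel variance (ddof=0).
    """
    was_1d = np.asarray(epoch).ndim == 1
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if not np.all(np.isfinite(epoch)):
        raise ValueError("epoch contains non-finite samples")
    n = epoch.shape[-1]
    x = epoch - epoch.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(x, axis=-1)
    power = (np.abs(spec) ** 2) / n**2
    # one-sided: double every bin that has a negative-frequency twin
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0  # Nyquist bin is unique
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return freqs, power[0] if was_1d else power


def band_powers(freqs: np.ndarray, power: np.ndarray,
                bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> dict[str, np.ndarray]:
    """Sum spectrum bins into absolute band powers, half-open [f_low, f_high).

    Bands must lie within the 1-50 Hz analysis range.
    """
    out: dict[str, np.ndarray] = {}
    for band in bands:
        if band.f_low < ANALYSIS_LOW_HZ - 1e-9 or band.f_high > ANALYSIS_HIGH_HZ + 1e-9:
            raise ValueError(
                f"band {band.name!r} [{band.f_low}, {band.f_high}) outside the "
                f"analyzed range [{ANALYSIS_LOW_HZ}, {ANALYSIS_HIGH_HZ})"
            )
        sel = (freqs >= band.f_low) & (freqs < band.f_high)
        out[band.name] = np.asarray(power)[..., sel].sum(axis=-1)
    return out


def average_band_powers(per_epoch: np.ndarray) -> np.ndarray:
    """Arithmetic mean over retained epochs (axis 0); errors on zero epochs."""
    per_epoch = np.asarray(per_epoch, dtype=float)
    if per_epoch.shape[0] == 0:
        raise ValueError("no retained epochs to average (subject excluded upstream)")
    return per_epoch.mean(axis=0)


def relative_power(absolute: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Band power as a fraction of the total 1-50 Hz power; fractions sum to 1."""
    total = sum(absolute.values())
    if np.any(np.asarray(total) <= 0):
        raise ValueError("total band power must be positive")
    return {name: np.asarray(p) / total for name, p in absolute.items()}


def reactivity(ec_power, eo_power):
    """EEG reactivity: (EC - EO) / EC band power.

    Positive when the band (classically alpha) is suppressed on eye opening;
    bounded above by 1, negative when EO power exceeds EC power.
    """
    ec = np.asarray(ec_power, dtype=float)
    eo = np.asarray(eo_power, dtype=float)
    if np.any(ec <= 0):
        raise ValueError("eyes-closed band power must be positive")
    out = (ec - eo) / ec
    return float(out) if out.ndim == 0 else out


def channel_average(values) -> float:
    """Unweighted mean of a per-channel feature; the subject's scalar summary."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty channel set")
    return float(values.mean())


def epochset_band_powers(epochs: EpochSet,
                         bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> pd.DataFrame:
    """Per-channel absolute and relative band powers for one subject x condition.

    Power spectra are computed per retained epoch, absolute band powers
    averaged across epochs, and relative powers formed from the averages.
    Returns a tidy frame: subject_id, group, condition, channel, band,
    absolute_power, relative_power, n_epochs.
    """
    retained = epochs.retained
    if retained.shape[0] == 0:
        raise ValueError(
            f"{epochs.subject_id}/{epochs.condition}: no retained epochs"
        )
    freqs, power = epoch_psd(
        retained.reshape(-1, retained.shape[-1]), epochs.sample_rate
    )
    power = power.reshape(retained.shape[0], retained.shape[1], -1)
    abs_bands = {
        name: average_band_powers(p)  # (n_channels,)
        for name, p in band_powers(freqs, power, bands).items()
    }
    rel_bands = relative_power(abs_bands)
    rows = []
    for b in bands:
        for ci, ch in enumerate(epochs.channel_labels):
            rows.append(
                (epochs.subject_id, epochs.group, epochs.condition, ch, b.name,
                 abs_bands[b.name][ci], rel_bands[b.name][ci], retained.shape[0])
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "condition", "channel", "band",
                 "absolute_power", "relative_power", "n_epochs"],
    )
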