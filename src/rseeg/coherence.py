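"""Magnitude-squared coherence (MSC) between EEG channels.

C_xy(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f)), with auto- and cross-spectra
estimated by Welch averaging of mean-corrected, Hann-tapered periodograms over
the retained two-second epochs (no overlap). With a single segment the
estimator is identically 1, so at least two segments are required. For
independent signals its expected value is approximately 1/L for L segments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import BandDefinition, DEFAULT_BANDS
from .recording import EpochSet


def _segment_ffts(segments: np.ndarray) -> np.ndarray:
    """Hann-tapered, mean-corrected rFFT of (n_seg, ..., n_samples) segments."""
    from scipy.signal import get_window

    x = segments - segments.mean(axis=-1, keepdims=True)
    window = get_window("hann", x.shape[-1])  # periodic, the Welch convention
    return np.fft.rfft(x * window, axis=-1)


def _epochize(x: np.ndarray, n_per_seg: int) -> np.ndarray:
    n_seg = x.shape[-1] // n_per_seg
    return x[..., : n_seg * n_per_seg].reshape(*x.shape[:-1], n_seg, n_per_seg)


def msc(x: np.ndarray, y: np.ndarray, sample_rate: float,
        segment_length: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence of two equal-length signals.

    Returns (freqs, coherence); coherence lies in [0, 1] at every frequency.
    Raises ValueError with fewer than two segments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    n_per_seg = int(round(segment_length * sample_rate))
    n_seg = x.shape[-1] // n_per_seg
    if n_seg < 2:
        raise ValueError(
            f"need >= 2 segments of {segment_length} s; got {n_seg} "
            "(single-segment coherence is identically 1)"
        )
    zx = _segment_ffts(_epochize(x, n_per_seg))
    zy = _segment_ffts(_epochize(y, n_per_seg))
    pxx = (zx * zx.conj()).real.mean(axis=0)
    pyy = (zy * zy.conj()).real.mean(axis=0)
    pxy = (zx * zy.conj()).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (np.abs(pxy) ** 2) / (pxx * pyy)
    c = np.nan_to_num(c, nan=0.0).clip(0.0, 1.0)
    freqs = np.fft.rfftfreq(n_per_seg, d=1.0 / sample_rate)
    return freqs, c


def band_coherence(freqs: np.ndarray, coherence: np.ndarray,
                   band: BandDefinition) -> float:
    """Unweighted mean of C(f) over bins with f_low <= f < f_high."""
    sel = (np.asarray(freqs) >= band.f_low) & (np.asarray(freqs) < band.f_high)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band.name!r}")
    return float(np.asarray(coherence)[..., sel].mean(axis=-1))


def coherence_matrix(epochs: EpochSet, band: BandDefinition) -> pd.DataFrame:
    """Band-averaged MSC between all channel pairs of one subject x condition.

    Welch segments are the retained epochs. Returns a symmetric channels x
    channels DataFrame with unit diagonal, labelled by channel.
    """
    retained = epochs.retained  # (n_seg, n_ch, n_samp)
    if retained.shape[1] < 2:
        raise ValueError("coherence needs >= 2 channels")
    if retained.shape[0] < 2:
        raise ValueError("coherence needs >= 2 retained epochs")
    z = _segment_ffts(retained)  # (n_seg, n_ch, n_freq)
    freqs = np.fft.rfftfreq(retained.shape[-1], d=1.0 / epochs.sample_rate)
    sel = (freqs >= band.f_low) & (freqs < band.f_high)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band.name!r}")
    z = z[..., sel]
    cross = np.einsum("eaf,ebf->abf", z, z.conj()) / z.shape[0]
    auto = np.real(np.einsum("eaf,eaf->af", z, z.conj())) / z.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (np.abs(cross) ** 2) / (auto[:, None, :] * auto[None, :, :])
    c = np.nan_to_num(c, nan=0.0).clip(0.0, 1.0).mean(axis=-1)
    np.fill_diagonal(c, 1.0)
    c = (c + c.T) / 2.0  # enforce exact symmetry against round-off
    return pd.DataFrame(c, index=list(epochs.channel_labels),
                        columns=list(epochs.channel_labels))


def lower_triangle_mean(matrix: pd.DataFrame | np.ndarray) -> float:
    """Mean of strictly-below-diagonal entries of a square coherence matrix."""
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    n = values.shape[0]
    if values.ndim != 2 or values.shape[1] != n:
        raise ValueError("coherence matrix must be square")
    if n < 2:
        raise ValueError("lower-triangle mean needs >= 2 channels")
    rows, cols = np.tril_indices(n, k=-1)
    return float(values[rows, cols].mean())


def epochset_band_coherences(epochs: EpochSet,
                             bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> pd.DataFrame:
    """Tidy channel-pair coherence for all bands of one subject x condition.

    One row per unordered channel pair (lower-triangle) per band:
    subject_id, group, condition, band, ch_a, ch_b, coherence, n_segments.
    """
    labels = list(epochs.channel_labels)
    rows, cols = np.tril_indices(len(labels), k=-1)
    frames = []
    for band in bands:
        mat = coherence_matrix(epochs, band).to_numpy()
        frames.append(pd.DataFrame({
            "subject_id": epochs.subject_id,
            "group": epochs.group,
            "condition": epochs.condition,
            "band": band.name,
            "ch_a": [labels[r] for r in rows],
            "ch_b": [labels[c] for c in cols],
            "coherence": mat[rows, cols],
            "n_segments": epochs.n_retained,
        }))
    return pd.concat(frames, ignore_index=True)
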