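"""In-memory containers for multichannel EEG recordings and epoched data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Default 31-channel scalp montage (10-20 extended labels). The study montage
#: is a 31-electrode actiCap layout; Cz is omitted from the standard 32-label
#: set to keep every lateral pair and the midline Fz/Pz/Oz electrodes.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "FT9", "FT10", "FC1", "FC2", "FC5", "FC6",
    "T7", "T8", "C3", "C4",
    "TP9", "TP10", "CP1", "CP2", "CP5", "CP6",
    "P3", "P4", "P7", "P8", "Pz",
    "O1", "O2", "Oz",
)

GROUPS: tuple[str, ...] = ("never", "past", "smoker")
CONDITIONS: tuple[str, ...] = ("EC", "EO")


@dataclass
class Recording:
    """One subject x condition multichannel EEG signal.

    data is (n_channels, n_samples) in microvolts. The sampling rate must
    exceed twice the 50 Hz analysis-band edge.
    """

    subject_id: str
    group: str
    condition: str
    sample_rate: float
    channel_labels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sample_rate <= 100.0:
            raise ValueError(
                "sample_rate must exceed 100 Hz (Nyquist for the 1-50 Hz band)"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one Recording, with rejection bookkeeping.

    ``epochs`` keeps every epoch (including rejected ones) so that the trimmed
    parent signal can be reconstructed exactly; ``rejected`` marks epochs
    excluded from all downstream averaging.
    """

    subject_id: str
    group: str
    condition: str
    sample_rate: float
    channel_labels: tuple[str, ...]
    epoch_length: float
    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    rejected: np.ndarray = field(default=None)  # bool (n_epochs,)
    exclusion_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x channel x sample)")
        if self.rejected is None:
            self.rejected = np.zeros(self.epochs.shape[0], dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def retained(self) -> np.ndarray:
        """Epochs not marked rejected, (n_retained, channels, samples)."""
        return self.epochs[~self.rejected]

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    @property
    def rejected_epoch_indices(self) -> np.ndarray:
        return np.flatnonzero(self.rejected)

    @property
    def is_excluded(self) -> bool:
        return self.n_retained == 0 or any(self.exclusion_flags.values())
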