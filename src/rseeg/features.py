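"""Cohort-level feature extraction: recordings -> tidy feature tables.

Runs the per-recording preprocessing chain (1-50 Hz band-pass, CAR,
two-second epochs, amplitude rejection), computes per-channel band powers and
channel-pair coherences, applies the per-condition spectral-power outlier
exclusion, and derives EC/EO reactivity for subjects retained in both
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BandDefinition, DEFAULT_BANDS
from .coherence import epochset_band_coherences
from .preprocess import (DEFAULT_AMPLITUDE_THRESHOLD_UV, DEFAULT_SD_THRESHOLD,
                         exclude_power_outliers, preprocess_recording)
from .recording import Recording
from .spectral import epochset_band_powers, reactivity


@dataclass
class FeatureSet:
    """Tidy per-cohort feature tables plus the exclusion log."""

    powers: pd.DataFrame      # subject_id, group, condition, channel, band, ...
    reactivity: pd.DataFrame  # subject_id, group, band, channel, reactivity
    coherence: pd.DataFrame   # subject_id, group, condition, band, ch_a, ch_b, ...
    total_power: pd.DataFrame  # subject_id, group, condition, power, included
    exclusions: pd.DataFrame  # subject_id, group, condition, reason
    params: dict = field(default_factory=dict)


def extract_features(recordings: list[Recording], *,
                     bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                     low: float = 1.0, high: float = 50.0, car: bool = True,
                     epoch_length: float = 2.0,
                     amp_threshold: float = DEFAULT_AMPLITUDE_THRESHOLD_UV,
                     sd_threshold: float = DEFAULT_SD_THRESHOLD,
                     reactivity_source: str = "absolute",
                     coherence_car: bool | None = None) -> FeatureSet:
    """Compute the full feature set for a cohort of recordings.

    ``reactivity_source`` selects whether EC/EO reactivity is computed on
    absolute band power (default) or on relative power. ``coherence_car``
    overrides the reference used for coherence only (defaults to ``car``).
    """
    if reactivity_source not in ("absolute", "relative"):
        raise ValueError("reactivity_source must be 'absolute' or 'relative'")
    if coherence_car is None:
        coherence_car = car

    power_frames, coh_frames, exclusions = [], [], []
    for rec in recordings:
        epochs = preprocess_recording(rec, low=low, high=high, car=car,
                                      epoch_length=epoch_length,
                                      amp_threshold=amp_threshold)
        if epochs.n_retained == 0:
            exclusions.append((rec.subject_id, rec.group, rec.condition,
                               f"all epochs over {amp_threshold} uV"))
            continue
        power_frames.append(epochset_band_powers(epochs, bands))
        if epochs.n_retained >= 2 and epochs.epochs.shape[1] >= 2:
            if coherence_car == car:
                coh_epochs = epochs
            else:
                coh_epochs = preprocess_recording(
                    rec, low=low, high=high, car=coherence_car,
                    epoch_length=epoch_length, amp_threshold=amp_threshold)
            coh_frames.append(epochset_band_coherences(coh_epochs, bands))
        else:
            exclusions.append((rec.subject_id, rec.group, rec.condition,
                               "fewer than 2 retained epochs: no coherence"))
    if not power_frames:
        raise ValueError("every recording was excluded; no features to compute")
    powers = pd.concat(power_frames, ignore_index=True)
    coherence = (pd.concat(coh_frames, ignore_index=True) if coh_frames
                 else pd.DataFrame(columns=["subject_id", "group", "condition",
                                            "band", "ch_a", "ch_b", "coherence",
                                            "n_segments"]))

    # channel-averaged total 1-50 Hz absolute power per subject x condition,
    # screened per condition against the group mean
    total = (powers.groupby(["subject_id", "group", "condition", "channel"])
             ["absolute_power"].sum().groupby(["subject_id", "group", "condition"])
             .mean().rename("power").reset_index())
    total = exclude_power_outliers(total, sd_threshold)
    for _, row in total[~total["included"]].iterrows():
        exclusions.append((row["subject_id"], row["group"], row["condition"],
                           f"total power > {sd_threshold} SD from group mean"))
    included = total[total["included"]][["subject_id", "condition"]]
    powers = powers.merge(included, on=["subject_id", "condition"])
    if not coherence.empty:
        coherence = coherence.merge(included, on=["subject_id", "condition"])

    value = "absolute_power" if reactivity_source == "absolute" else "relative_power"
    wide = powers.pivot_table(index=["subject_id", "group", "band", "channel"],
                              columns="condition", values=value, aggfunc="first")
    both = wide.dropna(subset=[c for c in ("EC", "EO") if c in wide.columns]) \
        if {"EC", "EO"} <= set(wide.columns) else wide.iloc[0:0]
    react = both.reset_index()
    if not react.empty:
        react["reactivity"] = reactivity(react["EC"].to_numpy(),
                                         react["EO"].to_numpy())
        react = react[["subject_id", "group", "band", "channel", "reactivity"]]
    else:
        react = pd.DataFrame(columns=["subject_id", "group", "band", "channel",
                                      "reactivity"])

    exclusion_log = pd.DataFrame(
        exclusions, columns=["subject_id", "group", "condition", "reason"])
    return FeatureSet(powers=powers, reactivity=react, coherence=coherence,
                      total_power=total, exclusions=exclusion_log,
                      params={"bands": [b.name for b in bands], "low": low,
                              "high": high, "car": car,
                              "epoch_length": epoch_length,
                              "amp_threshold": amp_threshold,
                              "sd_threshold": sd_threshold,
                              "reactivity_source": reactivity_source})


def summary_features(feature_set: FeatureSet) -> pd.DataFrame:
    """Per-subject scalar summaries: channel-averaged relative band powers and
    reactivity, and the lower-triangle mean coherence, per band and condition.

    Columns follow ``rel_<band>_<ec|eo>_mean``, ``reactivity_<band>_mean`` and
    ``coh_<band>_<ec|eo>_mean``; index is subject_id with a ``group`` column.
    """
    parts = []
    rel = (feature_set.powers
           .groupby(["subject_id", "condition", "band"])["relative_power"]
           .mean().unstack(["condition", "band"]))
    rel.columns = [f"rel_{band}_{cond.lower()}_mean" for cond, band in rel.columns]
    parts.append(rel)
    if not feature_set.reactivity.empty:
        rea = (feature_set.reactivity
               .groupby(["subject_id", "band"])["reactivity"].mean().unstack())
        rea.columns = [f"reactivity_{band}_mean" for band in rea.columns]
        parts.append(rea)
    if not feature_set.coherence.empty:
        # mean over lower-triangle pair rows == lower-triangle matrix mean
        coh = (feature_set.coherence
               .groupby(["subject_id", "condition", "band"])["coherence"]
               .mean().unstack(["condition", "band"]))
        coh.columns = [f"coh_{band}_{cond.lower()}_mean" for cond, band in coh.columns]
        parts.append(coh)
    out = pd.concat(parts, axis=1)
    groups = (feature_set.powers[["subject_id", "group"]]
              .drop_duplicates().set_index("subject_id")["group"])
    out.insert(0, "group", groups)
    out.index.name = "subject_id"
    return out
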