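"""Synthetic three-group resting-state EEG cohorts with known ground truth.

The signal model is a sum of independent band-limited Gaussian noise
components (one per frequency band, 4th-order zero-phase Butterworth on white
noise, normalized to a configured RMS in microvolts) plus a 1/f^beta
background shaped in the frequency domain. Eyes-closed recordings differ from
eyes-open only in the alpha component, whose amplitude is multiplied by a
group-specific EC gain (>= 1). Inter-channel alpha coherence is induced by a
single shared alpha source: each channel's alpha component is

    amplitude * (sqrt(s) * g_ch * shared + sqrt(1 - s) * private_ch)

where s is the group's shared fraction and g_ch is a balanced random-polarity
(+/-1) per-channel topography. The topography keeps every channel's alpha
variance at amplitude^2 and the pairwise magnitude-squared coherence near s^2
while leaving the instantaneous channel mean close to zero, so the planted
coherence survives common-average re-referencing the way a dipolar source
topography would.

Covariates are drawn per group to configured means/SDs and bounds (the study's
demographic table), with planted covariate-feature correlations realized by a
linear blend of the standardized features and independent noise.

Everything is bit-identical under a fixed (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BAND_NAMES, DEFAULT_BANDS, band_by_name
from .recording import CONDITIONS, DEFAULT_MONTAGE, GROUPS, Recording

_GENERATOR_FILTER_ORDER = 4  # per pass, zero-phase
_COND_CODE = {"EC": 1, "EO": 2}


@dataclass(frozen=True)
class CovariateSpec:
    """Per-group mean/SD, bounds and missing rate for one covariate.

    Groups absent from ``by_group`` do not have the covariate at all
    (structurally missing, e.g. smoking measures for never-smokers).
    """

    name: str
    by_group: dict  # group -> (mean, sd)
    bounds: tuple[float, float]
    missing_rate: dict = field(default_factory=dict)  # group -> rate
    integer: bool = False


@dataclass
class EffectConfig:
    """Ground-truth effect sizes and cohort layout for the generator.

    ``band_amplitude[group][band]`` is the RMS (uV) of the band-limited
    component; for alpha it is the eyes-open amplitude, and the eyes-closed
    amplitude is ``alpha_ec_gain[group]`` times larger.
    """

    n_per_group: int | dict = 20
    sample_rate: float = 500.0
    duration: float = 180.0  # seconds per condition
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    band_amplitude: dict = field(default_factory=dict)  # group -> band -> uV RMS
    background_rms: float = 3.0
    background_exponent: float = 1.0
    alpha_ec_gain: dict = field(default_factory=dict)  # group -> factor >= 1
    alpha_shared_fraction: dict = field(default_factory=dict)  # group -> [0, 1]
    amplitude_jitter: float = 0.15  # lognormal CV of per-subject band RMS
    covariates: tuple[CovariateSpec, ...] = ()
    planted_correlations: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def group_n(self, group: str) -> int:
        n = self.n_per_group[group] if isinstance(self.n_per_group, dict) \
            else self.n_per_group
        return int(n)

    def validate(self) -> None:
        for group in GROUPS:
            if self.group_n(group) < 2:
                raise ValueError(f"n_per_group[{group}] must be >= 2")
            for band, amp in self.band_amplitude.get(group, {}).items():
                if amp < 0:
                    raise ValueError(f"negative amplitude for {group}/{band}")
            s = self.alpha_shared_fraction.get(group, 0.0)
            if not 0.0 <= s <= 1.0:
                raise ValueError("alpha_shared_fraction must lie in [0, 1]")
            if self.alpha_ec_gain.get(group, 1.0) < 1.0:
                raise ValueError("alpha_ec_gain must be >= 1")
        if self.duration < 4.0:
            raise ValueError("duration must be >= 4 s (at least two epochs)")
        for cov, feat, r in self.planted_correlations:
            if abs(r) >= 1.0:
                raise ValueError(f"planted |r| must be < 1 ({cov} vs {feat}: {r})")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = [dataclasses.asdict(c) for c in self.covariates]
        d["planted_correlations"] = [list(t) for t in self.planted_correlations]
        d["montage"] = list(self.montage)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EffectConfig":
        d = dict(d)
        d["covariates"] = tuple(
            CovariateSpec(**{**c, "bounds": tuple(c["bounds"])})
            for c in d.get("covariates", ())
        )
        d["planted_correlations"] = tuple(
            tuple(t) for t in d.get("planted_correlations", ()))
        d["montage"] = tuple(d.get("montage", DEFAULT_MONTAGE))
        return cls(**d)


@dataclass
class GroundTruth:
    """Realized per-subject parameters; regeneration is bit-identical."""

    config: EffectConfig
    seed: int
    subjects: pd.DataFrame  # subject_id, group, subject_seed, amp_<band>, ...


@dataclass
class Cohort:
    recordings: list[Recording]
    covariates: pd.DataFrame
    ground_truth: GroundTruth
    features: pd.DataFrame | None = None  # per-subject summaries, if computed


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------

def _unit_rms(x: np.ndarray) -> np.ndarray:
    rms = x.std(axis=-1, keepdims=True)
    return x / np.where(rms > 0, rms, 1.0)


def _band_noise(rng: np.random.Generator, shape: tuple, f_low: float,
                f_high: float, fs: float) -> np.ndarray:
    sos = signal.butter(_GENERATOR_FILTER_ORDER, [f_low, min(f_high, fs / 2 * 0.99)],
                        btype="bandpass", fs=fs, output="sos")
    return _unit_rms(signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1))


def _background_noise(rng: np.random.Generator, shape: tuple, exponent: float,
                      fs: float) -> np.ndarray:
    """1/f^exponent background, shaped in the frequency domain (flat below 1 Hz)."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    weight = np.ones_like(freqs)
    pos = freqs >= 1.0
    weight[pos] = freqs[pos] ** (-exponent / 2.0)
    weight[0] = 0.0
    return _unit_rms(np.fft.irfft(spec * weight, n=shape[-1], axis=-1))


def _subject_params(config: EffectConfig, group: str, subject_seed: int):
    """Per-subject realized band amplitudes and shared-source topography.

    Drawn from a condition-independent stream so eyes-closed and eyes-open
    recordings of one subject share the same subject-level parameters.
    """
    rng = np.random.default_rng([config.seed, subject_seed, 0])
    sigma = config.amplitude_jitter
    amps = {}
    for band in BAND_NAMES:
        base = config.band_amplitude.get(group, {}).get(band, 0.0)
        # mean-one lognormal multiplicative jitter
        jitter = np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0) if sigma > 0 else 1.0
        amps[band] = base * jitter
    n_ch = len(config.montage)
    signs = np.ones(n_ch)
    signs[: n_ch // 2] = -1.0
    rng.shuffle(signs)
    return amps, signs


def generate_recording(group: str, condition: str, config: EffectConfig,
                       subject_seed: int) -> Recording:
    """Generate one subject x condition multichannel recording (uV).

    Deterministic given (config, subject_seed); eyes-closed and eyes-open
    recordings differ in the alpha amplitude (EC = EO * alpha_ec_gain) and in
    their noise realizations, but share subject-level parameters.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    config.validate()
    fs = config.sample_rate
    n = int(round(config.duration * fs))
    n_ch = len(config.montage)
    amps, signs = _subject_params(config, group, subject_seed)
    rng = np.random.default_rng([config.seed, subject_seed, _COND_CODE[condition]])

    data = np.zeros((n_ch, n))
    for band_def in DEFAULT_BANDS:
        amp = amps[band_def.name]
        if band_def.name == "alpha":
            if condition == "EC":
                amp = amp * config.alpha_ec_gain.get(group, 1.0)
            s = config.alpha_shared_fraction.get(group, 0.0)
            shared = _band_noise(rng, (n,), band_def.f_low, band_def.f_high, fs)
            private = _band_noise(rng, (n_ch, n), band_def.f_low, band_def.f_high, fs)
            data += amp * (np.sqrt(s) * signs[:, None] * shared[None, :]
                           + np.sqrt(1.0 - s) * private)
        elif amp > 0:
            data += amp * _band_noise(rng, (n_ch, n), band_def.f_low,
                                      band_def.f_high, fs)
    if config.background_rms > 0:
        data += config.background_rms * _background_noise(
            rng, (n_ch, n), config.background_exponent, fs)

    return Recording(subject_id=f"{group}{subject_seed:03d}", group=group,
                     condition=condition, sample_rate=fs,
                     channel_labels=config.montage, data=data)


def inject_spikes(recording: Recording, epoch_indices, amplitude: float = 200.0,
                  epoch_length: float = 2.0, channel: int = 0) -> Recording:
    """Plant a single-sample artifact spike mid-epoch in the given epochs."""
    data = recording.data.copy()
    n_per = int(round(epoch_length * recording.sample_rate))
    for idx in epoch_indices:
        pos = idx * n_per + n_per // 2
        if pos >= recording.n_samples:
            raise ValueError(f"epoch index {idx} beyond recording end")
        data[channel, pos] += amplitude
    return recording.with_data(data)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _blend_weights(z: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve for blend weights so corr(cov, feature_i) = targets_i.

    z is (n, k) standardized features; returns (weights, residual SD) with
    weights solving R w = r for the empirical feature correlation matrix R.
    """
    corr = np.corrcoef(z, rowvar=False).reshape(z.shape[1], z.shape[1])
    weights = np.linalg.solve(corr, targets)
    resid_var = 1.0 - float(weights @ targets)
    if resid_var < 1e-10:
        raise ValueError(
            f"planted correlations {targets} are jointly infeasible "
            "(implied residual variance < 0)")
    return weights, np.sqrt(resid_var)


def generate_covariates(config: EffectConfig, features: pd.DataFrame,
                        seed: int) -> pd.DataFrame:
    """Draw the covariate table, honouring planted feature correlations.

    ``features`` must be indexed by subject_id with a ``group`` column and one
    column per feature named in ``config.planted_correlations``; it is required
    whenever planted correlations are configured. Covariates are scaled to the
    configured per-group mean/SD, clipped to bounds, and thinned
    missing-at-random at the configured per-group rate.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, seed, 99])
    out = pd.DataFrame(index=features.index)
    out["group"] = features["group"]
    for spec in config.covariates:
        targets = [(feat, r) for cov, feat, r in config.planted_correlations
                   if cov == spec.name]
        for feat, _ in targets:
            if feat not in features.columns:
                raise ValueError(
                    f"planted correlation for {spec.name!r} references absent "
                    f"feature {feat!r}")
        col = np.full(len(features), np.nan)
        mask = features["group"].isin(spec.by_group).to_numpy()
        n_sel = int(mask.sum())
        if n_sel:
            if targets:
                raw = features.loc[mask, [f for f, _ in targets]].to_numpy(float)
                z = (raw - np.nanmean(raw, axis=0)) / np.nanstd(raw, axis=0)
                # subjects lacking a feature (excluded condition) fall back to
                # pure noise for the planted component
                z = np.nan_to_num(z, nan=0.0)
                weights, resid_sd = _blend_weights(
                    z, np.array([r for _, r in targets]))
                std_cov = z @ weights + resid_sd * rng.standard_normal(n_sel)
            else:
                std_cov = rng.standard_normal(n_sel)
            sel_groups = features.loc[mask, "group"].to_numpy()
            means = np.array([spec.by_group[g][0] for g in sel_groups])
            sds = np.array([spec.by_group[g][1] for g in sel_groups])
            vals = np.clip(means + sds * std_cov, *spec.bounds)
            if spec.integer:
                vals = np.round(vals)
            # missing-at-random thinning, per group
            rates = np.array([spec.missing_rate.get(g, 0.0) for g in sel_groups])
            vals[rng.random(n_sel) < rates] = np.nan
            col[mask] = vals
        out[spec.name] = col
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_recordings(config: EffectConfig) -> tuple[list[Recording], GroundTruth]:
    """Generate the EC+EO recordings for every subject plus the ground truth."""
    config.validate()
    recordings, subject_rows = [], []
    subject_seed = 0
    for group in GROUPS:
        for _ in range(config.group_n(group)):
            amps, _ = _subject_params(config, group, subject_seed)
            row = {"subject_id": f"{group}{subject_seed:03d}", "group": group,
                   "subject_seed": subject_seed,
                   "alpha_ec_gain": config.alpha_ec_gain.get(group, 1.0),
                   "alpha_shared_fraction":
                       config.alpha_shared_fraction.get(group, 0.0)}
            row.update({f"amp_{b}": amps[b] for b in BAND_NAMES})
            subject_rows.append(row)
            for condition in CONDITIONS:
                recordings.append(
                    generate_recording(group, condition, config, subject_seed))
            subject_seed += 1
    truth = GroundTruth(config=config, seed=config.seed,
                        subjects=pd.DataFrame(subject_rows))
    return recordings, truth


def generate_cohort(config: EffectConfig, compute_features: bool | None = None) -> Cohort:
    """Generate the full cohort: EC+EO recordings, covariates, ground truth.

    Per-subject summary features are computed through the analysis pipeline
    whenever planted correlations require them (or when ``compute_features``
    is forced True) and returned on the cohort for reuse.
    """
    if compute_features is None:
        compute_features = bool(config.planted_correlations)
    recordings, truth = generate_recordings(config)

    features = None
    if compute_features:
        from .features import extract_features, summary_features
        features = summary_features(extract_features(recordings))
    if config.covariates:
        if config.planted_correlations and features is None:
            raise ValueError("planted correlations require computed features")
        base = features if features is not None else pd.DataFrame(
            {"group": truth.subjects["group"].to_numpy()},
            index=pd.Index(truth.subjects["subject_id"], name="subject_id"))
        covariates = generate_covariates(config, base, seed=config.seed)
    else:
        covariates = pd.DataFrame(
            {"group": truth.subjects["group"].to_numpy()},
            index=pd.Index(truth.subjects["subject_id"], name="subject_id"))
    return Cohort(recordings=recordings, covariates=covariates,
                  ground_truth=truth, features=features)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Eyes-open band RMS amplitudes (uV). Values sit in the typical adult
#: resting-EEG range; group effects mirror the study's findings: a theta
#: deficit in both smoker groups, and higher alpha amplitude, EC gain and
#: shared-source coherence in current smokers only.
_BASE_AMPS = {"delta": 4.0, "theta": 3.0, "alpha": 4.0, "beta": 2.0, "gamma": 1.0}

_STUDY_EFFECTS = {
    "never": {"theta": 3.0, "alpha": 4.0},
    "past": {"theta": 2.4, "alpha": 4.0},
    "smoker": {"theta": 2.2, "alpha": 4.6},
}
_STUDY_GAINS = {"never": 1.3, "past": 1.3, "smoker": 1.6}
_STUDY_SHARED = {"never": 0.25, "past": 0.25, "smoker": 0.45}

#: Study group sizes (never / past / current smokers).
STUDY_N = {"never": 33, "past": 28, "smoker": 20}


def table1_covariate_specs() -> tuple[CovariateSpec, ...]:
    """Covariate distributions mirroring the study's demographic table,
    including its per-group missingness."""
    return (
        CovariateSpec("age", {"never": (53.09, 4.96), "past": (54.64, 6.48),
                              "smoker": (56.30, 7.12)}, (40.0, 75.0)),
        CovariateSpec("education", {"never": (3.67, 1.14), "past": (3.32, 1.12),
                                    "smoker": (3.00, 0.97)}, (1, 5), integer=True),
        CovariateSpec("income", {"never": (3.15, 1.25), "past": (3.14, 1.41),
                                 "smoker": (2.85, 1.42)}, (1, 6), integer=True),
        CovariateSpec("kbdi", {"never": (8.63, 6.89), "past": (9.96, 6.50),
                               "smoker": (8.75, 6.27)}, (0.0, 63.0)),
        CovariateSpec("initiation_age", {"past": (19.43, 1.32),
                                         "smoker": (18.10, 1.80)}, (12.0, 30.0)),
        CovariateSpec("years_smoking", {"past": (10.21, 6.43),
                                        "smoker": (37.80, 7.54)}, (0.5, 55.0)),
        CovariateSpec("cigarettes_per_day",
                      {"past": (18.24, 9.05), "smoker": (20.53, 6.76)},
                      (5.0, 45.0),
                      missing_rate={"past": 7 / 28, "smoker": 1 / 20}),
        CovariateSpec("quit_attempts", {"past": (2.11, 2.11), "smoker": (2.15, 1.04)},
                      (1, 10), missing_rate={"past": 10 / 28}, integer=True),
        CovariateSpec("ftnd", {"past": (3.15, 3.17), "smoker": (5.58, 2.09)},
                      (0.0, 10.0),
                      missing_rate={"past": 8 / 28, "smoker": 1 / 20}),
        CovariateSpec("qsu", {"past": (10.80, 2.73), "smoker": (21.32, 10.17)},
                      (10.0, 70.0),
                      missing_rate={"past": 8 / 28, "smoker": 1 / 20}),
    )


#: Planted covariate-feature correlations (the study's reported associations).
STUDY_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("cigarettes_per_day", "rel_theta_ec_mean", -0.31),
    ("ftnd", "rel_theta_ec_mean", -0.40),
    ("quit_attempts", "rel_theta_ec_mean", 0.43),
    ("cigarettes_per_day", "coh_alpha_ec_mean", 0.39),
)


def _amplitudes(effects: dict) -> dict:
    return {g: {**_BASE_AMPS, **effects.get(g, {})} for g in GROUPS}


def study_config(seed: int = 0, *, n_per_group: dict | int | None = None,
                      sample_rate: float = 500.0, duration: float = 180.0,
                      planted: bool = True) -> EffectConfig:
    """The default study-like preset: group sizes, effects and covariates
    mirroring the study conditions."""
    return EffectConfig(
        n_per_group=dict(STUDY_N) if n_per_group is None else n_per_group,
        sample_rate=sample_rate, duration=duration,
        band_amplitude=_amplitudes(_STUDY_EFFECTS),
        alpha_ec_gain=dict(_STUDY_GAINS),
        alpha_shared_fraction=dict(_STUDY_SHARED),
        covariates=table1_covariate_specs(),
        planted_correlations=STUDY_CORRELATIONS if planted else (),
        seed=seed,
    )


def null_config(seed: int = 0, *, n_per_group: dict | int | None = None,
                sample_rate: float = 500.0, duration: float = 180.0) -> EffectConfig:
    """Zero-effect preset: identical signal parameters in all three groups,
    no planted correlations."""
    never_only = {g: {} for g in GROUPS}
    return EffectConfig(
        n_per_group=dict(STUDY_N) if n_per_group is None else n_per_group,
        sample_rate=sample_rate, duration=duration,
        band_amplitude=_amplitudes(never_only),
        alpha_ec_gain={g: _STUDY_GAINS["never"] for g in GROUPS},
        alpha_shared_fraction={g: _STUDY_SHARED["never"] for g in GROUPS},
        covariates=table1_covariate_specs(),
        planted_correlations=(),
        seed=seed,
    )
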