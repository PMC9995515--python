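"""End-to-end orchestration: generate/load -> preprocess -> features ->
coherence -> group statistics -> bootstrap correlations, with tidy CSV
outputs, an exclusion log and a machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import BAND_NAMES
from .features import FeatureSet, extract_features, summary_features
from .io import load_directory
from .recording import CONDITIONS
from .stats import (GroupTestReport, anova_from_summary,
                    channelwise_group_analysis, pearson_bootstrap,
                    t_test_from_summary)
from .synthetic import (EffectConfig, generate_covariates, generate_recordings,
                        null_config, study_config)

#: channel-averaged features correlated against smoking covariates,
#: across current- and past-smokers
CORRELATION_FEATURES = ("rel_theta_ec_mean", "rel_alpha_ec_mean",
                        "reactivity_alpha_mean", "coh_alpha_ec_mean")
CORRELATION_COVARIATES = ("cigarettes_per_day", "ftnd", "quit_attempts",
                          "years_smoking")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    source: str = "synthetic"  # "synthetic" | "directory"
    preset: str = "study"      # "study" | "null" (synthetic source)
    effect: EffectConfig | None = None  # overrides the preset when given
    data_dir: str | None = None
    out_dir: str = "results/run"
    low: float = 1.0
    high: float = 50.0
    car: bool = True
    epoch_length: float = 2.0
    amp_threshold: float = 75.0
    sd_threshold: float = 3.0
    reactivity_source: str = "absolute"
    alpha: float = 0.05
    posthoc: str = "tukey"
    bootstrap_n: int = 10_000
    seed: int = 0

    def resolved_effect(self) -> EffectConfig:
        if self.effect is not None:
            return self.effect
        maker = {"study": study_config, "null": null_config}.get(self.preset)
        if maker is None:
            raise ValueError(f"unknown preset {self.preset!r}")
        return maker(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.effect is not None:
            d["effect"] = self.effect.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("effect"):
            d["effect"] = EffectConfig.from_dict(d["effect"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        # where results land does not change what is computed
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.source not in ("synthetic", "directory"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "directory":
            if not self.data_dir:
                raise ValueError("directory source requires data_dir")
            d = Path(self.data_dir)
            if not d.is_dir() or not any(
                    p.suffix.lower() in {".npy", ".edf", ".vhdr"}
                    for p in d.iterdir()):
                raise ValueError(f"no readable recordings in {self.data_dir!r}")
        else:
            self.resolved_effect().validate()
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def group_test_families(feature_set: FeatureSet, alpha: float = 0.05,
                        posthoc: str = "tukey") -> list[GroupTestReport]:
    """All channel-wise test families: relative power and coherence per band x
    condition, reactivity per band. FDR is controlled within each family."""
    reports = []
    for band in BAND_NAMES:
        for condition in CONDITIONS:
            reports.append(channelwise_group_analysis(
                feature_set.powers, "relative_power", band, condition,
                alpha=alpha, posthoc=posthoc))
            if not feature_set.coherence.empty:
                reports.append(channelwise_group_analysis(
                    feature_set.coherence, "coherence", band, condition,
                    alpha=alpha, posthoc=posthoc))
        if not feature_set.reactivity.empty:
            reports.append(channelwise_group_analysis(
                feature_set.reactivity, "reactivity", band, None,
                alpha=alpha, posthoc=posthoc))
    return reports


def _reports_to_frames(reports: list[GroupTestReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    tests, posthocs = [], []
    for rep in reports:
        t = rep.table.copy()
        t.insert(0, "feature", rep.feature)
        t.insert(1, "band", rep.band)
        t.insert(2, "condition", rep.condition)
        tests.append(t)
        if not rep.posthoc.empty:
            p = rep.posthoc.copy()
            p.insert(0, "feature", rep.feature)
            p.insert(1, "band", rep.band)
            p.insert(2, "condition", rep.condition)
            posthocs.append(p)
    tests_df = pd.concat(tests, ignore_index=True)
    posthoc_df = (pd.concat(posthocs, ignore_index=True) if posthocs else
                  pd.DataFrame(columns=["feature", "band", "condition", "unit",
                                        "group_a", "group_b", "mean_diff", "p",
                                        "direction"]))
    return tests_df, posthoc_df


def correlation_table(summaries: pd.DataFrame, covariates: pd.DataFrame,
                      n_boot: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Bootstrap Pearson correlations between channel-averaged EEG features and
    smoking covariates across current- and past-smokers (pairwise-complete)."""
    joined = summaries.join(covariates.drop(columns=["group"]), how="inner")
    smokers = joined[joined["group"].isin(["smoker", "past"])]
    rows = []
    for fi, feat in enumerate(CORRELATION_FEATURES):
        if feat not in smokers.columns:
            continue
        for ci, cov in enumerate(CORRELATION_COVARIATES):
            if cov not in smokers.columns:
                continue
            x = smokers[feat].to_numpy(float)
            y = smokers[cov].to_numpy(float)
            if np.isfinite(x[np.isfinite(y)]).sum() < 3:
                continue
            res = pearson_bootstrap(x, y, n_boot=n_boot,
                                    seed=seed + 1000 * fi + ci,
                                    feature=feat, covariate=cov)
            rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def run(config: RunConfig) -> Path:
    """Execute the full analysis graph; returns the run directory.

    Outputs: features_power.csv, features_reactivity.csv,
    features_coherence.csv, summary_features.csv, covariates.csv,
    group_tests.csv, posthoc.csv, correlations.csv, exclusions.csv,
    ground_truth.csv (synthetic runs), config.yaml, summary.json, run.log.
    Deterministic for a fixed config (seed included).
    """
    config.validate()  # before any output is created
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"run config hash {config.config_hash}"]

    truth = None
    covariates = None
    if config.source == "synthetic":
        effect = config.resolved_effect()
        recordings, truth = generate_recordings(effect)
        log.append(f"generated {len(recordings)} recordings "
                   f"({len(truth.subjects)} subjects x {len(CONDITIONS)} conditions)")
    else:
        recordings = load_directory(config.data_dir)
        log.append(f"loaded {len(recordings)} recordings from {config.data_dir}")
        cov_path = Path(config.data_dir) / "covariates.csv"
        if cov_path.exists():
            covariates = pd.read_csv(cov_path, index_col="subject_id")

    feature_set = extract_features(
        recordings, low=config.low, high=config.high, car=config.car,
        epoch_length=config.epoch_length, amp_threshold=config.amp_threshold,
        sd_threshold=config.sd_threshold,
        reactivity_source=config.reactivity_source)
    summaries = summary_features(feature_set)
    if config.source == "synthetic":
        covariates = generate_covariates(effect, summaries, seed=effect.seed)
    log.append(f"features for {summaries.shape[0]} subjects; "
               f"{len(feature_set.exclusions)} exclusion events")

    reports = group_test_families(feature_set, alpha=config.alpha,
                                  posthoc=config.posthoc)
    tests_df, posthoc_df = _reports_to_frames(reports)
    n_sig = int(tests_df["significant"].sum())
    log.append(f"{len(reports)} test families, {n_sig} FDR-significant units")

    correlations = (correlation_table(summaries, covariates,
                                      n_boot=config.bootstrap_n,
                                      seed=config.seed)
                    if covariates is not None else pd.DataFrame())
    if len(correlations):
        log.append(f"{len(correlations)} bootstrap correlations "
                   f"(B={config.bootstrap_n})")

    fmt = dict(float_format="%.10g")
    feature_set.powers.to_csv(out / "features_power.csv", index=False, **fmt)
    feature_set.reactivity.to_csv(out / "features_reactivity.csv", index=False, **fmt)
    feature_set.coherence.to_csv(out / "features_coherence.csv", index=False, **fmt)
    summaries.to_csv(out / "summary_features.csv", **fmt)
    feature_set.exclusions.to_csv(out / "exclusions.csv", index=False)
    tests_df.to_csv(out / "group_tests.csv", index=False, **fmt)
    posthoc_df.to_csv(out / "posthoc.csv", index=False, **fmt)
    if covariates is not None:
        covariates.to_csv(out / "covariates.csv", **fmt)
    if len(correlations):
        correlations.to_csv(out / "correlations.csv", index=False, **fmt)
    if truth is not None:
        truth.subjects.to_csv(out / "ground_truth.csv", index=False, **fmt)
    (out / "config.yaml").write_text(config.to_yaml())

    summary = {
        "config_hash": config.config_hash,
        "n_recordings": len(recordings),
        "n_subjects": int(summaries.shape[0]),
        "exclusions": feature_set.exclusions.to_dict(orient="records"),
        "significant_units": {
            f"{r.feature}/{r.band}/{r.condition or 'both'}": r.significant_units
            for r in reports if r.significant_units},
        "correlations": correlations.to_dict(orient="records")
        if len(correlations) else [],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out


# ---------------------------------------------------------------------------
# printed-summary validation
# ---------------------------------------------------------------------------

def table1_path() -> Path:
    """Path to the bundled demographic-summary fixture (printed means/SDs/ns)."""
    return Path(resources.files("rseeg") / "data" / "table1.csv")


def validate_table1(path: str | Path | None = None) -> pd.DataFrame:
    """Recompute every t and F statistic from a printed-summary table.

    The file lists per measure, per group: mean, sd, n, and the test kind
    ('t' or 'anova'). Two-group t statistics are signed as second-listed
    group minus first-listed group. Returns a frame: measure, test,
    statistic, df1, df2, p.
    """
    path = Path(path) if path is not None else table1_path()
    table = pd.read_csv(path)
    required = {"measure", "test", "group", "mean", "sd", "n"}
    if missing := required - set(table.columns):
        raise ValueError(f"summary file missing columns: {sorted(missing)}")
    rows = []
    for measure, chunk in table.groupby("measure", sort=False):
        kind = chunk["test"].iloc[0]
        if not np.isfinite(chunk[["mean", "sd"]].to_numpy()).all():
            raise ValueError(f"malformed summary row for measure {measure!r}")
        if kind == "t":
            if len(chunk) != 2:
                raise ValueError(f"t-test measure {measure!r} needs exactly 2 rows")
            a, b = chunk.iloc[0], chunk.iloc[1]
            t, df, p = t_test_from_summary(b["mean"], b["sd"], int(b["n"]),
                                           a["mean"], a["sd"], int(a["n"]))
            rows.append((measure, "t", t, df, np.nan, p))
        elif kind == "anova":
            f, df1, df2, p = anova_from_summary(chunk["mean"], chunk["sd"],
                                                chunk["n"].astype(int))
            rows.append((measure, "anova", f, df1, df2, p))
        else:
            raise ValueError(f"unknown test kind {kind!r} for measure {measure!r}")
    return pd.DataFrame(rows, columns=["measure", "test", "statistic", "df1",
                                       "df2", "p"])
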