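import numpy as np
import pandas as pd
import pytest

from rseeg.bands import DEFAULT_BANDS
from rseeg.features import extract_features, summary_features
from rseeg.preprocess import make_epochs
from rseeg.spectral import band_powers, epoch_psd
from rseeg.synthetic import (CovariateSpec, EffectConfig, generate_cohort,
                             generate_covariates, generate_recording,
                             generate_recordings, null_config,
                             study_config, table1_covariate_specs)

GROUPS = ("never", "past", "smoker")


def _flat_config(**kw):
    base = dict(
        n_per_group=2, sample_rate=250.0, duration=8.0,
        montage=("a", "b", "c", "d"),
        band_amplitude={g: {"delta": 4.0, "theta": 3.0, "alpha": 4.0,
                            "beta": 2.0, "gamma": 1.0} for g in GROUPS},
        alpha_ec_gain={g: 1.3 for g in GROUPS},
        alpha_shared_fraction={g: 0.2 for g in GROUPS},
        background_rms=0.0, amplitude_jitter=0.0, seed=5)
    base.update(kw)
    return EffectConfig(**base)


class TestGenerateRecording:
    def test_deterministic_bit_identical(self):
        cfg = _flat_config()
        a = generate_recording("past", "EC", cfg, 3)
        b = generate_recording("past", "EC", cfg, 3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_conditions_differ_only_in_alpha_statistics(self):
        cfg = _flat_config(alpha_ec_gain={g: 2.0 for g in GROUPS},
                           duration=60.0)
        ec = generate_recording("never", "EC", cfg, 0)
        eo = generate_recording("never", "EO", cfg, 0)
        for rec, expected_alpha_rms in ((ec, 8.0), (eo, 4.0)):
            es = make_epochs(rec, 2.0)
            freqs, p = epoch_psd(es.epochs.reshape(-1, es.epochs.shape[-1]),
                                 rec.sample_rate)
            bp = band_powers(freqs, p)
            alpha_rms = np.sqrt(bp["alpha"].mean())
            assert alpha_rms == pytest.approx(expected_alpha_rms, rel=0.15)

    @pytest.mark.parametrize("band,target", [("delta", 4.0), ("theta", 3.0),
                                             ("alpha", 4.0), ("beta", 2.0),
                                             ("gamma", 1.0)])
    def test_realized_band_rms_within_10pct_over_60s(self, band, target):
        # each band component in isolation, so neighbouring-band leakage
        # cannot contaminate the band-integrated power
        amps = {g: {band: target} for g in GROUPS}
        cfg = _flat_config(duration=60.0, band_amplitude=amps)
        rec = generate_recording("never", "EO", cfg, 1)
        es = make_epochs(rec, 2.0)
        freqs, p = epoch_psd(es.epochs.reshape(-1, es.epochs.shape[-1]),
                             rec.sample_rate)
        rms = np.sqrt(band_powers(freqs, p)[band].mean())
        assert rms == pytest.approx(target, rel=0.10)

    def test_unknown_labels_error(self):
        cfg = _flat_config()
        with pytest.raises(ValueError, match="unknown group"):
            generate_recording("vaper", "EC", cfg, 0)
        with pytest.raises(ValueError, match="unknown condition"):
            generate_recording("never", "resting", cfg, 0)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="duration"):
            _flat_config(duration=3.0).validate()
        with pytest.raises(ValueError, match="negative amplitude"):
            _flat_config(band_amplitude={
                g: {"theta": -1.0} for g in GROUPS}).validate()
        with pytest.raises(ValueError, match="shared_fraction"):
            _flat_config(alpha_shared_fraction={g: 1.5 for g in GROUPS}).validate()
        with pytest.raises(ValueError, match="n_per_group"):
            _flat_config(n_per_group=1).validate()
        with pytest.raises(ValueError, match="alpha_ec_gain"):
            _flat_config(alpha_ec_gain={g: 0.5 for g in GROUPS}).validate()

    def test_theta_deficit_orders_relative_theta_everywhere(self):
        # group A theta silenced, group B at full amplitude
        amps = {"never": {"delta": 4.0, "theta": 0.0, "alpha": 4.0,
                          "beta": 2.0, "gamma": 1.0},
                "past": {"delta": 4.0, "theta": 3.0, "alpha": 4.0,
                         "beta": 2.0, "gamma": 1.0},
                "smoker": {"delta": 4.0, "theta": 3.0, "alpha": 4.0,
                           "beta": 2.0, "gamma": 1.0}}
        cfg = _flat_config(band_amplitude=amps, n_per_group=20, duration=8.0)
        recs, _ = generate_recordings(cfg)
        fs = extract_features([r for r in recs if r.condition == "EC"])
        rel = (fs.powers[fs.powers.band == "theta"]
               .groupby(["group", "channel"])["relative_power"].mean().unstack())
        assert (rel.loc["never"] < rel.loc["past"]).all()


class TestReactivityGroundTruth:
    def test_ec_gain_drives_alpha_reactivity_only(self):
        cfg = _flat_config(alpha_ec_gain={g: 1.6 for g in GROUPS},
                           n_per_group=6, duration=30.0)
        recs, _ = generate_recordings(cfg)
        fs = extract_features(recs)
        mean_react = fs.reactivity.groupby("band")["reactivity"].mean()
        assert mean_react["alpha"] > 0.3
        # spectrally distant bands stay near zero; adjacent bands may pick up
        # a little band-edge leakage from the boosted alpha component
        assert abs(mean_react["delta"]) < 0.10
        assert abs(mean_react["gamma"]) < 0.10
        assert mean_react["alpha"] > 3 * abs(mean_react["theta"])

    def test_relative_power_reactivity_path_preserves_sign(self):
        cfg = _flat_config(alpha_ec_gain={g: 1.6 for g in GROUPS},
                           n_per_group=4, duration=30.0)
        recs, _ = generate_recordings(cfg)
        fs = extract_features(recs, reactivity_source="relative")
        assert fs.reactivity.groupby("band")["reactivity"].mean()["alpha"] > 0.1


class TestGenerateCohort:
    def test_recording_count(self):
        cohort = generate_cohort(_flat_config(n_per_group=2))
        assert len(cohort.recordings) == 12  # 3 groups x 2 subjects x 2 conditions

    def test_unequal_group_sizes(self):
        cfg = _flat_config(n_per_group={"never": 4, "past": 3, "smoker": 2})
        cohort = generate_cohort(cfg)
        assert len(cohort.recordings) == 18
        counts = cohort.ground_truth.subjects["group"].value_counts()
        assert counts["never"] == 4 and counts["smoker"] == 2

    def test_full_determinism(self):
        cfg = _flat_config(covariates=table1_covariate_specs())
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        np.testing.assert_array_equal(a.recordings[5].data, b.recordings[5].data)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)
        pd.testing.assert_frame_equal(a.ground_truth.subjects,
                                      b.ground_truth.subjects)

    def test_study_preset_shape(self):
        cfg = study_config(seed=0)
        assert cfg.group_n("never") == 33 and cfg.group_n("smoker") == 20
        assert cfg.sample_rate == 500.0 and cfg.duration == 180.0
        assert len(cfg.montage) == 31
        cfg.validate()
        null = null_config(seed=0)
        assert null.band_amplitude["smoker"] == null.band_amplitude["never"]
        assert null.planted_correlations == ()

    def test_config_roundtrip_through_dict(self):
        cfg = study_config(seed=3)
        again = EffectConfig.from_dict(cfg.to_dict())
        assert again == cfg


class TestGenerateCovariates:
    @staticmethod
    def _features(rng, n=48):
        groups = np.repeat(["past", "smoker"], n // 2)
        return pd.DataFrame({
            "group": groups,
            "rel_theta_ec_mean": rng.normal(0.15, 0.03, n),
            "coh_alpha_ec_mean": rng.normal(0.10, 0.02, n),
        }, index=pd.Index([f"s{i:02d}" for i in range(n)], name="subject_id"))

    def test_zero_target_independent(self):
        cfg = _flat_config(
            covariates=(CovariateSpec("ftnd", {"past": (4.0, 2.0),
                                               "smoker": (4.0, 2.0)}, (0, 10)),),
            planted_correlations=(("ftnd", "rel_theta_ec_mean", 0.0),))
        inside = []
        for seed in range(20):
            feats = self._features(np.random.default_rng(seed))
            cov = generate_covariates(cfg, feats, seed=seed)
            r = np.corrcoef(cov["ftnd"], feats["rel_theta_ec_mean"])[0, 1]
            inside.append(abs(r) < 2 / np.sqrt(len(feats)))
        assert np.mean(inside) >= 0.8  # ~95% bound per draw

    def test_planted_negative_correlation_recovered(self, rng):
        cfg = _flat_config(
            covariates=(CovariateSpec("ftnd", {"past": (4.0, 2.5),
                                               "smoker": (4.0, 2.5)}, (0, 10)),),
            planted_correlations=(("ftnd", "rel_theta_ec_mean", -0.40),))
        rs = []
        for seed in range(25):
            feats = self._features(np.random.default_rng(seed))
            cov = generate_covariates(cfg, feats, seed=seed)
            rs.append(np.corrcoef(cov["ftnd"], feats["rel_theta_ec_mean"])[0, 1])
        inside = np.mean([(-0.65 < r < -0.15) for r in rs])
        assert inside >= 0.9  # sampling distribution of r at n = 48

    def test_missing_rate_thinning(self, rng):
        cfg = _flat_config(
            covariates=(CovariateSpec(
                "ftnd", {"past": (4.0, 2.0)}, (0, 10),
                missing_rate={"past": 0.3}),))
        feats = self._features(rng, n=2000).assign(group="past")
        cov = generate_covariates(cfg, feats, seed=2)
        assert cov["ftnd"].isna().mean() == pytest.approx(0.3, abs=0.04)

    def test_structural_missingness_by_group(self, rng):
        cfg = _flat_config(covariates=table1_covariate_specs())
        feats = self._features(rng)
        feats.iloc[:10, feats.columns.get_loc("group")] = "never"
        cov = generate_covariates(cfg, feats, seed=0)
        assert cov.loc[cov.group == "never", "ftnd"].isna().all()
        assert cov.loc[cov.group == "never", "age"].notna().all()

    def test_bounds_and_integer_covariates(self, rng):
        cov = generate_covariates(
            _flat_config(covariates=table1_covariate_specs()),
            self._features(rng), seed=0)
        assert cov["ftnd"].dropna().between(0, 10).all()
        edu = cov["education"].dropna()
        assert (edu == edu.round()).all() and edu.between(1, 5).all()

    def test_errors(self, rng):
        feats = self._features(rng)
        bad = _flat_config(
            covariates=(CovariateSpec("ftnd", {"past": (4, 2)}, (0, 10)),),
            planted_correlations=(("ftnd", "no_such_feature", 0.2),))
        with pytest.raises(ValueError, match="absent feature"):
            generate_covariates(bad, feats, seed=0)
        with pytest.raises(ValueError, match=r"\|r\| must be < 1"):
            _flat_config(planted_correlations=(("ftnd", "x", 1.0),)).validate()


def test_cohort_summary_features_expected_group_ordering(tiny_features):
    """The study-like preset orders group means: theta never > smoker,
    alpha-coherence smoker > never."""
    summaries = summary_features(tiny_features)
    by_group = summaries.groupby("group").mean(numeric_only=True)
    assert by_group.loc["never", "rel_theta_ec_mean"] > \
        by_group.loc["smoker", "rel_theta_ec_mean"]
    assert by_group.loc["smoker", "coh_alpha_ec_mean"] > \
        by_group.loc["never", "coh_alpha_ec_mean"]
    assert by_group.loc["smoker", "reactivity_alpha_mean"] > \
        by_group.loc["never", "reactivity_alpha_mean"]
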