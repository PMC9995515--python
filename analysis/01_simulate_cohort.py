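"""Stage 1 — simulate the three-group resting-state EEG cohort.

Generates eyes-closed and eyes-open recordings for every subject with the
study-like planted effects (theta deficit in both smoker groups; higher alpha
amplitude, EC gain and shared-source coherence in current smokers), and
writes the per-subject ground truth. Covariates are written in stage 4 once
features exist to plant correlations against.
"""

import importlib

import pandas as pd

common = importlib.import_module("00_config")

from rseeg.synthetic import generate_recordings  # noqa: E402


def main() -> None:
    cfg = common.COHORT_CONFIG
    recordings, truth = generate_recordings(cfg)
    out = common.RESULTS / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    truth.subjects.to_csv(out / "ground_truth.csv", index=False)

    print(f"simulated {len(recordings)} recordings "
          f"({len(truth.subjects)} subjects x EC/EO) at "
          f"{cfg.sample_rate:.0f} Hz, {cfg.duration:.0f} s per condition")
    realized = truth.subjects.groupby("group")[
        ["amp_theta", "amp_alpha", "alpha_ec_gain", "alpha_shared_fraction"]
    ].mean().round(3)
    print("\nrealized group means of the planted parameters:")
    print(realized.to_string())
    print(f"\nground truth -> {out / 'ground_truth.csv'}")


if __name__ == "__main__":
    main()
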