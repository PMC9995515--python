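"""Stage 3 — channel-wise group statistics.

Kruskal-Wallis per channel (per channel pair for coherence) with
Benjamini-Hochberg FDR within each band x condition x feature family, and
Tukey HSD post-hocs where the omnibus test survives. Prints which families
recover the planted effects and in which direction.
"""

import importlib

common = importlib.import_module("00_config")

from rseeg.features import extract_features  # noqa: E402
from rseeg.pipeline import _reports_to_frames, group_test_families  # noqa: E402
from rseeg.synthetic import generate_recordings  # noqa: E402


def main() -> None:
    recordings, _ = generate_recordings(common.COHORT_CONFIG)
    reports = group_test_families(extract_features(recordings))
    tests, posthoc = _reports_to_frames(reports)
    out = common.RESULTS / "stats"
    out.mkdir(parents=True, exist_ok=True)
    tests.to_csv(out / "group_tests.csv", index=False)
    posthoc.to_csv(out / "posthoc.csv", index=False)

    print("families with FDR-significant units (alpha = 0.05):")
    for rep in reports:
        if not rep.significant_units:
            continue
        ph = rep.posthoc
        ns = ph[(ph.group_a == "never") & (ph.group_b == "smoker") & (ph.p < 0.05)]
        direction = ns.direction.mode().iloc[0] if len(ns) else "-"
        print(f"  {rep.feature:15s} {rep.band:6s} {rep.condition or 'EC-EO':5s} "
              f"{len(rep.significant_units):4d} units   never-vs-smoker: {direction}")
    print(f"\ntables -> {out}")


if __name__ == "__main__":
    main()
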