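"""Stage 5 — recompute the demographic-table test statistics.

Every two-sample t and one-way ANOVA F in the bundled printed-summary fixture
is recomputed from the group means, SDs and ns alone.
"""

import importlib

common = importlib.import_module("00_config")

from rseeg.pipeline import validate_table1  # noqa: E402


def main() -> None:
    report = validate_table1()
    out = common.RESULTS / "table1_validation.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(out, index=False)
    print("recomputed summary statistics:")
    print(report.to_string(index=False,
                           float_format=lambda v: f"{v:.4g}"))
    print(f"\ntable -> {out}")


if __name__ == "__main__":
    main()
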