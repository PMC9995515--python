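"""Shared analysis configuration: the scaled study-like cohort.

Group sizes match the study (33 never-, 28 past-, 20 current-smokers); each
condition is simulated at 24 s / 250 Hz (12 two-second epochs) so the whole
analysis chain runs in seconds per stage. Import COHORT_CONFIG from the
numbered scripts; regeneration is deterministic, so every stage can rebuild
the identical cohort instead of shipping hundreds of megabytes of signals.
"""

from pathlib import Path

from rseeg.synthetic import study_config

SEED = 0
COHORT_CONFIG = study_config(seed=SEED, duration=24.0, sample_rate=250.0)
RESULTS = Path(__file__).resolve().parent.parent / "results"
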