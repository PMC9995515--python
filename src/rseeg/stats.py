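"""Group statistics: Kruskal-Wallis omnibus tests with Benjamini-Hochberg FDR
across channels, Tukey HSD post-hocs, summary-statistic t/ANOVA recomputation,
Mann-Whitney U, chi-squared contingency tests, and bootstrap Pearson
correlations with percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# elemental tests
# ---------------------------------------------------------------------------

def kruskal_wallis(*groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H on mid-ranks with tie correction.

    Returns (H, df, p) with p from the chi-squared approximation on k-1
    degrees of freedom. All observations identical across all groups is a
    defined degenerate case: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need >= 3 observations in total")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), df, float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def posthoc_tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey HSD on group means for all unordered pairs.

    ``groups`` maps label -> sample. Returns a frame with columns
    group_a, group_b, mean_diff (a - b), p, direction ('a<b', 'a>b', 'a=b').
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(labels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("Tukey HSD needs >= 2 groups with >= 2 observations each")
    if all(np.allclose(s, s[0]) for s in samples):
        raise ValueError("zero within-group variance everywhere: HSD undefined")
    res = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            diff = samples[i].mean() - samples[j].mean()
            direction = f"{labels[i]}<{labels[j]}" if diff < 0 else (
                f"{labels[i]}>{labels[j]}" if diff > 0 else f"{labels[i]}={labels[j]}")
            rows.append((labels[i], labels[j], diff,
                         float(res.pvalue[i, j]), direction))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p",
                                       "direction"])


def posthoc_dunn(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based all-pairs post-hoc (z on mean ranks, tie-corrected).

    Same output layout as :func:`posthoc_tukey`; raw (unadjusted) p-values.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    bounds = np.cumsum([0] + [len(s) for s in samples])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(labels))]
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ni, nj = len(samples[i]), len(samples[j])
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2 * sps.norm.sf(abs(z))
            diff = samples[i].mean() - samples[j].mean()
            direction = f"{labels[i]}<{labels[j]}" if diff < 0 else (
                f"{labels[i]}>{labels[j]}" if diff > 0 else f"{labels[i]}={labels[j]}")
            rows.append((labels[i], labels[j], diff, float(p), direction))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p",
                                       "direction"])


def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from printed summary statistics.

    Returns (t, df, p) with df = n1 + n2 - 2 and a two-sided p. The sign of t
    follows mean1 - mean2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("degenerate standard deviations")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                    equal_var=True)
    return float(t), n1 + n2 - 2, float(p)


def anova_from_summary(means, sds, ns) -> tuple[float, int, int, float]:
    """One-way ANOVA F from per-group means, SDs and ns.

    Between and within mean squares are reconstructed from the summaries;
    returns (F, df_between, df_within, p).
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    k = len(means)
    if k < 2 or np.any(ns < 2):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if np.all(sds == 0):
        raise ValueError("zero within-group variance everywhere")
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, int(n_total - k)
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))


def mann_whitney_u(sample1, sample2) -> tuple[float, float]:
    """Mann-Whitney U with U = min(U1, U2).

    The p-value is exact (null-distribution enumeration) for small tie-free
    samples with n1*n2 <= 400, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (not ties and len(x) * len(y) <= 400) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, len(x) * len(y) - u1)
    return u, float(res.pvalue)


def chi_squared_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-squared on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# bootstrap Pearson correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    feature: str
    covariate: str
    n: int
    r: float
    p_boot: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def pearson_bootstrap(x, y, n_boot: int = 10_000, seed: int = 0,
                      feature: str = "x", covariate: str = "y") -> CorrelationResult:
    """Pearson r with nonparametric bootstrap CI and two-sided sign-crossing p.

    Missing entries (NaN) are dropped pairwise-complete. B paired resamples
    with replacement give the 2.5-97.5 percentile interval; the two-sided
    bootstrap p is 2 * min(frac of resampled r <= 0, frac >= 0), floored at
    2/B and capped at 1. Deterministic for fixed (n_boot, seed).
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 pairwise-complete observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bx, by = x[idx], y[idx]
    bxc = bx - bx.mean(axis=1, keepdims=True)
    byc = by - by.mean(axis=1, keepdims=True)
    denom = np.sqrt((bxc**2).sum(axis=1) * (byc**2).sum(axis=1))
    valid = denom > 0  # a degenerate resample (constant draw) carries no r
    br = (bxc * byc).sum(axis=1)[valid] / denom[valid]
    ci_low, ci_high = np.percentile(br, [2.5, 97.5])
    p = 2.0 * min((br <= 0).mean(), (br >= 0).mean())
    p = min(1.0, max(p, 2.0 / n_boot))
    return CorrelationResult(feature=feature, covariate=covariate, n=n, r=r,
                             p_boot=float(p), ci_low=float(ci_low),
                             ci_high=float(ci_high), n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# channel-wise group analysis
# ---------------------------------------------------------------------------

# The studentized-range survival function is expensive (numerical integration
# per evaluation). Family-level post-hocs share one (k, df), so p-values are
# interpolated on a cached log-sf grid; the elemental posthoc_tukey stays
# exact. Interpolation error is ~1e-4 on p, far below any decision threshold.
_SRANGE_GRID: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _srange_logsf_grid(k: int, df: int) -> tuple[np.ndarray, np.ndarray]:
    key = (k, df)
    if key not in _SRANGE_GRID:
        q = np.linspace(1e-3, 20.0, 200)
        sf = sps.studentized_range.sf(q, k, df)
        logsf = np.log(np.clip(sf, 1e-300, None))
        _SRANGE_GRID[key] = (q, logsf)
    return _SRANGE_GRID[key]


def _tukey_batch(unit_rows: list[tuple[str, int]], values: np.ndarray,
                 col_idx: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey-Kramer HSD for many units sharing one group layout."""
    labels = list(col_idx)
    k = len(labels)
    ns = np.array([len(col_idx[g]) for g in labels])
    df = int(ns.sum() - k)
    grid_q, grid_logsf = _srange_logsf_grid(k, df)
    rows, qs = [], []
    for unit, ui in unit_rows:
        samples = [values[ui, col_idx[g]] for g in labels]
        means = np.array([s.mean() for s in samples])
        msw = sum(((s - s.mean()) ** 2).sum() for s in samples) / df
        for i in range(k):
            for j in range(i + 1, k):
                diff = means[i] - means[j]
                se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                qs.append(abs(diff) / se if se > 0 else np.inf)
                direction = f"{labels[i]}<{labels[j]}" if diff < 0 else (
                    f"{labels[i]}>{labels[j]}" if diff > 0
                    else f"{labels[i]}={labels[j]}")
                rows.append((unit, labels[i], labels[j], diff, direction))
    qs = np.asarray(qs)
    with np.errstate(over="ignore"):
        p = np.exp(np.interp(qs, grid_q, grid_logsf))
    p[qs <= grid_q[0]] = 1.0
    out = pd.DataFrame(rows, columns=["unit", "group_a", "group_b",
                                      "mean_diff", "direction"])
    out.insert(3, "p", np.clip(p, 0.0, 1.0))
    return out[["unit", "group_a", "group_b", "mean_diff", "p", "direction"]]

@dataclass
class GroupTestReport:
    """Channel-wise (or pair-wise) omnibus results for one test family.

    One family = one feature kind x band x condition; FDR is controlled
    within the family (31 channels, or 465 channel pairs for coherence).
    """

    feature: str
    band: str
    condition: str
    alpha: float
    table: pd.DataFrame  # unit, H, df, p_raw, p_fdr, significant
    posthoc: pd.DataFrame  # unit, group_a, group_b, mean_diff, p, direction

    @property
    def significant_units(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "unit"])


_FEATURE_VALUE = {
    "relative_power": "relative_power",
    "absolute_power": "absolute_power",
    "reactivity": "reactivity",
    "coherence": "coherence",
}


def channelwise_group_analysis(features: pd.DataFrame, feature: str, band: str,
                               condition: str | None, alpha: float = 0.05,
                               posthoc: str = "tukey") -> GroupTestReport:
    """Kruskal-Wallis per channel (or channel pair) with BH-FDR and post-hocs.

    ``features`` is the tidy table for the feature kind: power tables need
    columns subject_id, group, condition, channel, band and the value column;
    coherence tables use ch_a/ch_b pairs; reactivity tables have no condition.
    Post-hoc comparisons (Tukey HSD by default, Dunn optionally) run only on
    units whose omnibus test survives FDR.
    """
    if feature not in _FEATURE_VALUE:
        raise ValueError(f"unknown feature kind {feature!r}")
    value_col = _FEATURE_VALUE[feature]
    sub = features[features["band"] == band]
    if condition is not None and "condition" in sub.columns:
        sub = sub[sub["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no rows for feature={feature} band={band} "
                         f"condition={condition}")
    if feature == "coherence":
        sub = sub.assign(unit=sub["ch_a"] + "-" + sub["ch_b"])
    else:
        sub = sub.assign(unit=sub["channel"])

    posthoc_fn = {"tukey": posthoc_tukey, "dunn": posthoc_dunn}[posthoc]
    # one wide (unit x subject) matrix per family: within a family every unit
    # shares the same subject set, so group membership is resolved once
    wide = sub.pivot_table(index="unit", columns="subject_id",
                           values=value_col, aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("feature table has missing unit x subject cells")
    group_of = sub.drop_duplicates("subject_id").set_index("subject_id")["group"]
    col_idx = {g: np.flatnonzero(group_of[wide.columns].to_numpy() == g)
               for g in sorted(group_of.unique())}
    if len(col_idx) < 2 or any(len(ix) < 3 for ix in col_idx.values()):
        raise ValueError("need >= 2 groups with >= 3 subjects each")
    values = wide.to_numpy()
    stats_rows, samples_by_unit = [], {}
    for ui, unit in enumerate(wide.index):
        groups = {g: values[ui, ix] for g, ix in col_idx.items()}
        h, df, p = kruskal_wallis(*groups.values())
        stats_rows.append((unit, h, df, p))
        samples_by_unit[unit] = groups
    table = pd.DataFrame(stats_rows, columns=["unit", "H", "df", "p_raw"])
    table["p_fdr"] = fdr_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_fdr"] < alpha

    sig_units = list(table.loc[table["significant"], "unit"])
    empty = pd.DataFrame(columns=["unit", "group_a", "group_b", "mean_diff",
                                  "p", "direction"])
    if not sig_units:
        posthoc_table = empty
    elif posthoc == "tukey":
        unit_pos = {u: i for i, u in enumerate(wide.index)}
        posthoc_table = _tukey_batch([(u, unit_pos[u]) for u in sig_units],
                                     values, col_idx)
    else:
        ph_frames = []
        for unit in sig_units:
            ph = posthoc_fn(samples_by_unit[unit])
            ph.insert(0, "unit", unit)
            ph_frames.append(ph)
        posthoc_table = pd.concat(ph_frames, ignore_index=True)
    return GroupTestReport(feature=feature, band=band,
                           condition=condition or "", alpha=alpha,
                           table=table, posthoc=posthoc_table)
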