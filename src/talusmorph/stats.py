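"""Cohort statistics on raw per-specimen records and on (n, mean, SD) summaries.

All two-group comparisons use the pooled-variance (Student) t statistic,
the multi-group comparison is a one-way independent-groups ANOVA, and the
post-hoc procedure is Fisher's LSD (pairwise t on the within-group mean
square, no multiplicity correction). Every test is two-sided. Operating on
summaries makes published (n, mean, SD) tables directly recomputable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "pooled_t_from_summaries",
    "paired_t",
    "oneway_anova_from_summaries",
    "lsd_pairwise",
    "pearson_r",
    "weighted_pool",
    "cohort_report",
    "format_p",
]

REGION_COLUMNS = ("r_am", "r_al", "r_pm", "r_pl", "r_ma", "r_mp")


@dataclass(frozen=True)
class GroupSummary:
    """(n, mean, SD) of one group of measurements (mm)."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError(f"group '{self.label}': n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"group '{self.label}': sd must be >= 0")


@dataclass
class TestResult:
    """One test statistic with its degrees of freedom and two-sided p."""

    statistic: str  # "t", "F" or "r"
    value: float
    df: float | tuple[float, float]
    p_two_sided: float
    label: str = ""
    infinite: bool = False  # zero-variance denominator with a nonzero effect

    def __post_init__(self):
        if not self.infinite and not (0.0 <= self.p_two_sided <= 1.0):
            raise ValidationError(f"p-value out of range: {self.p_two_sided}")

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "value": float(self.value),
            "df": self.df if np.isscalar(self.df) else list(self.df),
            "p_two_sided": float(self.p_two_sided),
            "label": self.label,
        }


def format_p(p: float) -> str:
    """Report-style p formatting: three decimals, '< 0.001' below that."""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def summarize(values, label: str = "") -> GroupSummary:
    """(n, mean, SD) of raw values, with the sample (ddof=1) SD."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("summarize needs a 1-D sample of length >= 2")
    return GroupSummary(n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)), label=label)


def pooled_t_from_summaries(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Independent two-sample Student t from group summaries.

    t = (m1 - m2) / (sp * sqrt(1/n1 + 1/n2)) with the pooled variance
    sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2), df = n1 + n2 - 2.
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    label = f"{g1.label} vs {g2.label}".strip()
    if sp2 == 0.0:
        if diff == 0.0:
            return TestResult("t", 0.0, df, 1.0, label)
        return TestResult("t", math.copysign(math.inf, diff), df, 0.0, label, infinite=True)
    t = diff / math.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("t", t, df, p, label)


def paired_t(x, y, label: str = "") -> TestResult:
    """Paired Student t on matched samples: t = mean(d) / (sd(d)/sqrt(n))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("paired_t needs two matched 1-D samples of length >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if d.mean() == 0.0:
            return TestResult("t", 0.0, df, 1.0, label)
        return TestResult(
            "t", math.copysign(math.inf, d.mean()), df, 0.0, label, infinite=True
        )
    t = d.mean() / (sd / math.sqrt(n))
    return TestResult("t", float(t), df, 2.0 * sps.t.sf(abs(t), df), label)


def _anova_sums(groups: list[GroupSummary]):
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    s = np.array([g.sd for g in groups])
    N = n.sum()
    grand = float((n * m).sum() / N)
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * s**2).sum())
    return N, grand, ssb, ssw


def oneway_anova_from_summaries(groups: list[GroupSummary]) -> TestResult:
    """One-way independent-groups ANOVA from (n, mean, SD) summaries."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    k = len(groups)
    N, _, ssb, ssw = _anova_sums(groups)
    df = (k - 1, N - k)
    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult("F", 0.0, df, 1.0)
        return TestResult("F", math.inf, df, 0.0, infinite=True)
    F = (ssb / df[0]) / (ssw / df[1])
    return TestResult("F", float(F), df, float(sps.f.sf(F, *df)))


def lsd_pairwise(groups: list[GroupSummary]) -> list[TestResult]:
    """Fisher's LSD: unadjusted pairwise t tests on the ANOVA's within-group
    mean square, df = N - k, for every pair of groups."""
    if len(groups) < 2:
        raise ValidationError("LSD needs at least 2 groups")
    k = len(groups)
    N, _, _, ssw = _anova_sums(groups)
    df = N - k
    msw = ssw / df
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = gi.mean - gj.mean
            label = f"{gi.label} vs {gj.label}".strip()
            se = math.sqrt(msw * (1.0 / gi.n + 1.0 / gj.n))
            if se == 0.0:
                if diff == 0.0:
                    results.append(TestResult("t", 0.0, df, 1.0, label))
                else:
                    results.append(
                        TestResult("t", math.copysign(math.inf, diff), df, 0.0, label, True)
                    )
                continue
            t = diff / se
            results.append(TestResult("t", t, df, 2.0 * sps.t.sf(abs(t), df), label))
    return results


def pearson_r(x, y, label: str = "") -> TestResult:
    """Sample Pearson correlation with two-sided p via t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson_r needs two matched 1-D samples of length >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValidationError("pearson_r is undefined for a zero-variance sample")
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return TestResult("r", r, df, 0.0, label)
    t = r * math.sqrt(df / (1.0 - r * r))
    return TestResult("r", r, df, 2.0 * sps.t.sf(abs(t), df), label)


def weighted_pool(groups: list[GroupSummary], label: str = "pooled") -> GroupSummary:
    """Count-weighted pooling of group summaries into one summary.

    The pooled SD is derived from the total sum of squares, i.e. within-group
    plus between-group scatter about the pooled mean.
    """
    if len(groups) == 0:
        raise ValidationError("weighted_pool needs at least one group")
    if len(groups) == 1:
        return groups[0]
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    s = np.array([g.sd for g in groups])
    N = int(n.sum())
    mean = float((n * m).sum() / n.sum())
    ss_total = float(((n - 1) * s**2).sum() + (n * (m - mean) ** 2).sum())
    sd = math.sqrt(ss_total / (N - 1))
    return GroupSummary(n=N, mean=mean, sd=sd, label=label)


def _group_summaries(df: pd.DataFrame, by: str, column: str) -> dict[str, GroupSummary]:
    out = {}
    for key, sub in df.groupby(by, observed=True):
        if len(sub) >= 2:
            out[str(key)] = summarize(sub[column].to_numpy(), label=str(key))
    return out


def cohort_report(records: pd.DataFrame, age_cut: float | str = "median") -> dict:
    """Full cohort statistics on a per-specimen records table.

    Produces, per region and for the cylinder-fit radius: summaries and
    pooled t by sex, by side, and by age group (split at ``age_cut``, by
    default the cohort median age); paired t between sides for bilateral
    specimens matched on specimen id; and the age correlation of the fitted
    radius overall and stratified by sex and side. Comparisons whose groups
    have n < 2 are skipped and listed under "skipped".
    """
    required = {"specimen_id", "sex", "age", "side", *REGION_COLUMNS, "r_cyl"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"records table missing column(s): {sorted(missing)}")
    df = records.copy()
    cut = float(df["age"].median()) if age_cut == "median" else float(age_cut)
    df["age_group"] = np.where(df["age"] <= cut, f"age<={cut:g}", f"age>{cut:g}")

    report: dict = {
        "n_records": int(len(df)),
        "age_cut": cut,
        "summaries": {},
        "tests": {},
        "skipped": [],
    }
    columns = list(REGION_COLUMNS) + ["r_cyl"]

    region_groups = []
    for col in REGION_COLUMNS:
        if len(df) >= 2:
            region_groups.append(summarize(df[col].to_numpy(), label=col))
    if region_groups:
        report["summaries"]["regions"] = {g.label: vars(g) | {} for g in region_groups}
    if len(region_groups) >= 2:
        report["tests"]["anova_regions"] = oneway_anova_from_summaries(region_groups).as_dict()
        report["tests"]["lsd_regions"] = [
            r.as_dict() for r in lsd_pairwise(region_groups)
        ]

    for by, keys in (("sex", ("male", "female")), ("side", ("right", "left")),
                     ("age_group", None)):
        for col in columns:
            groups = _group_summaries(df, by, col)
            names = keys if keys is not None else tuple(sorted(groups))
            if len(names) == 2 and all(k in groups for k in names):
                res = pooled_t_from_summaries(groups[names[0]], groups[names[1]])
                report["tests"][f"t_{by}_{col}"] = res.as_dict()
            else:
                report["skipped"].append(f"t_{by}_{col}: a group has n < 2")

    # matched bilateral comparison per region
    wide = df.pivot_table(index="specimen_id", columns="side", values=columns,
                          aggfunc="first")
    for col in columns:
        if ("right" not in df["side"].values) or ("left" not in df["side"].values):
            report["skipped"].append(f"paired_t_{col}: missing a side")
            continue
        sub = wide[col].dropna(subset=["left", "right"]) if col in wide else None
        if sub is None or len(sub) < 2:
            report["skipped"].append(f"paired_t_{col}: fewer than 2 bilateral pairs")
            continue
        res = paired_t(sub["right"].to_numpy(), sub["left"].to_numpy(),
                       label=f"right vs left {col}")
        report["tests"][f"paired_t_{col}"] = res.as_dict()

    # age correlation of the fitted radius, overall and stratified
    def _corr(sub: pd.DataFrame, name: str):
        if len(sub) < 3 or sub["age"].std() == 0 or sub["r_cyl"].std() == 0:
            report["skipped"].append(f"{name}: insufficient data")
            return
        res = pearson_r(sub["age"].to_numpy(), sub["r_cyl"].to_numpy(), label=name)
        report["tests"][name] = res.as_dict()

    _corr(df, "corr_age_r_cyl")
    for sex in ("male", "female"):
        _corr(df[df["sex"] == sex], f"corr_age_r_cyl_{sex}")
    for side in ("right", "left"):
        _corr(df[df["side"] == side], f"corr_age_r_cyl_{side}")

    return report
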