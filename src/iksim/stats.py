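"""Group comparisons used in the analysis pipeline.

Per-cell summary metrics (V50, T50, tau ratios, ddG0) are compared with the
conventions of the field: group values as mean +/- SEM, one-way ANOVA with
Dunnett's test against a control group, pair-wise Bonferroni-adjusted tests
for named pairs, and a two-tailed one-sample t-test against 1 for paired
time-constant ratios.  Two-sided p < 0.05 counts as significant throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupData:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("group values must be 1-D")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        return float(sps.sem(self.values))


def significance_stars(p: float) -> str:
    """Figure-legend star annotation: * <0.05, ** <0.01, *** <0.001."""
    if not np.isfinite(p):
        return "nd"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _require_groups(groups: list[GroupData]) -> None:
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2, has {g.n}")


def anova_dunnett(groups: list[GroupData], control: str) -> pd.DataFrame:
    """One-way ANOVA with Dunnett's multiple-comparison test vs a control.

    Returns one row per non-control group with the two-sided Dunnett-adjusted
    p-value and its star band; the overall ANOVA F and p are attached in
    ``DataFrame.attrs``.  Degenerate input (zero variance everywhere) is
    flagged rather than reported as a significant difference.
    """
    _require_groups(groups)
    labels = [g.label for g in groups]
    if control not in labels:
        raise ValueError(f"control group {control!r} not among {labels}")
    ctrl = next(g for g in groups if g.label == control)
    others = [g for g in groups if g.label != control]
    if not others:
        raise ValueError("need at least one non-control group")

    pooled = np.concatenate([g.values for g in groups])
    degenerate = np.ptp(pooled) == 0.0
    if degenerate:
        rows = [
            {"group": g.label, "n": g.n, "mean": g.mean, "sem": g.sem, "p_adj": 1.0,
             "stars": "ns", "flag": "degenerate_zero_variance"}
            for g in others
        ]
        df = pd.DataFrame(rows)
        df.attrs.update({"anova_F": 0.0, "anova_p": 1.0, "control": control})
        return df

    res = sps.dunnett(*[g.values for g in others], control=ctrl.values)
    f_stat, anova_p = sps.f_oneway(*[g.values for g in groups])
    rows = []
    for g, p in zip(others, np.atleast_1d(res.pvalue)):
        rows.append(
            {"group": g.label, "n": g.n, "mean": g.mean, "sem": g.sem,
             "p_adj": float(p), "stars": significance_stars(float(p)), "flag": ""}
        )
    df = pd.DataFrame(rows)
    df.attrs.update({"anova_F": float(f_stat), "anova_p": float(anova_p), "control": control})
    return df


def anova_bonferroni_pairs(groups: list[GroupData], pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pair-wise two-sample t-tests with Bonferroni correction.

    Each named pair is tested with a two-sided independent t-test and the raw
    p-value multiplied by the number of pairs (capped at 1), matching the
    homozygous-versus-heterozygous comparisons convention.
    """
    _require_groups(groups)
    by_label = {g.label: g for g in groups}
    for a, b in pairs:
        if a not in by_label or b not in by_label:
            raise ValueError(f"pair ({a!r}, {b!r}) references unknown group")
    m = len(pairs)
    rows = []
    for a, b in pairs:
        ga, gb = by_label[a], by_label[b]
        if np.ptp(np.concatenate([ga.values, gb.values])) == 0.0:
            p_raw = 1.0
            flag = "degenerate_zero_variance"
        else:
            p_raw = float(sps.ttest_ind(ga.values, gb.values).pvalue)
            flag = ""
        p_adj = min(1.0, p_raw * m)
        rows.append(
            {"group_a": a, "group_b": b, "p_raw": p_raw, "p_adj": p_adj,
             "stars": significance_stars(p_adj), "flag": flag}
        )
    return pd.DataFrame(rows)


def one_sample_t_ratio(ratios, mu0: float = 1.0) -> dict:
    """Two-tailed one-sample t-test of paired ratios against ``mu0`` (=1).

    Zero-variance input is flagged degenerate (the t statistic is undefined)
    instead of silently returning NaN.
    """
    x = np.asarray(list(ratios), dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two ratios")
    if np.ptp(x) == 0.0:
        if x[0] == mu0:
            # all ratios exactly at the null value: t = 0, nothing to reject
            return {
                "mean": float(mu0), "sem": 0.0, "n": len(x),
                "t": 0.0, "p": 1.0, "flag": "degenerate_zero_variance",
                "stars": "ns",
            }
        return {
            "mean": float(x.mean()), "sem": 0.0, "n": len(x),
            "t": np.nan, "p": np.nan, "flag": "degenerate_zero_variance",
            "stars": "nd",
        }
    res = sps.ttest_1samp(x, popmean=mu0)
    return {
        "mean": float(x.mean()), "sem": float(sps.sem(x)), "n": len(x),
        "t": float(res.statistic), "p": float(res.pvalue), "flag": "",
        "stars": significance_stars(float(res.pvalue)),
    }
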