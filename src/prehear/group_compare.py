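"""Group-level summaries, hypothesis tests and report tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["GroupComparison", "summarize", "compare", "build_report",
           "significance_stars"]

_TESTS = {"unpaired_t", "paired_t", "mann_whitney", "ks", "chi_square",
          "two_way_anova"}


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    summary_a: str
    summary_b: str
    n_a: int
    n_b: int
    test: str
    statistic: float | None
    p_value: float | None


def summarize(values, style: str = "mean_sem") -> dict:
    """Mean +- SEM (sample sd / sqrt(n)) or median with 25/75% quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if style == "mean_sem":
        sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        return {"style": style, "center": float(np.mean(v)), "spread": sem,
                "n": int(v.size),
                "text": f"{np.mean(v):.4g} ± {sem:.3g}"}
    if style == "median_iqr":
        q25, q50, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
        return {"style": style, "center": float(q50),
                "q25": float(q25), "q75": float(q75), "n": int(v.size),
                "text": f"{q50:.4g} [{q25:.4g}, {q75:.4g}]"}
    raise ValueError(f"unknown summary style {style!r}")


def compare(group_a, group_b, test: str = "mann_whitney",
            paired: bool = False, metric: str = "") -> GroupComparison:
    """Two-tailed comparison with an explicitly chosen standard test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}")
    if a.size < 2 or b.size < 2:
        return GroupComparison(metric, summarize(a)["text"] if a.size else "",
                               summarize(b)["text"] if b.size else "",
                               a.size, b.size, test, None, None)
    if paired or test == "paired_t":
        if a.size != b.size:
            raise ValueError("paired design requires equal group sizes")
        diffs = a - b
        if np.allclose(diffs, 0.0):
            return GroupComparison(metric, summarize(a)["text"],
                                   summarize(b)["text"], a.size, b.size,
                                   "paired_t", 0.0, 1.0)
        res = stats.ttest_rel(a, b)
        return GroupComparison(metric, summarize(a)["text"],
                               summarize(b)["text"], a.size, b.size,
                               "paired_t", float(res.statistic),
                               float(res.pvalue))
    if test == "unpaired_t":
        res = stats.ttest_ind(a, b)
        sa, sb = summarize(a), summarize(b)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        sa, sb = summarize(a, "median_iqr"), summarize(b, "median_iqr")
    elif test == "ks":
        res = stats.ks_2samp(a, b)
        sa, sb = summarize(a, "median_iqr"), summarize(b, "median_iqr")
    else:
        raise ValueError(f"test {test!r} needs dedicated input; "
                         "use compare_isi_distributions or anova helpers")
    return GroupComparison(metric, sa["text"], sb["text"], a.size, b.size,
                           test, float(res.statistic), float(res.pvalue))


def significance_stars(p: float | None) -> str:
    if p is None:
        return "n/a"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def build_report(metrics: dict[str, dict], label_a: str = "WT",
                 label_b: str = "cKO") -> pd.DataFrame:
    """Assemble the panel-style comparison table.

    ``metrics`` maps metric name -> {"a": values, "b": values,
    "test": name, "paired": bool}; metrics with missing data are omitted
    with a warning rather than failing the whole report.
    """
    rows = []
    for name, spec in metrics.items():
        a, b = spec.get("a"), spec.get("b")
        if a is None or b is None or len(a) == 0 or len(b) == 0:
            logger.warning("metric %s missing data; omitted from report", name)
            continue
        comp = compare(a, b, test=spec.get("test", "mann_whitney"),
                       paired=spec.get("paired", False), metric=name)
        rows.append({
            "metric": name,
            label_a: comp.summary_a,
            label_b: comp.summary_b,
            f"n_{label_a}": comp.n_a,
            f"n_{label_b}": comp.n_b,
            "test": comp.test,
            "statistic": comp.statistic,
            "p": comp.p_value,
            "sig": significance_stars(comp.p_value),
        })
    return pd.DataFrame(rows)


def rate_level_anova(levels_db, rates_a: np.ndarray, rates_b: np.ndarray,
                     label_a: str = "WT", label_b: str = "cKO") -> pd.DataFrame:
    """Two-way ANOVA (genotype x level) of rate-level functions.

    ``rates_a``/``rates_b`` are (n_units, n_levels) matrices.  A thin call
    to the standard OLS ANOVA machinery.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    frames = []
    for label, mat in ((label_a, np.asarray(rates_a)),
                       (label_b, np.asarray(rates_b))):
        for u, row in enumerate(mat):
            frames.append(pd.DataFrame({
                "rate": row, "level": np.asarray(levels_db, float),
                "strain": label, "unit": f"{label}-{u}"}))
    data = pd.concat(frames, ignore_index=True)
    model = ols("rate ~ C(strain) * level", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)
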