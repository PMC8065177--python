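"""Per-retina summaries and group comparisons.

Aggregates per-unit classifications into per-retina class counts and the
percentage of light-responsive units, and runs the standard group
comparisons (t tests, one-way ANOVA with Tukey post hoc, two-way ANOVA) as
a thin reporting layer over scipy/statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classification import ResponseClass

__all__ = [
    "RetinaSummary",
    "summarize_retina",
    "summarize_population",
    "compare_groups",
    "significance_stars",
]

GROUPS = ("untreated", "WT_cone", "CNGB3_cone", "Gnat1_ko")


@dataclass(frozen=True)
class RetinaSummary:
    retina_id: str
    group: str
    n_units: int
    pct_light_responsive: float
    class_counts: dict[str, int] = field(default_factory=dict)


def summarize_retina(
    classifications: pd.DataFrame, group: str = "none"
) -> RetinaSummary:
    """Class counts and % light-responsive for one retina's units."""
    if classifications.empty:
        raise ValueError("no units to summarize")
    retina_ids = classifications["retina_id"].astype(str).unique()
    if len(retina_ids) != 1:
        raise ValueError("summarize_retina expects one retina; use summarize_population")
    counts = {cls.value: 0 for cls in ResponseClass}
    for value, n in classifications["response_class"].value_counts().items():
        counts[str(value)] += int(n)
    n_units = int(len(classifications))
    n_nonresponsive = counts[ResponseClass.NON_LIGHT_RESPONSIVE.value]
    pct = 100.0 * (n_units - n_nonresponsive) / n_units
    return RetinaSummary(
        retina_id=str(retina_ids[0]),
        group=group,
        n_units=n_units,
        pct_light_responsive=pct,
        class_counts=counts,
    )


def summarize_population(
    classifications: pd.DataFrame,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One summary row per retina; ``groups`` maps retina_id -> group label."""
    groups = groups or {}
    rows = []
    for retina_id, sub in classifications.groupby("retina_id", sort=True):
        s = summarize_retina(sub, groups.get(str(retina_id), "none"))
        row = {
            "retina_id": s.retina_id,
            "group": s.group,
            "n_units": s.n_units,
            "pct_light_responsive": s.pct_light_responsive,
        }
        for cls in ResponseClass:
            row[f"n_{cls.value}"] = s.class_counts[cls.value]
            row[f"pct_{cls.value}"] = 100.0 * s.class_counts[cls.value] / s.n_units
        rows.append(row)
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Star notation at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_groups(
    samples: dict[str, np.ndarray],
    test: str = "anova",
    paired: bool = False,
) -> pd.DataFrame:
    """Group comparisons; one row per test with statistic, df, p and stars.

    ``test`` is ``"t"`` (two groups, paired or unpaired) or ``"anova"``
    (one-way omnibus followed by Tukey's HSD pairwise post hoc). Groups with
    fewer than 2 observations are excluded with a warning.
    """
    clean: dict[str, np.ndarray] = {}
    for name, values in samples.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            warnings.warn(f"group {name!r} has <2 observations; excluded")
            continue
        clean[name] = arr
    if len(clean) < 2:
        raise ValueError("need at least two groups with >=2 observations")
    names = list(clean)
    rows = []
    if test == "t":
        if len(clean) != 2:
            raise ValueError("t test requires exactly two groups")
        a, b = clean[names[0]], clean[names[1]]
        if paired:
            res = stats.ttest_rel(a, b)
            df = a.size - 1
        else:
            res = stats.ttest_ind(a, b)
            df = a.size + b.size - 2
        rows.append(
            {
                "test": "paired t" if paired else "unpaired t",
                "comparison": f"{names[0]} vs {names[1]}",
                "statistic": float(res.statistic),
                "df": float(df),
                "p": float(res.pvalue),
            }
        )
    elif test == "anova":
        f_res = stats.f_oneway(*clean.values())
        k = len(clean)
        n = sum(a.size for a in clean.values())
        rows.append(
            {
                "test": "one-way ANOVA",
                "comparison": "omnibus",
                "statistic": float(f_res.statistic),
                "df": float(k - 1),
                "p": float(f_res.pvalue),
            }
        )
        tukey = stats.tukey_hsd(*clean.values())
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "test": "Tukey HSD",
                        "comparison": f"{names[i]} vs {names[j]}",
                        "statistic": float(tukey.statistic[i, j]),
                        "df": float(n - k),
                        "p": float(tukey.pvalue[i, j]),
                    }
                )
    else:
        raise ValueError("test must be 't' or 'anova'")
    frame = pd.DataFrame(rows)
    frame["stars"] = frame["p"].map(significance_stars)
    return frame
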