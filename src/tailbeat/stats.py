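"""Group comparisons and episode-duration summaries.

Implements exactly the statistical toolkit of the study: two-tailed paired
and unpaired (equal-variance Student) t tests, one-way ANOVA, Bonferroni
adjustment of the 0.05 critical value, and pooled mean ± SEM summaries of
swimming-episode durations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "ComparisonResult",
    "compare",
    "bonferroni_alpha",
    "format_alpha",
    "episode_duration_summary",
]


@dataclass
class ComparisonResult:
    test: str              # "paired_t" | "unpaired_t" | "anova_oneway"
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    alpha_adjusted: float
    significant: bool


def compare(groups: list, design: str, alpha: float = 0.05,
            n_tests: int = 1) -> ComparisonResult:
    """Two-tailed comparison of observation groups.

    ``design`` is ``"paired"`` (same fish in two conditions),
    ``"unpaired"`` (different fish; classic equal-variance Student t) or
    ``"anova"`` (one-way, >= 2 groups).  The significance flag applies the
    Bonferroni-adjusted critical value ``alpha / n_tests``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("need at least 2 observations per group")
    alpha_adj = bonferroni_alpha(alpha, n_tests)

    if design == "paired":
        if len(groups) != 2 or groups[0].size != groups[1].size:
            raise ValueError("paired design needs two equal-length groups")
        diff = groups[0] - groups[1]
        if np.all(diff == diff[0]):
            if diff[0] == 0.0:  # identical pairs: no effect, by convention
                stat, p = 0.0, 1.0
            else:
                raise ValueError("constant non-zero difference: t undefined")
        else:
            stat, p = _st.ttest_rel(groups[0], groups[1])
        df = groups[0].size - 1
        return ComparisonResult("paired_t", float(stat), df, float(p),
                                alpha_adj, float(p) < alpha_adj)

    if design == "unpaired":
        if len(groups) != 2:
            raise ValueError("unpaired design needs exactly two groups")
        if groups[0].std(ddof=1) == 0.0 and groups[1].std(ddof=1) == 0.0:
            if groups[0].mean() == groups[1].mean():
                stat, p = 0.0, 1.0
            else:
                raise ValueError("zero variance in both groups: t undefined")
        else:
            stat, p = _st.ttest_ind(groups[0], groups[1], equal_var=True)
        df = groups[0].size + groups[1].size - 2
        return ComparisonResult("unpaired_t", float(stat), df, float(p),
                                alpha_adj, float(p) < alpha_adj)

    if design == "anova":
        stat, p = _st.f_oneway(*groups)
        k = len(groups)
        n_total = sum(g.size for g in groups)
        df = (k - 1, n_total - k)
        return ComparisonResult("anova_oneway", float(stat), df, float(p),
                                alpha_adj, float(p) < alpha_adj)

    raise ValueError(f"unknown design {design!r}")


def bonferroni_alpha(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-adjusted critical value alpha / n_tests (exact)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def format_alpha(alpha_adjusted: float, decimals: int = 4) -> str:
    """Display form of an adjusted critical value, truncated (not rounded).

    0.05/3 prints as "0.0166" and 0.05/4 as "0.0125"."""
    scale = 10 ** decimals
    return f"{math.floor(alpha_adjusted * scale) / scale:.{decimals}f}"


def episode_duration_summary(episodes_per_animal: dict,
                             pooled: bool = True) -> tuple[float, float]:
    """Mean and SEM of swimming-episode durations for one group.

    ``episodes_per_animal`` maps animal id -> sequence of episode durations
    (seconds).  ``pooled=True`` (default) pools all episodes, e.g. 10 per
    fish for five fish -> n = 50, SEM = SD/sqrt(50); ``pooled=False``
    averages within animals first and reports SEM across animals.
    """
    if not episodes_per_animal:
        raise ValueError("empty group")
    for animal, durs in episodes_per_animal.items():
        if len(durs) == 0:
            raise ValueError(f"animal {animal!r} contributes no episodes")
    if pooled:
        values = np.concatenate(
            [np.asarray(d, dtype=float) for d in episodes_per_animal.values()])
    else:
        values = np.array([np.mean(d) for d in episodes_per_animal.values()])
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, sem
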