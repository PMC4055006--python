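"""Statistical toolkit of the study, operable on raw replicates or summaries.

Groups are reported as mean +/- SD at a stated n, so every test here accepts
either raw replicate vectors or :class:`GroupSummary` records and gives
identical answers when the replicates realize the summaries exactly:

* Pearson product-moment correlation with the t-based two-sided p,
  t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom;
* Student's two-sample t test, pooled-variance by default (Welch behind a
  flag) — the study does not say which SPSS variant was used and pooled is
  the textbook "Student t";
* one-way ANOVA with Fisher's least-significant-difference (LSD) post-hoc:
  pairwise t on the pooled within-group MSE at N-k degrees of freedom, with
  no multiplicity correction (mirroring the study's LSD usage; a known
  limitation, not a recommendation).

Derived metrics of the study are also here: fold ratios of group means,
relative MRI signal intensity (anterior wall / interventricular septum),
cell-retention rate (detected / infused), and capillary density per mm^2.
All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "StatResult",
    "pearson",
    "two_sample_t",
    "one_way_anova",
    "lsd_posthoc",
    "fold_ratio",
    "relative_signal_intensity",
    "retention_rate",
    "capillary_density",
]


@dataclass(frozen=True)
class GroupSummary:
    """mean +/- SD at n for one experimental group."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_replicates(cls, label: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(label=label, mean=float(np.mean(v)),
                   sd=float(np.std(v, ddof=1)), n=v.size)


@dataclass(frozen=True)
class StatResult:
    """One test statistic with its degrees of freedom and two-sided p."""

    name: str
    value: float
    df: float | tuple
    p: float
    method: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def _as_summary(group, default_label="group") -> GroupSummary:
    if isinstance(group, GroupSummary):
        return group
    return GroupSummary.from_replicates(default_label, group)


def pearson(x, y) -> StatResult:
    """Pearson r with the exact t-based two-sided p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return StatResult(name="r", value=float(r), df=x.size - 2, p=float(p),
                      method="Pearson correlation, t-based two-sided p")


def two_sample_t(a, b, welch: bool = False) -> StatResult:
    """Student's two-sample t on replicates or :class:`GroupSummary` inputs.

    Pooled-variance by default (df = n_a + n_b - 2); ``welch=True`` uses the
    unequal-variance form with Welch-Satterthwaite df.
    """
    sa = _as_summary(a, "a")
    sb = _as_summary(b, "b")
    if sa.sd == 0 and sb.sd == 0 and sa.mean == sb.mean:
        # identical degenerate groups: no evidence of a difference
        return StatResult(name="t", value=0.0, df=sa.n + sb.n - 2, p=1.0,
                          method="Student t (pooled)")
    t, p = sps.ttest_ind_from_stats(sa.mean, sa.sd, sa.n,
                                    sb.mean, sb.sd, sb.n,
                                    equal_var=not welch)
    if welch:
        va, vb = sa.sd ** 2 / sa.n, sb.sd ** 2 / sb.n
        df = (va + vb) ** 2 / (va ** 2 / (sa.n - 1) + vb ** 2 / (sb.n - 1))
        method = "Welch t"
    else:
        df = sa.n + sb.n - 2
        method = "Student t (pooled)"
    if not np.isfinite(t):
        raise ZeroDivisionError("zero pooled variance")
    return StatResult(name="t", value=float(t), df=float(df), p=float(p),
                      method=method)


def _anova_components(groups):
    summaries = [_as_summary(g, f"group{i}") for i, g in enumerate(groups)]
    ns = np.array([s.n for s in summaries])
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    big_n = int(ns.sum())
    k = len(summaries)
    grand = float(np.sum(ns * means) / big_n)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds ** 2))
    return summaries, k, big_n, ss_between, ss_within


def one_way_anova(groups: Sequence) -> StatResult:
    """One-way ANOVA F on (k-1, N-k) df from replicates or summaries."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    _, k, big_n, ssb, ssw = _anova_components(groups)
    df1, df2 = k - 1, big_n - k
    if ssw == 0 and ssb == 0:
        return StatResult(name="F", value=0.0, df=(df1, df2), p=1.0,
                          method="one-way ANOVA")
    if ssw == 0:
        raise ZeroDivisionError("degenerate within-group variance")
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    return StatResult(name="F", value=float(f), df=(df1, df2), p=p,
                      method="one-way ANOVA")


def lsd_posthoc(groups: Sequence) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons after one-way ANOVA.

    Pairwise t uses the pooled MSE across all groups at N-k df; p-values are
    two-sided and deliberately uncorrected for multiplicity (that is what the
    LSD test is). Returns a table with columns group_a, group_b, diff, t, df, p.
    """
    if len(groups) < 3:
        raise ValueError("LSD post-hoc expects >= 3 groups")
    summaries, k, big_n, _, ssw = _anova_components(groups)
    df = big_n - k
    if ssw == 0:
        raise ZeroDivisionError("degenerate within-group variance")
    mse = ssw / df
    rows = []
    for sa, sb in combinations(summaries, 2):
        se = np.sqrt(mse * (1.0 / sa.n + 1.0 / sb.n))
        t = (sa.mean - sb.mean) / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
        rows.append({"group_a": sa.label, "group_b": sb.label,
                     "diff": sa.mean - sb.mean, "t": float(t), "df": df,
                     "p": p})
    return pd.DataFrame(rows)


def fold_ratio(numerator_mean: float, denominator_mean: float) -> float:
    """Plain ratio of group means (reported to 2 decimals in summaries)."""
    if denominator_mean <= 0:
        raise ZeroDivisionError("denominator mean must be positive")
    return numerator_mean / denominator_mean


def relative_signal_intensity(anterior_si, septum_si):
    """Relative MRI signal intensity: anterior wall SI / septum SI."""
    anterior = np.asarray(anterior_si, dtype=float)
    septum = np.asarray(septum_si, dtype=float)
    if np.any(septum <= 0):
        raise ZeroDivisionError("septum signal intensity must be positive")
    out = anterior / septum
    return out if out.ndim else float(out)


def retention_rate(detected_cells, infused_cells):
    """Cell-retention rate: cells detected in the heart / cells infused."""
    detected = np.asarray(detected_cells, dtype=float)
    infused = np.asarray(infused_cells, dtype=float)
    if np.any(infused <= 0):
        raise ZeroDivisionError("infused cell count must be positive")
    rate = detected / infused
    if np.any(rate > 1.0):
        import warnings
        warnings.warn("retention rate > 1 is implausible (more cells detected "
                      "than infused)", stacklevel=2)
    return rate if rate.ndim else float(rate)


def capillary_density(counts, areas_mm2):
    """Capillaries per mm^2, averaged over the counted fields.

    With scalar inputs returns count/area; with per-field vectors returns the
    mean of the field-wise densities (equal-area fields make this identical
    to pooled count / pooled area).
    """
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas_mm2, dtype=float)
    if np.any(areas <= 0):
        raise ZeroDivisionError("field area must be positive")
    dens = counts / areas
    return float(np.mean(dens))
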