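"""Significance tests for per-gene tissue expression distributions.

The tissue-distribution test is a per-gene fixed-effect one-way ANOVA
across tissues (each tissue a group of replicate intensities), either from
raw replicate values or reconstructed from published mean +/- SEM / n
summaries (SEM = sd/sqrt(n), so sd and hence the within-group sum of
squares are recoverable exactly). Post-hoc comparisons use the pooled ANOVA
error: Fisher's protected LSD (pairwise t) or Tukey's HSD (studentized
range; Tukey-Kramer for unequal n). Two-group comparisons use Student's
pooled-variance t test, optionally Welch. Reference-gene (housekeeping,
e.g. cyclophilin) normalization divides each sample by its reference value.

No multiple-testing correction is applied by default; an optional
Benjamini-Hochberg helper is provided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionDataset, ValidationError

ALPHA_DEFAULT = 0.05


@dataclass
class GroupSummary:
    """Per-group mean, SEM and n, e.g. one gene's per-tissue row."""

    labels: list[str]
    means: np.ndarray
    sems: np.ndarray
    ns: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sems = np.asarray(self.sems, dtype=float)
        self.ns = np.asarray(self.ns, dtype=int)
        k = len(self.labels)
        if not (len(self.means) == len(self.sems) == len(self.ns) == k):
            raise ValidationError("GroupSummary fields have mismatched lengths")
        if (self.sems < 0).any():
            raise ValidationError("SEM must be non-negative")

    @property
    def sds(self) -> np.ndarray:
        return self.sems * np.sqrt(self.ns)


@dataclass
class TestResult:
    statistic: float
    df1: float
    df2: float | None
    pvalue: float
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(f"p-value outside [0,1]: {self.pvalue}")


def summarize(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None) -> GroupSummary:
    """Collapse raw replicate groups to mean/SEM/n (ddof=1 sd)."""
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    arrs = [np.asarray(g, dtype=float) for g in groups]
    return GroupSummary(
        labels=labels,
        means=np.array([a.mean() for a in arrs]),
        sems=np.array([a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0 for a in arrs]),
        ns=np.array([len(a) for a in arrs]),
    )


def _check_groups(ns: np.ndarray) -> None:
    if len(ns) < 2:
        raise ValidationError("need at least 2 groups")
    if (ns < 2).any():
        raise ValidationError(f"every group needs n >= 2; got n = {list(ns)}")


def _anova_from_ss(ss_between: float, ss_within: float, k: int, n_total: int,
                   method: str) -> TestResult:
    df1 = k - 1
    df2 = n_total - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0.0:
        # degenerate: no within-group variance
        f = 0.0 if ms_between == 0.0 else np.inf
        p = 1.0 if ms_between == 0.0 else 0.0
    else:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df1, df2))
    if f == 0.0:
        p = 1.0
    return TestResult(statistic=float(f), df1=df1, df2=df2, pvalue=p, method=method,
                      extra={"ms_within": ms_within})


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical between/within F test on raw replicate groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    ns = np.array([len(a) for a in arrs])
    _check_groups(ns)
    grand = np.concatenate(arrs).mean()
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrs))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    return _anova_from_ss(ss_between, ss_within, len(arrs), int(ns.sum()),
                          "one-way ANOVA")


def anova_from_summary(summary: GroupSummary) -> TestResult:
    """One-way ANOVA reconstructed from per-group mean/SEM/n.

    Exactly equals :func:`one_way_anova` when the summary was computed from
    the raw data, since sd_i = SEM_i * sqrt(n_i) recovers the within-group
    sums of squares.
    """
    _check_groups(summary.ns)
    n_total = int(summary.ns.sum())
    grand = float((summary.ns * summary.means).sum() / n_total)
    ss_between = float((summary.ns * (summary.means - grand) ** 2).sum())
    ss_within = float(((summary.ns - 1) * summary.sds ** 2).sum())
    return _anova_from_ss(ss_between, ss_within, len(summary.labels), n_total,
                          "one-way ANOVA (from summary)")


def _pooled(data) -> tuple[GroupSummary, float, int]:
    """Group summary plus pooled MSE and its df from raw groups or a summary."""
    summary = data if isinstance(data, GroupSummary) else summarize(data)
    _check_groups(summary.ns)
    df_within = int(summary.ns.sum()) - len(summary.labels)
    mse = float(((summary.ns - 1) * summary.sds ** 2).sum() / df_within)
    return summary, mse, df_within


def posthoc_pairwise(data, method: str = "lsd") -> pd.DataFrame:
    """All pairwise comparisons on the pooled ANOVA error.

    ``method="lsd"``: Fisher's (protected) least significant difference —
    pairwise t statistics with the pooled MSE and its df. ``method="tukey"``:
    Tukey's HSD via the studentized range on the same pooled MSE
    (Tukey-Kramer standard error for unequal group sizes).

    Returns a DataFrame with one row per unordered pair: ``group_1``,
    ``group_2``, ``mean_diff``, ``statistic``, ``df``, ``pvalue``,
    ``method``.
    """
    if method not in ("lsd", "tukey"):
        raise ValidationError(f"method must be 'lsd' or 'tukey', got {method!r}")
    summary, mse, df_within = _pooled(data)
    k = len(summary.labels)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = summary.means[i] - summary.means[j]
        inv_n = 1.0 / summary.ns[i] + 1.0 / summary.ns[j]
        if method == "lsd":
            se = np.sqrt(mse * inv_n)
            t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf * np.sign(diff))
            p = float(2 * stats.t.sf(abs(t), df_within)) if np.isfinite(t) else 0.0
            stat = float(t)
        else:
            se = np.sqrt(mse / 2.0 * inv_n)
            q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p = float(stats.studentized_range.sf(q, k, df_within)) if np.isfinite(q) else 0.0
            stat = float(q)
        if diff == 0:
            p = 1.0
        rows.append((summary.labels[i], summary.labels[j], float(diff), stat,
                     df_within, min(max(p, 0.0), 1.0), method))
    return pd.DataFrame(
        rows,
        columns=["group_1", "group_2", "mean_diff", "statistic", "df", "pvalue", "method"],
    )


def student_t_test(a: Sequence[float], b: Sequence[float], welch: bool = False) -> TestResult:
    """Two-sided two-sample t test, pooled-variance by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("t test needs n >= 2 in both groups")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # zero variance, equal means
        t, p = 0.0, 1.0
    if t == 0.0:
        p = 1.0
    return TestResult(statistic=t, df1=float(res.df), df2=None, pvalue=p,
                      method="Welch t test" if welch else "Student t test")


def confirm_target_specificity(
    data, target: str, alpha: float = ALPHA_DEFAULT
) -> tuple[bool, TestResult, pd.DataFrame]:
    """Protected-LSD confirmation that ``target`` is the significantly
    highest-expressing group.

    A gene is confirmed when (i) the overall one-way ANOVA is significant
    at ``alpha``, (ii) the target group has the strictly largest mean, and
    (iii) every Fisher's protected LSD comparison of the target against
    another group is significant at ``alpha``. Returns the verdict, the
    overall ANOVA result, and the target-vs-other post-hoc rows.
    """
    summary = data if isinstance(data, GroupSummary) else summarize(data)
    if target not in summary.labels:
        raise ValidationError(f"unknown target group {target!r}")
    overall = anova_from_summary(summary)
    ph = posthoc_pairwise(summary, method="lsd")
    ph = ph[(ph["group_1"] == target) | (ph["group_2"] == target)].reset_index(drop=True)
    ti = summary.labels.index(target)
    is_max = bool(summary.means[ti] > np.delete(summary.means, ti).max())
    confirmed = (
        overall.pvalue < alpha and is_max and bool((ph["pvalue"] < alpha).all())
    )
    return confirmed, overall, ph


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in the pipeline)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def normalize_to_reference(
    dataset: ExpressionDataset, reference_symbol: str
) -> ExpressionDataset:
    """Divide every sample column by that sample's reference-gene value.

    The reference (housekeeping) gene is matched by case-insensitive
    symbol; when several probes carry the symbol their per-sample mean is
    the divisor, so the reference level maps to 1 in every sample. The
    reference must be present and strictly positive in every sample.
    """
    mask = dataset.gene_symbols.str.upper() == reference_symbol.strip().upper()
    if not mask.any():
        raise ValidationError(
            f"reference gene {reference_symbol!r} not found in annotation"
        )
    ref = dataset.values.loc[mask.values].mean(axis=0)
    bad = ref.index[~(ref > 0)].tolist()
    if bad:
        raise ValidationError(
            f"reference gene {reference_symbol!r} missing or nonpositive "
            f"in samples: {bad}"
        )
    return ExpressionDataset(
        species_label=dataset.species_label,
        values=dataset.values.div(ref, axis=1),
        gene_symbols=dataset.gene_symbols,
        metadata=list(dataset.metadata),
    )
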