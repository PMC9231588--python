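"""Group-comparison scheme and summary layer.

The dispatch mirrors common practice in behavioral phenotyping reports:

* per-group Shapiro-Wilk at alpha = 0.05 gates parametric vs nonparametric;
* two groups: Student's t (parametric) or Mann-Whitney U (nonparametric
  fallback — flagged as an extension, since rank-sum is the conventional
  stand-in where the parametric branch is unavailable);
* three or more groups: one-way ANOVA with Dunnett's multiple-comparison
  test against the wild-type reference, or Kruskal-Wallis with Dunn's test
  (Bonferroni-adjusted over the comparisons against the reference);
* paired designs: paired t-test.

All tests are two-tailed. Parametric summaries are mean +/- SEM;
nonparametric summaries are median with a seeded percentile-bootstrap 95%
confidence interval.

The model object :class:`GenotypeComparison` is built from a long-format
DataFrame (one row per fish) and ``fit()`` returns a
:class:`ComparisonResults` carrying the test used, per-group summaries,
p-values and significance stars, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GenotypeComparison",
    "ComparisonResults",
    "GroupSummary",
    "CountSummary",
    "normality_gate",
    "compare",
    "summarize",
    "count_summary",
    "dunn_test",
    "significance_stars",
    "format_p",
]

ALPHA = 0.05

#: significance thresholds and their star strings
STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_LEVELS:
        if p < thr:
            return stars
    return "ns"


def format_p(p: float) -> str:
    """Four significant digits; below 1e-4 rendered as '<0.0001'."""
    if np.isnan(p):
        return "NA"
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.4g}"


# ---------------------------------------------------------------------------
# normality gate and summaries
# ---------------------------------------------------------------------------

def normality_gate(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> str:
    """'parametric' iff every group passes Shapiro-Wilk at ``alpha``.

    Groups need n >= 3. A zero-variance (constant) group has no defined
    normality test and routes to the nonparametric branch.
    """
    for label, v in groups.items():
        v = np.asarray(v, dtype=float)
        if len(v) < 3:
            raise ValueError(f"group {label!r} has n={len(v)} < 3")
        if np.ptp(v) == 0:
            return "nonparametric"  # degenerate: W undefined
        if sps.shapiro(v).pvalue < alpha:
            return "nonparametric"
    return "parametric"


@dataclass
class GroupSummary:
    label: str
    n: int
    style: str  # mean_sem | median_ci
    mean: float = float("nan")
    sem: float = float("nan")
    median: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __str__(self) -> str:
        if self.style == "mean_sem":
            return f"{self.mean:.4g} ± {self.sem:.4g} (n={self.n})"
        return f"{self.median:.4g} [{self.ci_low:.4g}, {self.ci_high:.4g}] (n={self.n})"


def summarize(
    values,
    style: str = "mean_sem",
    *,
    label: str = "",
    n_boot: int = 10_000,
    seed: int = 0,
) -> GroupSummary:
    """Mean +/- SEM, or median with a percentile-bootstrap 95% CI.

    SEM = sd / sqrt(n) with the n-1 denominator in sd. The bootstrap CI is
    the 2.5/97.5 percentile of ``n_boot`` seeded resamples; constant input
    gives a degenerate CI.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("summarize needs n >= 2")
    if style == "mean_sem":
        return GroupSummary(label, len(v), style,
                            mean=float(np.mean(v)),
                            sem=float(np.std(v, ddof=1) / np.sqrt(len(v))))
    if style != "median_ci":
        raise ValueError(f"unknown style {style!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    boot_medians = np.median(v[idx], axis=1)
    lo, hi = np.percentile(boot_medians, [2.5, 97.5])
    return GroupSummary(label, len(v), style,
                        median=float(np.median(v)),
                        ci_low=float(lo), ci_high=float(hi))


# ---------------------------------------------------------------------------
# Dunn's test (vs a reference group)
# ---------------------------------------------------------------------------

def dunn_test(
    groups: dict[str, np.ndarray],
    reference: str,
    *,
    adjust: bool = True,
) -> dict[str, float]:
    """Dunn's rank comparison of each group against ``reference``.

    Pooled mid-ranks with tie correction; per comparison
    ``z = (R̄_ref − R̄_g) / sqrt((N(N+1)/12 − C_tie) (1/n_ref + 1/n_g))``
    with ``C_tie = Σ(t³ − t) / (12 (N − 1))``; two-sided normal p, then
    Bonferroni over the number of comparisons when ``adjust`` is set.
    """
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not among groups")
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    mean_rank: dict[str, float] = {}
    i = 0
    for k in labels:
        n_k = len(groups[k])
        mean_rank[k] = float(np.mean(ranks[i : i + n_k]))
        i += n_k
    others = [k for k in labels if k != reference]
    out: dict[str, float] = {}
    n_ref = len(groups[reference])
    for k in others:
        n_k = len(groups[k])
        se = np.sqrt((N * (N + 1) / 12.0 - tie_c) * (1.0 / n_ref + 1.0 / n_k))
        z = (mean_rank[reference] - mean_rank[k]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust:
            p = min(1.0, p * len(others))
        out[k] = float(p)
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResults:
    """Fitted group comparison for one behavioral metric."""

    metric: str
    design: str
    test_used: str
    branch: str  # parametric | nonparametric
    reference: str | None
    group_summaries: dict[str, GroupSummary]
    p_overall: float
    p_per_comparison: dict[str, float]  # group label -> p vs reference
    p_unadjusted: dict[str, float] = field(default_factory=dict)
    alpha: float = ALPHA
    two_tailed: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def stars(self) -> dict[str, str]:
        return {k: significance_stars(p) for k, p in self.p_per_comparison.items()}

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "design": self.design,
            "test_used": self.test_used,
            "branch": self.branch,
            "reference": self.reference,
            "alpha": self.alpha,
            "two_tailed": self.two_tailed,
            "p_overall": None if np.isnan(self.p_overall) else float(self.p_overall),
            "comparisons": {
                k: {"p": float(p), "p_formatted": format_p(p),
                    "stars": significance_stars(p)}
                for k, p in self.p_per_comparison.items()
            },
            "groups": {
                k: {
                    "n": s.n, "style": s.style,
                    **({"mean": s.mean, "sem": s.sem} if s.style == "mean_sem"
                       else {"median": s.median, "ci95": [s.ci_low, s.ci_high]}),
                }
                for k, s in self.group_summaries.items()
            },
            "notes": self.notes,
        }

    def summary(self) -> str:
        lines = [
            f"Metric: {self.metric}",
            f"Design: {self.design}  Test: {self.test_used} "
            f"({self.branch}, two-tailed, alpha={self.alpha})",
        ]
        if self.reference:
            lines.append(f"Reference group: {self.reference}")
        lines.append("")
        lines.append(f"{'group':<8} {'summary':<36}")
        for k, s in self.group_summaries.items():
            lines.append(f"{k:<8} {str(s):<36}")
        lines.append("")
        if not np.isnan(self.p_overall):
            lines.append(f"Overall p = {format_p(self.p_overall)}")
        for k, p in self.p_per_comparison.items():
            vs = f" vs {self.reference}" if self.reference else ""
            lines.append(f"{k}{vs}: p = {format_p(p)} {significance_stars(p)}")
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines)


class GenotypeComparison:
    """Group-comparison model for one metric across genotypes.

    Parameters
    ----------
    groups : dict of label -> 1-D values (one value per fish)
    metric : metric name for reporting
    design : {"two_group", "multi_group_vs_reference", "paired"}
    reference : reference label for multi-group designs (default "WT")
    """

    def __init__(
        self,
        groups: dict[str, np.ndarray],
        metric: str = "metric",
        design: str | None = None,
        reference: str = "WT",
    ) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
        for k, v in self.groups.items():
            if np.any(~np.isfinite(v)):
                self.groups[k] = v[np.isfinite(v)]
        self.metric = metric
        if design is None:
            design = "two_group" if len(groups) == 2 else "multi_group_vs_reference"
        if design not in ("two_group", "multi_group_vs_reference", "paired"):
            raise ValueError(f"unknown design {design!r}")
        if design in ("two_group", "paired") and len(groups) != 2:
            raise ValueError(f"{design} design requires exactly 2 groups")
        if design == "multi_group_vs_reference":
            if len(groups) < 3:
                raise ValueError("multi_group_vs_reference requires >= 3 groups")
            if reference not in groups:
                raise ValueError(f"reference {reference!r} missing from groups")
        self.design = design
        self.reference = reference if design != "paired" else None

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        metric: str,
        value_col: str = "value",
        group_col: str = "genotype",
        design: str | None = None,
        reference: str = "WT",
    ) -> "GenotypeComparison":
        """Build from a long-format metric table (one row per fish)."""
        sub = data
        if "metric" in data.columns:
            sub = data[data["metric"] == metric]
        groups = {
            str(g): grp[value_col].to_numpy(dtype=float)
            for g, grp in sub.groupby(group_col, sort=False)
        }
        return cls(groups, metric=metric, design=design, reference=reference)

    def fit(self, alpha: float = ALPHA, seed: int = 0) -> ComparisonResults:
        g = self.groups
        labels = list(g)
        branch = normality_gate(g, alpha)
        notes: list[str] = []
        p_unadj: dict[str, float] = {}

        if self.design == "paired":
            a, b = (g[k] for k in labels)
            if len(a) != len(b):
                raise ValueError("paired design requires equal group lengths")
            res = sps.ttest_rel(a, b)
            test_used = "paired_t"
            p_overall = float(res.pvalue)
            p_cmp = {labels[1]: float(res.pvalue)}
            branch = "parametric"
        elif self.design == "two_group":
            a, b = (g[k] for k in labels)
            other = labels[1] if labels[0] == self.reference else labels[0]
            if branch == "parametric":
                res = sps.ttest_ind(a, b, equal_var=True)
                test_used = "student_t"
            else:
                res = sps.mannwhitneyu(a, b, alternative="two-sided")
                test_used = "mann_whitney"
                notes.append(
                    "nonparametric two-group fallback (Mann-Whitney U) — "
                    "extension beyond the named test family"
                )
            p_overall = float(res.pvalue)
            p_cmp = {other: float(res.pvalue)}
        else:  # multi_group_vs_reference
            others = [k for k in labels if k != self.reference]
            if branch == "parametric":
                p_overall = float(sps.f_oneway(*[g[k] for k in labels]).pvalue)
                # seeded quasi-MC so repeated fits are byte-identical
                dn = sps.dunnett(*[g[k] for k in others], control=g[self.reference],
                                 random_state=np.random.default_rng(seed))
                p_cmp = {k: float(p) for k, p in zip(others, dn.pvalue)}
                p_unadj = {
                    k: float(sps.ttest_ind(g[self.reference], g[k]).pvalue)
                    for k in others
                }
                test_used = "anova_dunnett"
            else:
                p_overall = float(sps.kruskal(*[g[k] for k in labels]).pvalue)
                p_cmp = dunn_test(g, self.reference, adjust=True)
                p_unadj = dunn_test(g, self.reference, adjust=False)
                test_used = "kruskal_dunn"

        style = "mean_sem" if branch == "parametric" else "median_ci"
        summaries = {
            k: summarize(v, style, label=k, seed=seed) for k, v in g.items()
        }
        return ComparisonResults(
            metric=self.metric, design=self.design, test_used=test_used,
            branch=branch, reference=self.reference,
            group_summaries=summaries, p_overall=p_overall,
            p_per_comparison=p_cmp, p_unadjusted=p_unadj,
            alpha=alpha, notes=notes,
        )


def compare(
    groups: dict[str, np.ndarray] | pd.DataFrame,
    design: str | None = None,
    *,
    metric: str = "metric",
    reference: str = "WT",
    alpha: float = ALPHA,
    seed: int = 0,
    **from_df_kwargs,
) -> ComparisonResults:
    """One-call group comparison (see :class:`GenotypeComparison`)."""
    if isinstance(groups, pd.DataFrame):
        model = GenotypeComparison.from_dataframe(
            groups, metric=metric, design=design, reference=reference,
            **from_df_kwargs,
        )
    else:
        model = GenotypeComparison(groups, metric=metric, design=design,
                                   reference=reference)
    return model.fit(alpha=alpha, seed=seed)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def format_percent(numerator: int, denominator: int) -> str:
    """'n/N (p%)' with one-decimal half-up rounding; integral percents
    render without the decimal (5% not 5.0%)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must be within [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    pct = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    pct_str = str(pct.quantize(Decimal("1"))) if pct == pct.to_integral_value() else str(pct)
    return f"{numerator}/{denominator} ({pct_str}%)"


@dataclass
class CountSummary:
    """Per-group 'n/N (p%)' summaries for labelled count rows."""

    rows: list[str]
    group_labels: list[str]
    cells: dict[tuple[str, str], tuple[int, int]]  # (row, group) -> (num, den)

    def formatted(self) -> pd.DataFrame:
        data = {
            grp: [format_percent(*self.cells[(row, grp)]) for row in self.rows]
            for grp in self.group_labels
        }
        return pd.DataFrame(data, index=self.rows)

    def percent(self, row: str, group: str) -> float:
        num, den = self.cells[(row, group)]
        return float(
            (Decimal(100 * num) / Decimal(den)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )


def count_summary(
    counts: dict[str, dict[str, tuple[int, int]]],
    group_labels: list[str] | None = None,
) -> CountSummary:
    """Build a count-percentage table from nested
    ``{row: {group: (numerator, denominator)}}`` counts."""
    rows = list(counts)
    if group_labels is None:
        group_labels = list(counts[rows[0]])
    cells = {}
    for row in rows:
        for grp in group_labels:
            num, den = counts[row][grp]
            if den <= 0:
                raise ValueError(f"non-positive denominator in ({row!r}, {grp!r})")
            if not (0 <= num <= den):
                raise ValueError(f"numerator out of range in ({row!r}, {grp!r})")
            cells[(row, grp)] = (int(num), int(den))
    return CountSummary(rows, group_labels, cells)
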