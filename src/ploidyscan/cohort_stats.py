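"""Cohort-level comparisons: contingency tests, rank tests, paired t,
lethal-phase and defect-rate reports.

The 2x2 machinery is closed-form Pearson chi-squared (with an optional
Yates variant) plus two-sided Fisher. Fisher's two-sided p is the sum
of all tables, at the observed margins, whose probability does not
exceed the observed table's — the usual convention, applied both to
2x2 tables (via scipy) and, by direct enumeration, to 2xC tables with
more than two groups. The latter matters because stage-wise frequency
comparisons are naturally three-way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Contingency2x2",
    "TestResult",
    "contingency_test",
    "fisher_exact_2xc",
    "rank_test",
    "paired_t_test",
    "lethal_phase_analysis",
    "defect_rate_report",
]


@dataclass(frozen=True)
class Contingency2x2:
    """Counts: rows are groups, columns are outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("empty table")

    @classmethod
    def from_proportions(
        cls, affected1: int, total1: int, affected2: int, total2: int
    ) -> "Contingency2x2":
        if affected1 > total1 or affected2 > total2:
            raise ValueError("affected exceeds total")
        return cls(affected1, total1 - affected1, affected2, total2 - affected2)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def swapped(self) -> "Contingency2x2":
        return Contingency2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float | None
    p_value: float
    n: tuple[int, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": list(self.n),
            "notes": self.notes,
        }


def contingency_test(table: Contingency2x2, method: str = "chisq") -> TestResult:
    """Pearson chi-squared (df=1, no continuity correction by default),
    Yates-corrected chi-squared, or two-sided Fisher's exact test."""
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2) == 0 or min(c1, c2) == 0:
        raise ValueError("empty margin")
    n = table.total
    notes = []
    if method in ("chisq", "chisq_yates"):
        expected_min = min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / n
        if expected_min < 5:
            notes.append(f"expected count {expected_min:.3g} < 5")
        cross = table.a * table.d - table.b * table.c
        if method == "chisq_yates":
            adj = max(abs(cross) - n / 2.0, 0.0)
            stat = n * adj * adj / (r1 * r2 * c1 * c2)
        else:
            stat = n * cross * cross / (r1 * r2 * c1 * c2)
        p = float(stats.chi2.sf(stat, df=1))
        return TestResult(
            method=method,
            statistic=float(stat),
            p_value=p,
            n=(r1, r2),
            notes="; ".join(notes),
        )
    if method == "fisher":
        odds, p = stats.fisher_exact(
            [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
        )
        return TestResult(
            method="fisher",
            statistic=None,
            p_value=float(p),
            n=(r1, r2),
            notes=f"odds_ratio={float(odds):.6g}",
        )
    raise ValueError(f"unknown method {method!r}")


def fisher_exact_2xc(groups: Sequence[tuple[int, int]], rel_tol: float = 1e-7) -> TestResult:
    """Exact two-sided Fisher test on a 2 x C table given as
    ``[(affected, total), ...]`` per group.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (within ``rel_tol`` relative slack on the comparison).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    affected = []
    totals = []
    for k, t in groups:
        if k < 0 or t <= 0 or k > t:
            raise ValueError(f"bad group counts ({k}, {t})")
        affected.append(int(k))
        totals.append(int(t))
    r1 = sum(affected)
    n = sum(totals)
    if r1 == 0 or r1 == n:
        return TestResult(
            method="fisher_2xc", statistic=None, p_value=1.0, n=tuple(totals),
            notes="degenerate margin",
        )

    # log-probability of a table given row-1 cells x_j:
    #   sum_j log C(total_j, x_j) - log C(N, r1)
    log_denominator = _log_comb(n, r1)

    def log_p(cells: Sequence[int]) -> float:
        return sum(_log_comb(t, x) for t, x in zip(totals, cells)) - log_denominator

    observed_lp = log_p(affected)
    cutoff = observed_lp + math.log1p(rel_tol)

    total_p = 0.0
    cells = [0] * len(totals)

    def recurse(j: int, remaining: int, partial_lp: float) -> None:
        nonlocal total_p
        if j == len(totals) - 1:
            if remaining <= totals[j]:
                lp = partial_lp + _log_comb(totals[j], remaining)
                if lp <= cutoff:
                    total_p += math.exp(lp)
            return
        tail_capacity = sum(totals[j + 1 :])
        lo = max(0, remaining - tail_capacity)
        hi = min(totals[j], remaining)
        for x in range(lo, hi + 1):
            recurse(j + 1, remaining - x, partial_lp + _log_comb(totals[j], x))

    recurse(0, r1, -log_denominator)
    return TestResult(
        method="fisher_2xc",
        statistic=None,
        p_value=min(total_p, 1.0),
        n=tuple(totals),
    )


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def rank_test(samples: Sequence[Sequence[float]], method: str) -> TestResult:
    """Mann-Whitney U (two samples) or Kruskal-Wallis (three or more).

    Mann-Whitney switches to exact null enumeration when the combined
    sample is small (n1+n2 <= 12) and tie-free; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty sample")
    sizes = tuple(int(a.size) for a in arrays)
    if method == "mann_whitney":
        if len(arrays) != 2:
            raise ValueError("mann_whitney takes exactly 2 samples")
        x, y = arrays
        pooled = np.concatenate([x, y])
        tie_free = np.unique(pooled).size == pooled.size
        exact = tie_free and (x.size + y.size) <= 12
        res = stats.mannwhitneyu(
            x,
            y,
            alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
        return TestResult(
            method="mann_whitney",
            statistic=float(res.statistic),
            p_value=float(min(res.pvalue, 1.0)),
            n=sizes,
            notes="exact" if exact else "normal approximation, tie-corrected",
        )
    if method == "kruskal_wallis":
        if len(arrays) < 3:
            raise ValueError("kruskal_wallis requires >= 3 samples")
        try:
            stat, p = stats.kruskal(*arrays)
        except ValueError as exc:  # all values identical
            if "identical" in str(exc):
                return TestResult(
                    method="kruskal_wallis", statistic=0.0, p_value=1.0,
                    n=sizes, notes="all values identical",
                )
            raise
        return TestResult(
            method="kruskal_wallis",
            statistic=float(stat),
            p_value=float(p),
            n=sizes,
            notes="chi-squared approximation, tie-corrected",
        )
    raise ValueError(f"unknown method {method!r}")


def paired_t_test(
    pairs: Sequence[tuple[float, float]], normality_check: bool = True
) -> TestResult:
    """Two-sided paired t-test on (x, y) pairs, optionally preceded by
    Shapiro-Wilk checks of each margin (recorded in notes)."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate pairs: zero-variance differences")
    n = d.size
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    notes = []
    if normality_check:
        for label, v in (("x", x), ("y", y)):
            if np.unique(v).size > 1:
                sw = stats.shapiro(v)
                notes.append(f"shapiro_{label}_p={float(sw.pvalue):.4g}")
            else:
                notes.append(f"shapiro_{label}_p=NA (constant)")
    return TestResult(
        method="paired_t",
        statistic=t,
        p_value=p,
        n=(n,),
        notes="; ".join(notes),
    )


def lethal_phase_analysis(
    counts: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
    cohort=None,
    crosses: Iterable[str] | None = None,
    method: str = "chisq",
) -> dict:
    """Blastulation vs hatch per cross.

    ``counts`` maps cross -> {"blastula": (k, n), "hatch": (k, n)};
    alternatively pass a simulated/observed cohort table. For each
    cross the report carries both percentages, their difference (the
    late lethal-phase estimate) and a pooled contingency test between
    the two scored populations.
    """
    if counts is None:
        if cohort is None:
            raise ValueError("provide counts or a cohort")
        counts = {
            cross: cohort.counts(cross)
            for cross in cohort.df["cross"].unique()
        }
    if crosses is not None:
        missing = [c for c in crosses if c not in counts]
        if missing:
            raise ValueError(f"missing crosses: {missing}")
        counts = {c: counts[c] for c in crosses}
    report = {}
    for cross, kv in counts.items():
        (bk, bn) = kv["blastula"]
        (hk, hn) = kv["hatch"]
        if bn == 0 or hn == 0:
            raise ValueError(f"cross {cross!r}: zero scored embryos")
        blast_pct = 100.0 * bk / bn
        hatch_pct = 100.0 * hk / hn
        table = Contingency2x2.from_proportions(bk, bn, hk, hn)
        report[cross] = {
            "blastulation_percent": blast_pct,
            "hatch_percent": hatch_pct,
            "deficit_percent_points": blast_pct - hatch_pct,
            "test": contingency_test(table, method=method).to_dict(),
        }
    return report


def defect_rate_report(
    groups: Mapping[str, tuple[int, int]],
    comparisons: Sequence[tuple[str, str, str]] = (),
) -> dict:
    """Proportions (percent affected) per named group plus pairwise
    tests. Each comparison is (groupA, groupB, method) with method one
    of chisq / chisq_yates / fisher."""
    proportions = {}
    for name, (k, t) in groups.items():
        if t <= 0:
            raise ValueError(f"group {name!r}: zero total")
        if k < 0 or k > t:
            raise ValueError(f"group {name!r}: bad counts ({k}, {t})")
        proportions[name] = {
            "affected": int(k),
            "total": int(t),
            "percent": 100.0 * k / t,
            "percent_rounded": round(100.0 * k / t),
        }
    results = []
    for ga, gb, method in comparisons:
        for g in (ga, gb):
            if g not in groups:
                raise KeyError(f"unknown group {g!r}")
        table = Contingency2x2.from_proportions(*groups[ga], *groups[gb])
        results.append(
            {
                "groups": [ga, gb],
                "test": contingency_test(table, method=method).to_dict(),
            }
        )
    return {"proportions": proportions, "comparisons": results}
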