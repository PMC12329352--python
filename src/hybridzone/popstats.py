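"""Basin-by-year class summaries and tests of proportion change.

``summarize`` tabulates the final classes (pure *P. nigromaculatus*,
pure *P. p. porosus*, pure *P. p. brevipodus*, hybrid) for one basin and
year; unresolved specimens are excluded from the denominator and
reported separately, since the published proportions are over specimens
genetically analysed.  Proportions are printed to one decimal with
half-up rounding.

``test_change`` compares two years class-by-class with Pearson 2x2
chi-squared tests (no continuity correction by default) and Bonferroni
correction; the corrected p is min(1, k * p_raw) and significance is at
alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from hybridzone.classify import ClassifiedSpecimen

__all__ = [
    "CLASSES",
    "BasinYearSummary",
    "TestResult",
    "PopstatsError",
    "round_percent",
    "summarize",
    "chi2_2x2",
    "test_change",
    "summaries_to_frame",
    "tests_to_frame",
]

#: the countable final classes, in publication column order
CLASSES = ("pure_N", "pure_P", "pure_B", "hybrid")


class PopstatsError(ValueError):
    """Empty selection or degenerate contingency table."""


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Percentage at fixed decimals with half-up rounding (the convention
    that reproduces the published tables)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(str(fraction)) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    )


@dataclasses.dataclass(frozen=True)
class BasinYearSummary:
    basin: str
    year: int
    site_filter: str
    counts: Mapping[str, int]
    n_unresolved: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        total = self.total
        return {cls: count / total for cls, count in self.counts.items()}

    @property
    def percentages(self) -> dict[str, float]:
        """Proportions as percentages rounded to one decimal, half-up."""
        return {
            cls: round_percent(frac) for cls, frac in self.proportions.items()
        }


@dataclasses.dataclass(frozen=True)
class TestResult:
    basin: str
    class_tested: str
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    df: int
    p_raw: float
    k: int
    p_corrected: float
    significant: bool
    note: str = ""


def summarize(
    classified: Iterable[ClassifiedSpecimen],
    basin: str,
    year: int,
    site_filter: Callable[[int], bool] | None = None,
    site_filter_label: str = "all sites",
) -> BasinYearSummary:
    """Count final classes for one basin and year.

    ``site_filter`` optionally restricts by site id (e.g. to exclude
    sites newly added in a later survey so years stay comparable);
    ``site_filter_label`` documents the restriction in the output.
    """
    counts = {cls: 0 for cls in CLASSES}
    n_unresolved = 0
    n_selected = 0
    for c in classified:
        if c.basin != basin or c.year != year:
            continue
        if site_filter is not None and not site_filter(c.site_id):
            continue
        n_selected += 1
        if c.final_class == "unresolved":
            n_unresolved += 1
        elif c.final_class in counts:
            counts[c.final_class] += 1
    if n_selected == 0:
        raise PopstatsError(
            f"no specimens selected for basin={basin!r}, year={year}"
        )
    return BasinYearSummary(
        basin=basin,
        year=year,
        site_filter=site_filter_label,
        counts=counts,
        n_unresolved=n_unresolved,
    )


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared for the 2x2 table [[a, b], [c, d]], df = 1,
    without continuity correction; p from the upper tail."""
    for value in (a, b, c, d):
        if value < 0:
            raise PopstatsError("negative cell count")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise PopstatsError("zero margin in 2x2 table")
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def chi2_2x2_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected variant, available behind the configuration flag."""
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise PopstatsError("zero margin in 2x2 table")
    n = a + b + c + d
    num = n * max(abs(a * d - b * c) - n / 2, 0) ** 2
    chi2 = num / ((a + b) * (c + d) * (a + c) * (b + d))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def test_change(
    summary_t1: BasinYearSummary,
    summary_t2: BasinYearSummary,
    classes: Sequence[str] = ("pure_N", "pure_P", "pure_B", "hybrid"),
    k: int | None = None,
    alpha: float = 0.05,
    yates: bool = False,
) -> list[TestResult]:
    """Test each class's proportion change between two years in one basin.

    Each class is tested class-vs-rest in a 2x2 table against year; the
    Bonferroni multiplier ``k`` defaults to the number of classes
    actually tested (classes absent in both years are skipped with a
    note and do not count toward ``k``).
    """
    if summary_t1.basin != summary_t2.basin:
        raise PopstatsError("summaries are from different basins")
    testable = []
    skipped = []
    for cls in classes:
        a = summary_t1.counts.get(cls, 0)
        c = summary_t2.counts.get(cls, 0)
        if a == 0 and c == 0:
            skipped.append(cls)
            continue
        testable.append((cls, a, summary_t1.total - a, c, summary_t2.total - c))
    multiplier = k if k is not None else len(testable)
    if multiplier < len(testable):
        raise PopstatsError(
            f"Bonferroni multiplier {multiplier} < number of tests "
            f"{len(testable)}"
        )
    results = []
    test = chi2_2x2_yates if yates else chi2_2x2
    for cls, a, b, c, d in testable:
        chi2, p_raw = test(a, b, c, d)
        p_corr = min(1.0, multiplier * p_raw)
        results.append(
            TestResult(
                basin=summary_t1.basin,
                class_tested=cls,
                table=((a, b), (c, d)),
                chi2=chi2,
                df=1,
                p_raw=p_raw,
                k=multiplier,
                p_corrected=p_corr,
                significant=p_corr < alpha,
            )
        )
    for cls in skipped:
        results.append(
            TestResult(
                basin=summary_t1.basin,
                class_tested=cls,
                table=((0, summary_t1.total), (0, summary_t2.total)),
                chi2=float("nan"),
                df=1,
                p_raw=float("nan"),
                k=multiplier,
                p_corrected=float("nan"),
                significant=False,
                note="class absent in both years; skipped",
            )
        )
    return results


def summaries_to_frame(summaries: Iterable[BasinYearSummary]) -> pd.DataFrame:
    """Tabulate summaries in the publication column layout."""
    rows = []
    for s in summaries:
        pct = s.percentages
        rows.append(
            {
                "basin": s.basin,
                "year": s.year,
                "sites": s.site_filter,
                **{cls: s.counts.get(cls, 0) for cls in CLASSES},
                **{f"{cls}_pct": pct.get(cls, 0.0) for cls in CLASSES},
                "total": s.total,
                "unresolved": s.n_unresolved,
            }
        )
    return pd.DataFrame(rows)


def tests_to_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        (a, b), (c, d) = r.table
        rows.append(
            {
                "basin": r.basin,
                "class": r.class_tested,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "chi2": r.chi2,
                "df": r.df,
                "p_raw": r.p_raw,
                "k": r.k,
                "p_corrected": r.p_corrected,
                "significant": r.significant,
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)
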