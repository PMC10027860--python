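"""Cohort-level statistics: allele-frequency tables, baseline summaries,
penetrance fractions and exact tests.

Percent formatting rounds half up at the configured precision and the raw
fraction is always carried alongside the formatted text, so downstream
users are never forced to reparse a rounded string.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "GenoPhenoCounts",
    "TwoByTwo",
    "allele_frequency_table",
    "penetrance",
    "fisher_exact_2x2",
    "binomial_vs_reference",
    "cohort_summary",
    "percent_text",
]


def percent_text(fraction: float, decimals: int = 2) -> str:
    """Format a fraction as a percent string, rounding half up."""
    q = Decimal(1).scaleb(-decimals) if decimals else Decimal(1)
    return str((Decimal(str(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortTable:
    """Per-allele counts and frequencies for one diploid cohort."""

    label: str
    table: pd.DataFrame  # columns: allele, count, frequency, percent
    n_individuals: int

    @property
    def total_alleles(self) -> int:
        return 2 * self.n_individuals

    def percent(self, allele: str) -> str:
        row = self.table.loc[self.table["allele"] == allele]
        if row.empty:
            raise KeyError(allele)
        return row["percent"].iloc[0]

    def frequency(self, allele: str) -> float:
        row = self.table.loc[self.table["allele"] == allele]
        if row.empty:
            raise KeyError(allele)
        return float(row["frequency"].iloc[0])


def allele_frequency_table(
    counts: Mapping[str, int],
    n_individuals: int,
    *,
    label: str = "cohort",
    decimals: int = 2,
) -> CohortTable:
    """Allele frequencies over ``2 * n_individuals`` chromosomes.

    The counts must account for every chromosome; a mismatch is a
    consistency error, not silently renormalised.
    """
    total = 2 * n_individuals
    got = sum(counts.values())
    if got != total:
        raise ValueError(
            f"allele counts sum to {got} but 2 x {n_individuals} individuals "
            f"= {total} chromosomes (difference {got - total:+d})"
        )
    rows = [
        {"allele": allele, "count": count,
         "frequency": count / total,
         "percent": percent_text(count / total, decimals)}
        for allele, count in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["allele", "count", "frequency", "percent"])
    return CohortTable(label=label, table=df, n_individuals=n_individuals)


@dataclass(frozen=True)
class GenoPhenoCounts:
    """Affected / total for one genotype group."""

    group: str
    affected: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.affected <= self.total):
            raise ValueError(f"{self.group}: need 0 <= affected <= total")


def penetrance(counts: GenoPhenoCounts, *, percent_style: str = "integer"):
    """Fraction of individuals of a genotype showing the phenotype.

    ``percent_style='integer'`` rounds half up to whole percent (the style
    used for animal-model penetrance reporting); ``'raw'`` keeps two
    decimals.  A group with no individuals has undefined penetrance and
    returns ``(None, None)``.
    """
    if counts.total == 0:
        return None, None
    fraction = counts.affected / counts.total
    decimals = 0 if percent_style == "integer" else 2
    return fraction, percent_text(fraction, decimals) + "%"


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table; rows are cohorts, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")


def fisher_exact_2x2(table: TwoByTwo, *, alternative: str = "two_sided"):
    """Exact hypergeometric test of association in a 2x2 table.

    The two-sided p-value sums the probabilities of all tables (with the
    observed margins) whose point probability does not exceed the
    observed one.  The odds ratio is the sample odds ratio ``ad/bc``
    (``inf`` when ``bc = 0`` with ``ad > 0``; undefined — ``None`` — when
    both products vanish).
    """
    if table.a + table.b == 0 or table.c + table.d == 0 \
            or table.a + table.c == 0 or table.b + table.d == 0:
        return {"p_value": None, "odds_ratio": None, "note": "degenerate margin"}
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    arr = [[table.a, table.b], [table.c, table.d]]
    result = stats.fisher_exact(arr, alternative=alt)
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        odds = None if ad == 0 else float("inf")
    else:
        odds = ad / bc
    return {"p_value": float(result.pvalue), "odds_ratio": odds}


def binomial_vs_reference(x: int, n: int, p0: float, alternative: str = "two_sided") -> float:
    """Exact binomial test of an observed proportion against a fixed reference.

    Suited to comparing a cohort proportion with a published population
    value for which only the proportion, not the counts, is available.
    """
    if not (0 < p0 < 1):
        raise ValueError(f"reference proportion must be in (0,1), got {p0}")
    if not (0 <= x <= n):
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    return float(stats.binomtest(x, n, p0, alternative=alt).pvalue)


def cohort_summary(patients: pd.DataFrame, *, decimals: int = 2) -> dict:
    """Baseline cohort summary: n, mean age ± SD, category counts and percents.

    Expects one row per index case with columns ``sex`` ("M"/"F"),
    ``age`` (years), ``family_history`` (bool) and ``sievers_type``;
    unknown or missing Sievers categories are counted under
    "Not determined".
    """
    n = len(patients)
    if n == 0:
        return {"n": 0, "mean_age": None, "sd_age": None,
                "male": None, "family_history": None, "sievers": {}}
    age = patients["age"].astype(float)
    n_male = int((patients["sex"] == "M").sum())
    n_fam = int(patients["family_history"].astype(bool).sum())

    sievers: dict[str, dict] = {}
    types = patients["sievers_type"].fillna("Not determined").replace("", "Not determined")
    for cat, cnt in types.value_counts().items():
        sievers[str(cat)] = {"count": int(cnt),
                             "percent": percent_text(cnt / n, decimals)}

    return {
        "n": n,
        "mean_age": float(age.mean()),
        "sd_age": float(age.std(ddof=1)) if n > 1 else 0.0,
        "male": {"count": n_male, "percent": percent_text(n_male / n, decimals)},
        "family_history": {"count": n_fam, "percent": percent_text(n_fam / n, decimals)},
        "sievers": sievers,
    }
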