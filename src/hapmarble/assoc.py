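"""Allele-versus-melting-temperature association statistics.

Fat melting temperature (Tm) is dichotomized at a convenience cutoff
(default 37 °C, roughly the median in long-fed Wagyu) and crossed against
marker alleles; the counting unit is the allele occurrence, so each typed
animal contributes two counts per locus.  The tests are implemented from
first principles: Fisher's exact test sums hypergeometric point
probabilities with fixed margins (two-sided by the sum-of-small-
probabilities convention), and the Pearson chi-squared p-value comes from
the regularized upper incomplete gamma function.  No continuity
correction is applied anywhere, and raw p-values are reported without
multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaincc, gammaln, stdtr

from .pedigree import Genotype
from .schema import MarkerSchema

__all__ = [
    "ChiSquareResult",
    "ContingencyTable",
    "GroupSummary",
    "TTestResult",
    "TmRecord",
    "build_allele_contingency",
    "chi_square_test",
    "dichotomize_tm",
    "fisher_exact_2x2",
    "group_summary",
    "two_sample_t",
]

BELOW = "below"
AT_OR_ABOVE = "at_or_above"


@dataclass
class TmRecord:
    """One animal's phenotype record: Tm (°C), days on feed, depot."""

    animal_id: str
    tm: Optional[float]
    dof: float = 0.0
    depot: str = "subcutaneous"
    marbling_score: Optional[int] = None

    def validate(self, tm_window: tuple[float, float] = (20.0, 60.0)) -> "TmRecord":
        if self.tm is not None and not tm_window[0] <= self.tm <= tm_window[1]:
            raise ValueError(
                f"{self.animal_id}: Tm {self.tm} outside plausibility window "
                f"{tm_window}"
            )
        if self.dof < 0:
            raise ValueError(f"{self.animal_id}: negative days on feed {self.dof}")
        if self.depot not in {"intramuscular", "subcutaneous"}:
            raise ValueError(f"{self.animal_id}: unknown depot {self.depot!r}")
        return self


def dichotomize_tm(
    records: Iterable[TmRecord], cutoff: float = 37.0
) -> tuple[dict[str, str], list[str]]:
    """Label each record ``below`` (Tm < cutoff) or ``at_or_above`` (Tm >= cutoff).

    Returns the labels keyed by animal id plus the ids excluded for a
    missing Tm.
    """
    labels: dict[str, str] = {}
    excluded: list[str] = []
    for r in records:
        if r.tm is None:
            excluded.append(r.animal_id)
        else:
            labels[r.animal_id] = BELOW if r.tm < cutoff else AT_OR_ABOVE
    return labels, excluded


@dataclass
class ContingencyTable:
    """Integer count table with labelled rows (Tm classes) and columns (alleles)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_text(self) -> str:
        """Printed layout: Tm classes as rows, allele labels as columns."""
        widths = [max(6, len(c) + 2) for c in self.col_labels]
        lines = [
            "Tm".ljust(12)
            + "".join(c.rjust(w) for c, w in zip(self.col_labels, widths))
            + "Total".rjust(8)
        ]
        for label, row in zip(self.row_labels, self.counts):
            lines.append(
                label.ljust(12)
                + "".join(str(v).rjust(w) for v, w in zip(row, widths))
                + str(row.sum()).rjust(8)
            )
        lines.append(
            "Total".ljust(12)
            + "".join(str(v).rjust(w) for v, w in zip(self.col_margins, widths))
            + str(self.grand_total).rjust(8)
        )
        return "\n".join(lines)


def build_allele_contingency(
    genotypes: Mapping[str, Genotype],
    records: Iterable[TmRecord],
    locus: str,
    schema: MarkerSchema,
    cutoff: float = 37.0,
) -> ContingencyTable:
    """Cross allele occurrences at ``locus`` against Tm classes.

    Each animal typed at the locus contributes its two allele labels to its
    Tm-class row; animals untyped at this locus (or lacking Tm) are
    excluded from this locus's table only, which is why grand totals can
    differ between loci of the same cohort.
    """
    if locus not in schema.locus_names:
        raise ValueError(f"locus {locus!r} not in schema {schema.locus_names}")
    labels, _ = dichotomize_tm(records, cutoff)
    observed_alleles = sorted(
        {
            a
            for animal_id, tm_class in labels.items()
            if (gt := genotypes.get(animal_id)) is not None
            and gt.calls.get(locus) is not None
            for a in gt.calls[locus]
        }
    )
    col_labels = tuple(a for a in schema.alleles(locus) if a in observed_alleles)
    row_labels = (BELOW, AT_OR_ABOVE)
    counts = np.zeros((2, len(col_labels)), dtype=int)
    col_index = {a: j for j, a in enumerate(col_labels)}
    for animal_id, tm_class in labels.items():
        gt = genotypes.get(animal_id)
        if gt is None:
            continue
        pair = gt.calls.get(locus)
        if pair is None:
            continue
        i = row_labels.index(tm_class)
        for allele in pair:
            counts[i, col_index[allele]] += 1
    return ContingencyTable(row_labels, col_labels, counts)


def _as_2x2(table) -> np.ndarray:
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {counts.shape}")
    if np.any(counts < 0) or not np.all(counts == np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    return counts.astype(np.int64)


def _log_hypergeom_pmf(a: np.ndarray, r1: int, c1: int, n: int) -> np.ndarray:
    # P(A = a | margins) for the 2x2 table [[a, r1-a], [c1-a, n-r1-c1+a]]
    return (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        + gammaln(n - r1 + 1)
        - gammaln(c1 - a + 1)
        - gammaln(n - r1 - c1 + a + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value for a 2x2 table.

    With all margins fixed the top-left cell follows a hypergeometric
    distribution; the two-sided p-value sums the point probabilities of
    every table whose probability does not exceed the observed one (with a
    1e-7 relative tolerance against ties lost to rounding).  One-sided
    alternatives (``less``/``greater``, on the top-left cell) are also
    available.
    """
    counts = _as_2x2(table)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("all-zero table: the test is undefined")
    r1 = int(counts[0].sum())
    c1 = int(counts[:, 0].sum())
    a_obs = int(counts[0, 0])
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    logp = _log_hypergeom_pmf(support, r1, c1, n)
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    p_obs = pmf[support == a_obs][0]
    if alternative == "two-sided":
        p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    elif alternative == "less":
        p = pmf[support <= a_obs].sum()
    elif alternative == "greater":
        p = pmf[support >= a_obs].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(1.0, p))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def chi_square_test(table) -> ChiSquareResult:
    """Pearson chi-squared test of independence on an r x c table.

    Expected counts come from the margins; the statistic is
    ``sum((O - E)^2 / E)`` with no continuity correction, on
    ``(r - 1)(c - 1)`` degrees of freedom.  The upper-tail p-value is the
    regularized incomplete gamma ``Q(df / 2, statistic / 2)``.
    """
    counts = (
        table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    ).astype(float)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if np.any(row == 0):
        raise ValueError(f"zero row margin at row {int(np.argmax(row == 0))}")
    if np.any(col == 0):
        raise ValueError(f"zero column margin at column {int(np.argmax(col == 0))}")
    expected = np.outer(row, col) / counts.sum()
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(gammaincc(df / 2.0, stat / 2.0))
    return ChiSquareResult(statistic=stat, df=df, p=p)


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    n: int
    sem: Optional[float]  # undefined (None) for n = 1


def group_summary(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, GroupSummary]:
    """Per-group mean, n and standard error of the mean (sample sd / sqrt(n))."""
    out: dict[str, GroupSummary] = {}
    for key, values in values_by_group.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {key!r} is empty")
        if v.size == 1:
            out[key] = GroupSummary(mean=float(v[0]), n=1, sem=None)
        else:
            sem = float(v.std(ddof=1) / math.sqrt(v.size))
            out[key] = GroupSummary(mean=float(v.mean()), n=int(v.size), sem=sem)
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero pooled variance with unequal means


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Classical pooled-variance two-sample Student's t-test, two-sided."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(
            t=math.copysign(math.inf, diff), df=df, p=0.0, degenerate=True
        )
    se = math.sqrt(pooled_var * (1 / a.size + 1 / b.size))
    t = diff / se
    p = float(2.0 * stdtr(df, -abs(t)))
    return TTestResult(t=float(t), df=df, p=p)
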