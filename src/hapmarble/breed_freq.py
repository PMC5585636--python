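"""Per-breed haplotype frequencies and the W-plot partition.

Frequencies are computed over *chromosomes* (two per animal), counting only
haplotype copies whose phase was empirically resolved; unresolved or
partial copies are excluded from both numerator and denominator.  The W
plot partitions the haplotype set of a two-breed comparison into shared
haplotypes and those found in one breed but effectively absent from the
other.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .haplotype import OBSERVED_PROVENANCES, Diplotype, Provenance
from .phasing import PhaseResult

__all__ = [
    "FreqTable",
    "WPlotCategory",
    "WPlotEntry",
    "WPlotData",
    "common_haplotypes",
    "estimate_frequencies",
    "wplot_partition",
    "write_freq_tsv",
    "write_wplot_tsv",
]


@dataclass
class FreqTable:
    """Haplotype counts and frequencies per breed, over resolved chromosomes."""

    counts: dict[str, Counter] = field(default_factory=dict)
    chromosomes: dict[str, int] = field(default_factory=dict)

    @property
    def breeds(self) -> tuple[str, ...]:
        return tuple(sorted(self.counts))

    @property
    def empty_breeds(self) -> tuple[str, ...]:
        """Breeds with zero resolved chromosomes (no frequencies defined)."""
        return tuple(b for b in self.breeds if self.chromosomes.get(b, 0) == 0)

    def haplotypes(self) -> tuple[str, ...]:
        haps: set[str] = set()
        for c in self.counts.values():
            haps.update(c)
        return tuple(sorted(haps))

    def freq(self, breed: str, haplotype: str) -> float:
        n = self.chromosomes.get(breed, 0)
        if n == 0:
            return 0.0
        return self.counts.get(breed, Counter()).get(haplotype, 0) / n

    def frequencies(self, breed: str) -> dict[str, float]:
        n = self.chromosomes.get(breed, 0)
        if n == 0:
            return {}
        return {h: c / n for h, c in sorted(self.counts[breed].items())}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for breed in self.breeds:
            n = self.chromosomes.get(breed, 0)
            for hap, count in sorted(self.counts[breed].items()):
                rows.append(
                    {
                        "breed": breed,
                        "haplotype": hap,
                        "count": count,
                        "chromosomes": n,
                        "frequency": count / n if n else float("nan"),
                    }
                )
        return pd.DataFrame(rows, columns=["breed", "haplotype", "count", "chromosomes", "frequency"])


def _countable_haplotypes(
    result: PhaseResult | Diplotype, include_imputed: bool
) -> list[str]:
    d = result.diplotype if isinstance(result, PhaseResult) else result
    if d is None or d.partial:
        return []
    allowed = set(OBSERVED_PROVENANCES)
    if include_imputed:
        allowed.add(Provenance.FREQUENCY_IMPUTED)
    return [
        str(h) for h, p in zip(d.haplotypes, d.provenance) if p in allowed
    ]


def estimate_frequencies(
    phased_by_breed: Mapping[str, Iterable[PhaseResult | Diplotype]],
    include_imputed: bool = False,
) -> FreqTable:
    """Estimate per-breed haplotype frequencies from phased diplotypes.

    Each fully resolved, non-partial haplotype copy counts once; unresolved
    or partial copies contribute to neither numerator nor denominator, so
    frequencies sum to one over the resolved chromosomes.  Imputed copies
    are excluded unless ``include_imputed`` is set.  A breed with no
    resolved chromosomes is flagged via :attr:`FreqTable.empty_breeds`
    rather than yielding NaN frequencies.
    """
    table = FreqTable()
    for breed, results in phased_by_breed.items():
        counter: Counter = Counter()
        n = 0
        for result in results:
            haps = _countable_haplotypes(result, include_imputed)
            counter.update(haps)
            n += len(haps)
        table.counts[breed] = counter
        table.chromosomes[breed] = n
    return table


def common_haplotypes(freqs: FreqTable, threshold: float = 0.05) -> list[str]:
    """Haplotypes above ``threshold`` frequency in at least one breed.

    Sorted by maximum across-breed frequency, descending (ties by string).
    The default 5% operationalises "occurs commonly".
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    best: dict[str, float] = {}
    for hap in freqs.haplotypes():
        m = max((freqs.freq(b, hap) for b in freqs.breeds), default=0.0)
        if m > threshold:
            best[hap] = m
    return sorted(best, key=lambda h: (-best[h], h))


class WPlotCategory(str, Enum):
    A_SPECIFIC = "A_specific"
    SHARED = "shared"
    B_SPECIFIC = "B_specific"


@dataclass(frozen=True)
class WPlotEntry:
    haplotype: str
    freq_a: float
    freq_b: float
    category: WPlotCategory


@dataclass
class WPlotData:
    """The W-plot partition of a two-breed comparison."""

    breed_a: str
    breed_b: str
    entries: tuple[WPlotEntry, ...]
    common_threshold: float
    specificity_floor: float

    def by_category(self, category: WPlotCategory) -> tuple[WPlotEntry, ...]:
        return tuple(e for e in self.entries if e.category == category)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "haplotype": e.haplotype,
                    f"freq_{self.breed_a}": e.freq_a,
                    f"freq_{self.breed_b}": e.freq_b,
                    "category": e.category.value,
                }
                for e in self.entries
            ]
        )


def wplot_partition(
    freqs: FreqTable,
    breed_a: str,
    breed_b: str,
    common_threshold: float = 0.05,
    specificity_floor: float = 0.01,
) -> WPlotData:
    """Partition haplotypes into shared / A-specific / B-specific.

    A haplotype is A-specific when common in breed A (frequency >=
    ``common_threshold``) yet effectively absent from breed B (frequency <
    ``specificity_floor``), and symmetrically for B.  Everything else is
    shared.  Absence in a sample is not absence in a breed, hence the
    configurable floor.  Entries are laid out shared-first (by descending
    maximum frequency), then A-specific, then B-specific — the stable "W"
    arrangement.
    """
    if breed_a not in freqs.breeds or breed_b not in freqs.breeds:
        raise ValueError(
            f"both breeds must be present in the table; have {freqs.breeds}"
        )
    if specificity_floor >= common_threshold:
        raise ValueError(
            f"specificity_floor ({specificity_floor}) must be below "
            f"common_threshold ({common_threshold})"
        )
    entries = []
    for hap in freqs.haplotypes():
        fa, fb = freqs.freq(breed_a, hap), freqs.freq(breed_b, hap)
        if fa == 0.0 and fb == 0.0:
            continue
        if fa >= common_threshold and fb < specificity_floor:
            cat = WPlotCategory.A_SPECIFIC
        elif fb >= common_threshold and fa < specificity_floor:
            cat = WPlotCategory.B_SPECIFIC
        else:
            cat = WPlotCategory.SHARED
        entries.append(WPlotEntry(hap, fa, fb, cat))

    def sort_key(e: WPlotEntry):
        order = {
            WPlotCategory.SHARED: 0,
            WPlotCategory.A_SPECIFIC: 1,
            WPlotCategory.B_SPECIFIC: 2,
        }
        return (order[e.category], -max(e.freq_a, e.freq_b), e.haplotype)

    return WPlotData(
        breed_a=breed_a,
        breed_b=breed_b,
        entries=tuple(sorted(entries, key=sort_key)),
        common_threshold=common_threshold,
        specificity_floor=specificity_floor,
    )


def write_freq_tsv(table: FreqTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_wplot_tsv(data: WPlotData, path: str | Path) -> None:
    data.to_frame().to_csv(path, sep="\t", index=False)


def plot_wplot(data: WPlotData, path: Optional[str | Path] = None):
    """Render the W arrangement (optional; the TSV is the contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = (
        data.by_category(WPlotCategory.A_SPECIFIC)
        + data.by_category(WPlotCategory.SHARED)
        + data.by_category(WPlotCategory.B_SPECIFIC)
    )
    x = range(len(entries))
    fig, ax = plt.subplots(figsize=(max(6, len(entries) * 0.6), 4))
    ax.plot(x, [e.freq_a for e in entries], "o-", label=data.breed_a)
    ax.plot(x, [-e.freq_b for e in entries], "s-", label=data.breed_b)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xticks(list(x))
    ax.set_xticklabels([e.haplotype for e in entries], rotation=90)
    ax.set_ylabel(f"frequency ({data.breed_a} up, {data.breed_b} down)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
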