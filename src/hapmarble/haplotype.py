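"""Haplotypes, diplotypes and breed-specificity classification.

A haplotype is a whole-segment combination of marker alleles transmitted as
an atomic unit — an *ancestral haplotype* conserved without intra-block
recombination.  The dotted string form follows the field's designation
conventions, e.g. ``60.10.S.10`` for the S-T segment (alleles at MPRIP,
TCAP, SREBF1, NT5M in that order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .schema import SEGMENTS, MarkerSchema, SchemaError

__all__ = [
    "AlleleError",
    "BreedClass",
    "Diplotype",
    "Haplotype",
    "HaplotypeFormatError",
    "MissingGenotypeError",
    "Provenance",
    "WAGYU_SPECIFIC_HAPLOTYPES",
    "COMMON_HAPLOTYPES",
    "classify_haplotype",
    "count_haplotype_space",
    "format_haplotype",
    "is_homozygous_at",
    "parse_haplotype",
]

MISSING_TOKEN = "?"


class HaplotypeFormatError(ValueError):
    """Wrong token count or separators in a haplotype string."""


class AlleleError(ValueError):
    """Allele label outside the schema alphabet for its locus."""


class MissingGenotypeError(KeyError):
    """A locus required by an operation is not typed."""


class Provenance(str, Enum):
    """How a phased haplotype was obtained.

    Only empirically forced resolutions (homozygosity, a single
    heterozygous locus, or pedigree segregation) are treated as observed;
    frequency imputation is always flagged so downstream analyses can
    exclude it.
    """

    OBSERVED_HOMOZYGOUS = "observed_homozygous"
    SEGREGATION = "segregation"
    SINGLE_HETEROZYGOUS_LOCUS = "single_heterozygous_locus"
    FREQUENCY_IMPUTED = "frequency_imputed"
    UNRESOLVED = "unresolved"


#: Provenances that count as empirically observed phase.
OBSERVED_PROVENANCES = frozenset(
    {
        Provenance.OBSERVED_HOMOZYGOUS,
        Provenance.SEGREGATION,
        Provenance.SINGLE_HETEROZYGOUS_LOCUS,
    }
)


class BreedClass(str, Enum):
    WAGYU_SPECIFIC = "wagyu_specific"
    BOS_INDICUS_SPECIFIC = "bos_indicus_specific"
    COMMON = "common"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True, order=True)
class Haplotype:
    """One segment-wide allele combination.

    ``alleles`` holds one label per segment locus, in the segment's display
    order; ``None`` marks an untyped locus of a partial haplotype.
    """

    segment: str
    alleles: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        seg = SEGMENTS.get(self.segment)
        if seg is None:
            raise SchemaError(f"unknown segment {self.segment!r}")
        if len(self.alleles) != len(seg.loci):
            raise HaplotypeFormatError(
                f"segment {self.segment!r} has {len(seg.loci)} loci, "
                f"got {len(self.alleles)} alleles"
            )

    @property
    def loci(self) -> tuple[str, ...]:
        return SEGMENTS[self.segment].loci

    @property
    def is_partial(self) -> bool:
        return any(a is None for a in self.alleles)

    def allele(self, locus: str) -> Optional[str]:
        try:
            return self.alleles[self.loci.index(locus)]
        except ValueError:
            raise MissingGenotypeError(
                f"locus {locus!r} not in segment {self.segment!r}"
            ) from None

    def validate(self, schema: MarkerSchema) -> "Haplotype":
        for locus, allele in zip(self.loci, self.alleles):
            if allele is not None and not schema.is_valid_allele(locus, allele):
                raise AlleleError(
                    f"allele {allele!r} not in alphabet of locus {locus!r} "
                    f"({schema.alleles(locus)})"
                )
        return self

    def __str__(self) -> str:
        return format_haplotype(self)


def parse_haplotype(
    text: str,
    schema: MarkerSchema,
    segment: str = "S-T",
    allow_missing: bool = False,
) -> Haplotype:
    """Parse a dotted haplotype designation such as ``"60.10.S.10"``.

    The token order is the segment's display convention (for S-T: MPRIP,
    TCAP, SREBF1, NT5M).  Raises :class:`HaplotypeFormatError` on a wrong
    token count or separators and :class:`AlleleError` on a label outside
    the schema alphabet.
    """
    seg = SEGMENTS.get(segment)
    if seg is None:
        raise SchemaError(f"unknown segment {segment!r}")
    tokens: list[str] = []
    rest = text
    for sep in seg.separators:
        head, found, rest = rest.partition(sep)
        if not found:
            raise HaplotypeFormatError(
                f"{text!r}: expected {len(seg.loci)} tokens separated by "
                f"{seg.separators!r} for segment {segment!r}"
            )
        tokens.append(head)
    tokens.append(rest)
    if any(t == "" for t in tokens):
        raise HaplotypeFormatError(f"{text!r}: empty allele token")
    alleles: list[Optional[str]] = []
    for locus, token in zip(seg.loci, tokens):
        if token == MISSING_TOKEN:
            if not allow_missing:
                raise AlleleError(f"{text!r}: missing allele at locus {locus!r}")
            alleles.append(None)
        else:
            if not schema.is_valid_allele(locus, token):
                raise AlleleError(
                    f"{text!r}: allele {token!r} not in alphabet of locus "
                    f"{locus!r} ({schema.alleles(locus)})"
                )
            alleles.append(token)
    return Haplotype(segment=segment, alleles=tuple(alleles))


def format_haplotype(h: Haplotype) -> str:
    """Dotted string form; inverse of :func:`parse_haplotype`."""
    seg = SEGMENTS[h.segment]
    out = [h.alleles[0] if h.alleles[0] is not None else MISSING_TOKEN]
    for sep, allele in zip(seg.separators, h.alleles[1:]):
        out.append(sep)
        out.append(allele if allele is not None else MISSING_TOKEN)
    return "".join(out)


def count_haplotype_space(allele_counts: Sequence[int]) -> int:
    """Number of possible haplotypes given per-locus allele counts.

    With free recombination every combination is possible, so the space is
    the product of the counts — e.g. 3 x 5 x 7 x 2 x 3 = 630 for the
    SREBF1-to-GH segment.  The empirical point of ancestral-haplotype
    analysis is that only a handful of these ever occur.
    """
    counts = list(allele_counts)
    if not counts:
        raise ValueError("allele_counts must be non-empty")
    for c in counts:
        if not isinstance(c, (int,)) or isinstance(c, bool) or c < 1:
            raise ValueError(f"allele counts must be integers >= 1, got {c!r}")
    return math.prod(counts)


#: Haplotypes classified as Wagyu-specific (S-T designation).
WAGYU_SPECIFIC_HAPLOTYPES = frozenset({"60.10.S.10", "30.20.S.20", "30.10.S.20"})

#: Example haplotypes found in all breeds studied.
COMMON_HAPLOTYPES = frozenset({"30.20.L.20", "40.20.L.20"})


def _numeric(label: Optional[str], locus: str) -> float:
    if label is None:
        raise MissingGenotypeError(f"locus {locus!r} untyped; cannot classify")
    try:
        return float(label)
    except ValueError:
        raise AlleleError(
            f"non-numeric {locus} allele {label!r}: the breed-specificity "
            f"rule compares numeric labels"
        ) from None


def classify_haplotype(
    h: Haplotype,
    wagyu_specific: Iterable[str] = WAGYU_SPECIFIC_HAPLOTYPES,
    common: Iterable[str] = COMMON_HAPLOTYPES,
    mprip_threshold: float = 60,
    nt5m_threshold: float = 22,
) -> BreedClass:
    """Breed-specificity class of an S-T haplotype.

    Rules, in priority order: membership in the enumerated Wagyu-specific
    list; then the numeric Bos indicus rule (MPRIP > 60 or NT5M > 22); then
    membership in the configured all-breed ("common") set; else
    unclassified.  The explicit list wins over the numeric rule.
    """
    if h.segment != "S-T":
        raise SchemaError(f"classification is defined on S-T haplotypes, got {h.segment!r}")
    text = format_haplotype(h)
    if text in set(wagyu_specific):
        return BreedClass.WAGYU_SPECIFIC
    if (
        _numeric(h.allele("MPRIP"), "MPRIP") > mprip_threshold
        or _numeric(h.allele("NT5M"), "NT5M") > nt5m_threshold
    ):
        return BreedClass.BOS_INDICUS_SPECIFIC
    if text in set(common):
        return BreedClass.COMMON
    return BreedClass.UNCLASSIFIED


def is_homozygous_at(genotype: "GenotypeLike", locus: str) -> bool:
    """True iff both allele labels at ``locus`` are equal.

    A missing locus raises :class:`MissingGenotypeError` — absence of data
    is never evidence of homozygosity.
    """
    calls = genotype.calls if hasattr(genotype, "calls") else genotype
    pair = calls.get(locus)
    if pair is None:
        raise MissingGenotypeError(f"locus {locus!r} not typed")
    a, b = pair
    return a == b


@dataclass(frozen=True)
class Diplotype:
    """An ordered-canonically pair of haplotypes with per-copy provenance.

    The pair is stored sorted by string form so that unordered equality is
    plain equality.  ``partial`` marks diplotypes phased over a subset of
    the segment loci (some loci untyped).
    """

    haplotypes: tuple[Haplotype, Haplotype]
    provenance: tuple[Provenance, Provenance]
    partial: bool = False

    def __post_init__(self) -> None:
        h1, h2 = self.haplotypes
        if h1.segment != h2.segment:
            raise SchemaError("diplotype haplotypes must share a segment")
        if str(h1) > str(h2):
            object.__setattr__(self, "haplotypes", (h2, h1))
            object.__setattr__(
                self, "provenance", (self.provenance[1], self.provenance[0])
            )

    @property
    def segment(self) -> str:
        return self.haplotypes[0].segment

    @property
    def is_resolved(self) -> bool:
        return all(p != Provenance.UNRESOLVED for p in self.provenance)

    def allele_multiset(self, locus: str) -> tuple[Optional[str], ...]:
        pair = (self.haplotypes[0].allele(locus), self.haplotypes[1].allele(locus))
        return tuple(sorted(pair, key=lambda x: (x is None, x)))

    def matches_genotype(self, calls: Mapping[str, Optional[tuple[str, str]]]) -> bool:
        """Locus-wise allele multisets equal the unphased genotype calls."""
        for locus in self.haplotypes[0].loci:
            pair = calls.get(locus)
            if pair is None:
                if self.allele_multiset(locus) != (None, None):
                    return False
                continue
            if self.allele_multiset(locus) != tuple(sorted(pair)):
                return False
        return True

    def __str__(self) -> str:
        return f"{self.haplotypes[0]}/{self.haplotypes[1]}"
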