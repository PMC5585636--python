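"""Diplotype inference from unphased genotypes.

Phase is resolved only by evidence the data actually force: complete
homozygosity, a single heterozygous locus, or pedigree segregation under
the no-intra-block-recombination premise (conserved ancestral haplotypes
are transmitted whole).  Breed haplotype frequencies can optionally break
residual ambiguity, but such calls are always flagged
``frequency_imputed`` so downstream analyses can exclude them.

The module also exposes :func:`enumerate_consistent_diplotypes`, the exact
brute-force enumeration of all haplotype pairs consistent with a genotype
(and optional parental-transmission constraints).  Every phased answer is,
by construction, a member of that set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from .haplotype import Diplotype, Haplotype, Provenance
from .pedigree import (
    Animal,
    Genotype,
    MendelViolation,
    Pedigree,
    PedigreeError,
    check_mendelian,
)
from .schema import MarkerSchema

__all__ = [
    "MendelianError",
    "PhaseResult",
    "TransmissionConstraint",
    "enumerate_consistent_diplotypes",
    "phase_pedigree",
    "phase_trio",
    "phase_unrelated",
]

HapPair = tuple[Haplotype, Haplotype]


class MendelianError(ValueError):
    """Raised when a trio to be phased violates Mendelian transmission."""

    def __init__(self, violations: list[MendelViolation]):
        self.violations = violations
        super().__init__("; ".join(v.description for v in violations))


@dataclass(frozen=True)
class TransmissionConstraint:
    """Haplotypes each parent could have transmitted (``None`` = unconstrained)."""

    sire: Optional[frozenset[Haplotype]] = None
    dam: Optional[frozenset[Haplotype]] = None


@dataclass
class PhaseResult:
    """Outcome of phasing one animal."""

    animal_id: str
    diplotype: Optional[Diplotype]
    candidates: tuple[HapPair, ...]
    partial: bool = False
    violations: list[MendelViolation] = field(default_factory=list)

    @property
    def is_resolved(self) -> bool:
        return self.diplotype is not None

    @property
    def provenance(self) -> tuple[Provenance, Provenance]:
        if self.diplotype is None:
            return (Provenance.UNRESOLVED, Provenance.UNRESOLVED)
        return self.diplotype.provenance


def _canonical(h1: Haplotype, h2: Haplotype) -> HapPair:
    return (h1, h2) if str(h1) <= str(h2) else (h2, h1)


def _orientation_ok(
    pair: HapPair,
    sire: Optional[frozenset[Haplotype]],
    dam: Optional[frozenset[Haplotype]],
) -> bool:
    h1, h2 = pair
    for s, d in ((h1, h2), (h2, h1)):
        if (sire is None or s in sire) and (dam is None or d in dam):
            return True
    return False


def enumerate_consistent_diplotypes(
    genotype: Genotype,
    schema: MarkerSchema,
    segment: str = "S-T",
    constraints: Optional[TransmissionConstraint] = None,
    max_het: int = 12,
) -> set[HapPair]:
    """All unordered haplotype pairs consistent with an unphased genotype.

    Exact 2^k enumeration over the k heterozygous loci; refuses k >
    ``max_het``.  With ``constraints``, a pair is kept only if some
    orientation draws one haplotype from each constrained parental set.
    Untyped loci appear as ``None`` alleles (partial haplotypes).
    """
    loci = schema.segment_loci(segment)
    het = genotype.het_loci(loci)
    if len(het) > max_het:
        raise ValueError(
            f"{genotype.animal_id}: {len(het)} heterozygous loci exceeds the "
            f"enumeration limit of {max_het}"
        )
    het_set = set(het)
    pairs: set[HapPair] = set()
    for flips in itertools.product((0, 1), repeat=len(het)):
        flip = dict(zip(het, flips))
        a1: list[Optional[str]] = []
        a2: list[Optional[str]] = []
        for locus in loci:
            call = genotype.calls.get(locus)
            if call is None:
                a1.append(None)
                a2.append(None)
            elif locus in het_set:
                x, y = call
                if flip[locus]:
                    x, y = y, x
                a1.append(x)
                a2.append(y)
            else:
                a1.append(call[0])
                a2.append(call[1])
        h1 = Haplotype(segment=segment, alleles=tuple(a1))
        h2 = Haplotype(segment=segment, alleles=tuple(a2))
        pairs.add(_canonical(h1, h2))
    if constraints is not None:
        pairs = {
            p for p in pairs if _orientation_ok(p, constraints.sire, constraints.dam)
        }
    return pairs


def _result_from_candidates(
    genotype: Genotype,
    schema: MarkerSchema,
    segment: str,
    candidates: set[HapPair],
    resolved_provenance: Provenance,
) -> PhaseResult:
    loci = schema.segment_loci(segment)
    partial = any(not genotype.is_typed(l) for l in loci)
    ordered = tuple(sorted(candidates, key=lambda p: (str(p[0]), str(p[1]))))
    n_het = len(genotype.het_loci(loci))
    if len(ordered) == 1:
        if n_het == 0:
            prov = Provenance.OBSERVED_HOMOZYGOUS
        elif n_het == 1:
            prov = Provenance.SINGLE_HETEROZYGOUS_LOCUS
        else:
            prov = resolved_provenance
        diplotype = Diplotype(
            haplotypes=ordered[0], provenance=(prov, prov), partial=partial
        )
        return PhaseResult(genotype.animal_id, diplotype, ordered, partial)
    return PhaseResult(genotype.animal_id, None, ordered, partial)


def phase_unrelated(
    genotype: Genotype, schema: MarkerSchema, segment: str = "S-T"
) -> PhaseResult:
    """Phase a single animal from its own genotype alone.

    Fully resolved when at most one segment locus is heterozygous;
    otherwise unresolved with the full candidate set attached.  Untyped
    loci give a partial phase over the typed loci.
    """
    candidates = enumerate_consistent_diplotypes(genotype, schema, segment)
    return _result_from_candidates(
        genotype, schema, segment, candidates, Provenance.SEGREGATION
    )


def _transmittable(
    source: Union[Diplotype, Genotype, None],
    schema: MarkerSchema,
    segment: str,
) -> Optional[frozenset[Haplotype]]:
    if source is None:
        return None
    if isinstance(source, Diplotype):
        return frozenset(source.haplotypes)
    haps: set[Haplotype] = set()
    for pair in enumerate_consistent_diplotypes(source, schema, segment):
        haps.update(pair)
    return frozenset(haps)


def _as_calls(source: Union[Diplotype, Genotype, None]) -> Optional[Genotype]:
    if source is None or isinstance(source, Genotype):
        return source
    calls = {
        locus: tuple(sorted(
            (source.haplotypes[0].allele(locus), source.haplotypes[1].allele(locus))
        ))
        for locus in source.haplotypes[0].loci
        if source.haplotypes[0].allele(locus) is not None
        and source.haplotypes[1].allele(locus) is not None
    }
    return Genotype("<parent>", calls)


def phase_trio(
    child: Genotype,
    sire: Union[Diplotype, Genotype, None],
    dam: Union[Diplotype, Genotype, None],
    schema: MarkerSchema,
    segment: str = "S-T",
) -> PhaseResult:
    """Phase a child against its parents' possible transmissions.

    The child is resolved (provenance ``segregation``) when exactly one
    unordered whole-haplotype pair is consistent with both parents;
    otherwise the surviving candidates are returned unresolved.  A
    Mendelian-inconsistent trio raises :class:`MendelianError`.
    """
    trio_ped = Pedigree(
        [
            Animal(id="<sire>", sex="M"),
            Animal(id="<dam>", sex="F"),
            Animal(id=child.animal_id, sire_id="<sire>", dam_id="<dam>"),
        ]
    )
    gts = {child.animal_id: child}
    sire_gt, dam_gt = _as_calls(sire), _as_calls(dam)
    if sire_gt is not None:
        gts["<sire>"] = Genotype("<sire>", dict(sire_gt.calls))
    if dam_gt is not None:
        gts["<dam>"] = Genotype("<dam>", dict(dam_gt.calls))
    violations = check_mendelian(trio_ped, gts)
    if violations:
        raise MendelianError(violations)
    constraint = TransmissionConstraint(
        sire=_transmittable(sire, schema, segment),
        dam=_transmittable(dam, schema, segment),
    )
    candidates = enumerate_consistent_diplotypes(
        child, schema, segment, constraints=constraint
    )
    return _result_from_candidates(
        child, schema, segment, candidates, Provenance.SEGREGATION
    )


def phase_pedigree(
    pedigree: Pedigree,
    genotypes: Mapping[str, Genotype],
    schema: MarkerSchema,
    segment: str = "S-T",
    freq_table: Optional["FreqTable"] = None,
    max_het: int = 12,
) -> dict[str, PhaseResult]:
    """Phase every typed animal by fixed-point constraint propagation.

    Candidate diplotype sets (from exact enumeration) are pruned breadth-
    first by generation: downward, a child's pair must be composable from
    its parents' transmittable haplotypes; upward, a parent must be able to
    supply a haplotype to each typed child.  Iterated to a fixed point, the
    procedure is deterministic given input order.  Animals implicated in
    Mendelian violations — or whose genotype admits no recombination-free
    explanation against their relatives — are left unresolved, never
    force-phased.  If ``freq_table`` is supplied, remaining ambiguity is
    broken by maximum haplotype-frequency product for the animal's breed
    and flagged ``frequency_imputed`` (ties: lexicographic string order).
    """
    for animal_id in genotypes:
        if animal_id not in pedigree:
            raise PedigreeError(f"genotype for unknown animal id {animal_id!r}")
    violations = check_mendelian(pedigree, genotypes)
    by_child: dict[str, list[MendelViolation]] = {}
    for v in violations:
        by_child.setdefault(v.animal_id, []).append(v)

    cand: dict[str, set[HapPair]] = {}
    for animal_id, gt in genotypes.items():
        cand[animal_id] = enumerate_consistent_diplotypes(
            gt, schema, segment, max_het=max_het
        )
    blocked: set[str] = set(by_child)

    order = [a.id for a in pedigree.by_generation() if a.id in cand]

    def transmittable(animal_id: Optional[str]) -> Optional[frozenset[Haplotype]]:
        if animal_id is None or animal_id not in cand or animal_id in blocked:
            return None
        haps: set[Haplotype] = set()
        for pair in cand[animal_id]:
            haps.update(pair)
        return frozenset(haps)

    def parent_supports_child(
        parent_pair: HapPair, child_id: str, other_set: Optional[frozenset[Haplotype]]
    ) -> bool:
        parent_haps = set(parent_pair)
        for c1, c2 in cand[child_id]:
            for mine, theirs in ((c1, c2), (c2, c1)):
                if mine in parent_haps and (other_set is None or theirs in other_set):
                    return True
        return False

    changed = True
    while changed:
        changed = False
        # Downward: prune children by parental transmittable sets.
        for animal_id in order:
            if animal_id in blocked:
                continue
            sire, dam = pedigree.parents_of(animal_id)
            sset = transmittable(sire.id if sire else None)
            dset = transmittable(dam.id if dam else None)
            if sset is None and dset is None:
                continue
            kept = {p for p in cand[animal_id] if _orientation_ok(p, sset, dset)}
            if not kept:
                # No recombination-free explanation: leave unresolved.
                blocked.add(animal_id)
                changed = True
            elif kept != cand[animal_id]:
                cand[animal_id] = kept
                changed = True
        # Upward: a parent must be able to serve every typed child.
        for animal_id in reversed(order):
            if animal_id in blocked:
                continue
            for child in pedigree.children_of(animal_id):
                if child.id not in cand or child.id in blocked:
                    continue
                sire, dam = pedigree.parents_of(child.id)
                other = dam if (sire and sire.id == animal_id) else sire
                other_set = transmittable(other.id if other else None)
                kept = {
                    p
                    for p in cand[animal_id]
                    if parent_supports_child(p, child.id, other_set)
                }
                if not kept:
                    blocked.add(animal_id)
                    changed = True
                    break
                if kept != cand[animal_id]:
                    cand[animal_id] = kept
                    changed = True

    results: dict[str, PhaseResult] = {}
    for animal_id in order:
        gt = genotypes[animal_id]
        if animal_id in blocked:
            full = enumerate_consistent_diplotypes(gt, schema, segment, max_het=max_het)
            res = PhaseResult(
                animal_id,
                None,
                tuple(sorted(full, key=lambda p: (str(p[0]), str(p[1])))),
                partial=any(
                    not gt.is_typed(l) for l in schema.segment_loci(segment)
                ),
                violations=by_child.get(animal_id, []),
            )
            results[animal_id] = res
            continue
        res = _result_from_candidates(
            gt, schema, segment, cand[animal_id], Provenance.SEGREGATION
        )
        if not res.is_resolved and freq_table is not None:
            breed = pedigree[animal_id].breed
            if breed in freq_table.breeds:

                def score(pair: HapPair) -> float:
                    return freq_table.freq(breed, str(pair[0])) * freq_table.freq(
                        breed, str(pair[1])
                    )

                # max() keeps the first maximum, so sorting first makes the
                # tie-break lexicographic on the haplotype strings.
                ordered = sorted(
                    res.candidates, key=lambda p: (str(p[0]), str(p[1]))
                )
                best = max(ordered, key=score)
                prov = Provenance.FREQUENCY_IMPUTED
                res.diplotype = Diplotype(
                    haplotypes=best, provenance=(prov, prov), partial=res.partial
                )
        results[animal_id] = res
    return results
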