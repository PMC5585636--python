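"""Pedigree and genotype records, Mendelian checking, and file I/O.

Pedigrees are PED-like: one row per animal with sire/dam ids, sex, breed
and Wagyu ancestry fraction.  Genotypes are unphased per-locus allele
pairs.  Mendelian consistency is the precondition for segregation-based
phasing — paternity in the source herds was confirmed by DNA testing, and
the same check is applied here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx

from .schema import MarkerSchema

__all__ = [
    "Animal",
    "Genotype",
    "MendelViolation",
    "Pedigree",
    "PedigreeError",
    "check_mendelian",
    "read_genotypes",
    "read_pedigree",
    "write_genotypes",
    "write_pedigree",
]

MISSING_PARENT = {"", "0", ".", "NA", None}


class PedigreeError(ValueError):
    """Structural pedigree problem (cycle, unknown id, sex conflict)."""


@dataclass(frozen=True)
class Animal:
    id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    sex: str = "U"  # M / F / U
    breed: str = ""
    wagyu_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("animal id must be non-empty")
        if not 0.0 <= self.wagyu_fraction <= 1.0:
            raise PedigreeError(
                f"{self.id}: wagyu_fraction must lie in [0, 1], "
                f"got {self.wagyu_fraction}"
            )


class Pedigree:
    """An acyclic set of animals with parent links.

    Iteration order follows generation depth (founders first), which makes
    downstream fixed-point phasing deterministic.
    """

    def __init__(self, animals: Iterable[Animal]):
        self._animals: dict[str, Animal] = {}
        for a in animals:
            if a.id in self._animals:
                raise PedigreeError(f"duplicate animal id {a.id!r}")
            self._animals[a.id] = a
        self._validate()

    def _validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._animals)
        for a in self._animals.values():
            for parent in (a.sire_id, a.dam_id):
                if parent is not None and parent in self._animals:
                    g.add_edge(parent, a.id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedigreeError(f"pedigree contains a cycle: {cycle}")
        for a in self._animals.values():
            sire = self._animals.get(a.sire_id) if a.sire_id else None
            dam = self._animals.get(a.dam_id) if a.dam_id else None
            if sire is not None and sire.sex == "F":
                raise PedigreeError(f"{a.id}: sire {sire.id} recorded as female")
            if dam is not None and dam.sex == "M":
                raise PedigreeError(f"{a.id}: dam {dam.id} recorded as male")
        self._graph = g
        depth: dict[str, int] = {}
        for node in nx.topological_sort(g):
            preds = list(g.predecessors(node))
            depth[node] = 1 + max((depth[p] for p in preds), default=-1)
        self._depth = depth

    def __len__(self) -> int:
        return len(self._animals)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._animals

    def __getitem__(self, animal_id: str) -> Animal:
        try:
            return self._animals[animal_id]
        except KeyError:
            raise PedigreeError(f"unknown animal id {animal_id!r}") from None

    def __iter__(self):
        return iter(self.by_generation())

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.by_generation())

    def generation(self, animal_id: str) -> int:
        return self._depth[animal_id]

    def by_generation(self) -> list[Animal]:
        return [
            self._animals[i]
            for i in sorted(self._animals, key=lambda i: (self._depth[i], i))
        ]

    def founders(self) -> list[Animal]:
        return [a for a in self.by_generation() if self._depth[a.id] == 0]

    def children_of(self, animal_id: str) -> list[Animal]:
        return [self._animals[c] for c in sorted(self._graph.successors(animal_id))]

    def parents_of(self, animal_id: str) -> tuple[Optional[Animal], Optional[Animal]]:
        a = self[animal_id]
        sire = self._animals.get(a.sire_id) if a.sire_id else None
        dam = self._animals.get(a.dam_id) if a.dam_id else None
        return sire, dam


@dataclass
class Genotype:
    """Unphased multi-locus genotype: per-locus unordered allele pairs.

    ``calls[locus]`` is a sorted ``(a1, a2)`` tuple or ``None`` when the
    locus is untyped.
    """

    animal_id: str
    calls: dict[str, Optional[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = {
            locus: (tuple(sorted(pair)) if pair is not None else None)
            for locus, pair in self.calls.items()
        }

    def validate(self, schema: MarkerSchema) -> "Genotype":
        from .haplotype import AlleleError

        for locus, pair in self.calls.items():
            if pair is None:
                continue
            for allele in pair:
                if not schema.is_valid_allele(locus, allele):
                    raise AlleleError(
                        f"{self.animal_id}: allele {allele!r} invalid at "
                        f"locus {locus!r}"
                    )
        return self

    def is_typed(self, locus: str) -> bool:
        return self.calls.get(locus) is not None

    def typed_loci(self, loci: Iterable[str]) -> tuple[str, ...]:
        return tuple(l for l in loci if self.is_typed(l))

    def het_loci(self, loci: Iterable[str]) -> tuple[str, ...]:
        return tuple(
            l
            for l in loci
            if self.is_typed(l) and self.calls[l][0] != self.calls[l][1]
        )


@dataclass(frozen=True)
class MendelViolation:
    """A child allele pair that no parental transmission can explain."""

    animal_id: str
    locus: str
    child_pair: tuple[str, str]
    sire_pair: Optional[tuple[str, str]]
    dam_pair: Optional[tuple[str, str]]

    @property
    def description(self) -> str:
        return (
            f"{self.animal_id} at {self.locus}: child {self.child_pair} "
            f"cannot be composed from sire {self.sire_pair} and dam {self.dam_pair}"
        )


def _pair_possible(
    child: tuple[str, str],
    sire: Optional[tuple[str, str]],
    dam: Optional[tuple[str, str]],
) -> bool:
    """Can one allele come from each (typed) parent?  Missing data never counts
    as evidence against."""
    a, b = child
    for x, y in ((a, b), (b, a)):
        sire_ok = sire is None or x in sire
        dam_ok = dam is None or y in dam
        if sire_ok and dam_ok:
            return True
    return False


def check_mendelian(
    pedigree: Pedigree, genotypes: Mapping[str, Genotype]
) -> list[MendelViolation]:
    """All per-locus transmission violations in the pedigree.

    A violation is reported only when no assignment of one allele from each
    typed parent explains the child's pair; an untyped parent or locus is
    never a violation.
    """
    for animal_id in genotypes:
        if animal_id not in pedigree:
            raise PedigreeError(f"genotype for unknown animal id {animal_id!r}")
    violations: list[MendelViolation] = []
    for animal in pedigree.by_generation():
        child_gt = genotypes.get(animal.id)
        if child_gt is None:
            continue
        sire, dam = pedigree.parents_of(animal.id)
        sire_gt = genotypes.get(sire.id) if sire else None
        dam_gt = genotypes.get(dam.id) if dam else None
        if sire_gt is None and dam_gt is None:
            continue
        for locus, child_pair in child_gt.calls.items():
            if child_pair is None:
                continue
            sire_pair = sire_gt.calls.get(locus) if sire_gt else None
            dam_pair = dam_gt.calls.get(locus) if dam_gt else None
            if not _pair_possible(child_pair, sire_pair, dam_pair):
                violations.append(
                    MendelViolation(
                        animal_id=animal.id,
                        locus=locus,
                        child_pair=child_pair,
                        sire_pair=sire_pair,
                        dam_pair=dam_pair,
                    )
                )
    return violations


# -- file I/O ---------------------------------------------------------------


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PED-like file (CSV or whitespace-delimited).

    Columns: id, sire, dam, sex, breed, wagyu_fraction.  Missing parents
    are written as ``0``, ``.`` or an empty field.
    """
    path = Path(path)
    text = path.read_text().strip()
    delimiter = "," if "," in text.splitlines()[0] else None
    animals = []
    for i, line in enumerate(text.splitlines()):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(delimiter) if delimiter else line.split()
        fields = [f.strip() for f in fields]
        if i == 0 and fields[0].lower() in {"id", "animal", "animal_id"}:
            continue
        if len(fields) < 6:
            raise PedigreeError(f"{path}:{i + 1}: expected 6 fields, got {len(fields)}")
        ident, sire, dam, sex, breed, frac = fields[:6]
        animals.append(
            Animal(
                id=ident,
                sire_id=None if sire in MISSING_PARENT else sire,
                dam_id=None if dam in MISSING_PARENT else dam,
                sex=sex or "U",
                breed=breed,
                wagyu_fraction=float(frac),
            )
        )
    return Pedigree(animals)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "sire", "dam", "sex", "breed", "wagyu_fraction"])
        for a in pedigree.by_generation():
            w.writerow(
                [a.id, a.sire_id or "0", a.dam_id or "0", a.sex, a.breed, a.wagyu_fraction]
            )


def read_genotypes(
    path: str | Path, schema: MarkerSchema
) -> dict[str, Genotype]:
    """Read a genotype CSV with two columns per locus (``MPRIP_1``, ``MPRIP_2``, ...).

    Empty cells mark an untyped locus (both columns must then be empty).
    """
    genotypes: dict[str, Genotype] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "animal" not in reader.fieldnames:
            raise PedigreeError(f"{path}: genotype CSV needs an 'animal' column")
        loci = [
            name
            for name in schema.locus_names
            if f"{name}_1" in reader.fieldnames and f"{name}_2" in reader.fieldnames
        ]
        for row in reader:
            animal_id = row["animal"].strip()
            calls: dict[str, Optional[tuple[str, str]]] = {}
            for locus in loci:
                a1 = (row.get(f"{locus}_1") or "").strip()
                a2 = (row.get(f"{locus}_2") or "").strip()
                if not a1 and not a2:
                    calls[locus] = None
                elif a1 and a2:
                    calls[locus] = (a1, a2)
                else:
                    raise PedigreeError(
                        f"{path}: {animal_id} half-typed at {locus}"
                    )
            if animal_id in genotypes:
                raise PedigreeError(f"{path}: duplicate genotype row for {animal_id}")
            genotypes[animal_id] = Genotype(animal_id, calls).validate(schema)
    return genotypes


def write_genotypes(
    genotypes: Mapping[str, Genotype], schema: MarkerSchema, path: str | Path
) -> None:
    loci = list(schema.locus_names)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["animal"]
        for locus in loci:
            header += [f"{locus}_1", f"{locus}_2"]
        w.writerow(header)
        for animal_id in sorted(genotypes):
            gt = genotypes[animal_id]
            row = [animal_id]
            for locus in loci:
                pair = gt.calls.get(locus)
                row += list(pair) if pair is not None else ["", ""]
            w.writerow(row)
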