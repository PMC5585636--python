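"""Marker schema for the conserved-haplotype block of bovine chromosome 19.

The ~20 Mb region bounded by SREBF1 and the FASN-adjacent SCT-FSN marker is
typed at six PCR markers.  A :class:`MarkerSchema` records, for each locus,
its physical position (Mb) and its allele alphabet.  Haplotypes are written
over *segments* — conventional sub-blocks with their own locus display order,
which deliberately differs from physical order (the S-T designation leads
with MPRIP.TCAP to emphasise conservation of the MPRIP–TCAP sub-block).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Locus",
    "MarkerSchema",
    "Segment",
    "SEGMENTS",
    "SchemaError",
    "default_schema",
]


class SchemaError(ValueError):
    """Raised for structurally invalid marker schemas."""


@dataclass(frozen=True)
class Locus:
    """A single PCR marker: name, physical position in Mb, allele alphabet."""

    name: str
    position_mb: float
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("locus name must be non-empty")
        if len(self.alleles) < 2:
            raise SchemaError(
                f"locus {self.name!r} must be polymorphic (>=2 alleles), "
                f"got {self.alleles!r}"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise SchemaError(f"duplicate allele labels at locus {self.name!r}")


@dataclass(frozen=True)
class Segment:
    """A haplotype naming convention: ordered loci plus printed separators.

    ``separators[i]`` is the character printed between locus ``i`` and
    locus ``i + 1`` in the dotted string form.
    """

    name: str
    loci: tuple[str, ...]
    separators: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.separators) != len(self.loci) - 1:
            raise SchemaError(
                f"segment {self.name!r}: need {len(self.loci) - 1} separators"
            )


#: Naming conventions.  S-T is the primary four-locus designation
#: (MPRIP.TCAP.SREB.NT5M); M-T is the MPRIP–TCAP sub-block; the extended
#: designation appends GH and SCT-FSN as MPRIP.TCAP_GH SCT-FSN.
SEGMENTS: dict[str, Segment] = {
    "S-T": Segment("S-T", ("MPRIP", "TCAP", "SREBF1", "NT5M"), (".", ".", ".")),
    "M-T": Segment("M-T", ("MPRIP", "TCAP"), (".",)),
    "extended": Segment(
        "extended", ("MPRIP", "TCAP", "GH", "SCT-FSN"), (".", "_", " ")
    ),
}


@dataclass(frozen=True)
class MarkerSchema:
    """Ordered marker loci of one chromosome block."""

    loci: tuple[Locus, ...]
    _by_name: Mapping[str, Locus] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise SchemaError("locus names must be unique")
        positions = [l.position_mb for l in self.loci]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise SchemaError("locus positions must be strictly increasing")
        object.__setattr__(self, "_by_name", {l.name: l for l in self.loci})

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    def locus(self, name: str) -> Locus:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown locus {name!r}") from None

    def alleles(self, name: str) -> tuple[str, ...]:
        return self.locus(name).alleles

    def is_valid_allele(self, locus: str, allele: str) -> bool:
        return allele in self.locus(locus).alleles

    def segment_loci(self, segment: str) -> tuple[str, ...]:
        seg = SEGMENTS.get(segment)
        if seg is None:
            raise SchemaError(
                f"unknown segment {segment!r}; known: {sorted(SEGMENTS)}"
            )
        missing = [n for n in seg.loci if n not in self._by_name]
        if missing:
            raise SchemaError(f"segment {segment!r} needs loci {missing}")
        return seg.loci

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, spec: Mapping) -> "MarkerSchema":
        """Build a schema from a mapping ``{"loci": [{name, position_mb, alleles}, ...]}``."""
        loci = tuple(
            Locus(
                name=str(entry["name"]),
                position_mb=float(entry["position_mb"]),
                alleles=tuple(str(a) for a in entry["alleles"]),
            )
            for entry in spec["loci"]
        )
        return cls(loci=loci)

    @classmethod
    def from_file(cls, path: str | Path) -> "MarkerSchema":
        """Load a schema from a YAML or JSON config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_dict(self) -> dict:
        return {
            "loci": [
                {
                    "name": l.name,
                    "position_mb": l.position_mb,
                    "alleles": list(l.alleles),
                }
                for l in self.loci
            ]
        }


def default_schema(extra_alleles: Mapping[str, Iterable[str]] | None = None) -> MarkerSchema:
    """The default C19 block schema.

    Allele alphabets list only the labels that are documented for these
    markers; the most polymorphic locus (MPRIP) carries at least seven
    alleles in practice, so user extensions are accepted via
    ``extra_alleles`` (a mapping of locus name to additional labels).
    Positions are in Mb on the reference assembly; MPRIP–TCAP spans the
    conserved 5.24 Mb sub-block.
    """
    base = [
        ("SREBF1", 35.4, ("S", "L")),
        ("NT5M", 36.7, ("10", "20", "22", "24")),
        ("MPRIP", 41.2, ("30", "40", "60", "70")),
        ("TCAP", 46.4, ("10", "20")),
        ("GH", 48.9, ("A", "B", "C")),
        ("SCT-FSN", 51.4, ("S", "L")),
    ]
    extra = {k: tuple(str(a) for a in v) for k, v in (extra_alleles or {}).items()}
    loci = tuple(
        Locus(name, pos, alleles + tuple(a for a in extra.get(name, ()) if a not in alleles))
        for name, pos, alleles in base
    )
    return MarkerSchema(loci=loci)
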