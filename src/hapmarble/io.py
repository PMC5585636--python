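"""Validated dataset loading and run manifests.

A dataset is a pedigree (PED-like CSV), unphased genotypes (CSV, two
columns per locus) and phenotypes (CSV: animal, tm, dof, depot, marbling
score).  Loading cross-references ids: orphan genotype or phenotype rows
(unknown animal) are excluded with a warning; structural problems —
duplicate ids, pedigree cycles, schema-invalid alleles — are hard errors
carried in an itemized validation report.  Every pipeline run emits a
manifest (command, configuration snapshot, input hashes, seed, version)
so that deterministic stages are reproducible from the manifest alone.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from . import __version__
from .assoc import TmRecord
from .pedigree import Genotype, Pedigree, read_genotypes, read_pedigree
from .schema import MarkerSchema

__all__ = [
    "DatasetBundle",
    "RunManifest",
    "ValidationError",
    "load_dataset",
    "read_phenotypes",
]


class ValidationError(ValueError):
    """Itemized validation failure."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def read_phenotypes(path: str | Path, tm_window=(20.0, 60.0)) -> list[TmRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "animal" not in reader.fieldnames:
            raise ValidationError([f"{path}: phenotype CSV needs an 'animal' column"])
        for row in reader:
            tm = row.get("tm", "").strip()
            ms = row.get("marbling_score", "").strip()
            records.append(
                TmRecord(
                    animal_id=row["animal"].strip(),
                    tm=float(tm) if tm else None,
                    dof=float(row.get("dof", "0") or 0),
                    depot=(row.get("depot") or "subcutaneous").strip(),
                    marbling_score=int(ms) if ms else None,
                ).validate(tm_window)
            )
    return records


@dataclass
class DatasetBundle:
    pedigree: Pedigree
    genotypes: dict[str, Genotype]
    phenotypes: list[TmRecord]
    warnings: list[str] = field(default_factory=list)


def load_dataset(
    pedigree_path: str | Path,
    genotype_path: Optional[str | Path],
    phenotype_path: Optional[str | Path],
    schema: MarkerSchema,
) -> DatasetBundle:
    """Load and cross-validate a dataset.

    Orphan genotype/phenotype rows are dropped with a warning; duplicate
    animal ids, cycles and invalid alleles raise :class:`ValidationError`.
    """
    problems: list[str] = []
    warnings: list[str] = []
    try:
        pedigree = read_pedigree(pedigree_path)
    except (ValueError, KeyError) as exc:
        raise ValidationError([f"pedigree: {exc}"]) from exc

    genotypes: dict[str, Genotype] = {}
    if genotype_path is not None:
        try:
            raw = read_genotypes(genotype_path, schema)
        except (ValueError, KeyError) as exc:
            raise ValidationError([f"genotypes: {exc}"]) from exc
        for animal_id, gt in raw.items():
            if animal_id not in pedigree:
                warnings.append(
                    f"genotype row for unknown animal {animal_id!r} excluded"
                )
            else:
                genotypes[animal_id] = gt

    phenotypes: list[TmRecord] = []
    if phenotype_path is not None:
        try:
            raw_ph = read_phenotypes(phenotype_path)
        except (ValueError, KeyError) as exc:
            raise ValidationError([f"phenotypes: {exc}"]) from exc
        seen = set()
        for rec in raw_ph:
            if rec.animal_id in seen:
                problems.append(f"duplicate phenotype row for {rec.animal_id!r}")
                continue
            seen.add(rec.animal_id)
            if rec.animal_id not in pedigree:
                warnings.append(
                    f"phenotype row for unknown animal {rec.animal_id!r} excluded"
                )
            else:
                phenotypes.append(rec)
    if problems:
        raise ValidationError(problems)
    return DatasetBundle(
        pedigree=pedigree,
        genotypes=genotypes,
        phenotypes=phenotypes,
        warnings=warnings,
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    command: str
    config: dict
    seed: Optional[int]
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    tool_version: str = __version__
    started: str = ""
    finished: str = ""

    @classmethod
    def start(cls, command: str, config: dict, seed: Optional[int],
              input_paths: dict[str, str | Path] | None = None) -> "RunManifest":
        return cls(
            command=command,
            config=config,
            seed=seed,
            inputs={
                name: _sha256(p)
                for name, p in (input_paths or {}).items()
                if Path(p).exists()
            },
            started=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
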