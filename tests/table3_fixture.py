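"""Programmatic per-animal dataset reproducing the published Mayura
allele-count tables.

The published tables report allele occurrences per Tm class, not raw
animals, so any pairing of the listed alleles into animals yields the same
contingency tables: 132 phenotyped animals (65 below 37 degC, 67 at or
above), all typed at SREBF1/NT5M/TCAP (264 alleles) and 129 typed at MPRIP
(258 alleles — two below-class and one above-class animal untyped there).
"""

from pathlib import Path

# Allele counts per Tm class: (below 37, at/above 37).
TABLE3 = {
    "SREBF1": {"S": (41, 52), "L": (89, 82)},
    "NT5M": {"10": (19, 32), "20": (84, 82), "22": (27, 20)},
    "MPRIP": {"30": (48, 34), "40": (60, 66), "60": (18, 32)},
    "TCAP": {"10": (55, 74), "20": (75, 60)},
}

# Published statistics for these cells.
PRINTED = {
    "SREBF1": ("fisher", 0.25),
    "NT5M": ("chi2", 4.32),
    "MPRIP": ("chi2", 6.5),
    "TCAP": ("fisher", 0.04),
}

N_BELOW, N_ABOVE = 65, 67  # animals per Tm class


def _pairs_for(locus: str, row: int) -> list[tuple[str, str] | None]:
    """Pair the row's alleles into per-animal calls; pad with None for
    animals untyped at this locus."""
    alleles: list[str] = []
    for allele, counts in sorted(TABLE3[locus].items()):
        alleles.extend([allele] * counts[row])
    assert len(alleles) % 2 == 0
    pairs: list[tuple[str, str] | None] = [
        (alleles[i], alleles[i + 1]) for i in range(0, len(alleles), 2)
    ]
    n_animals = N_BELOW if row == 0 else N_ABOVE
    pairs.extend([None] * (n_animals - len(pairs)))
    return pairs


def write_table3_dataset(out_dir: Path) -> tuple[Path, Path, Path]:
    """Write pedigree/genotype/phenotype CSVs whose allele contingency
    tables equal the published cells at every locus."""
    out_dir = Path(out_dir)
    loci = list(TABLE3)
    rows = []
    for row, (n, tm) in enumerate([(N_BELOW, 35.0), (N_ABOVE, 39.0)]):
        calls = {locus: _pairs_for(locus, row) for locus in loci}
        for i in range(n):
            ident = f"{'below' if row == 0 else 'above'}{i:03d}"
            rows.append((ident, tm, {l: calls[l][i] for l in loci}))

    ped = out_dir / "pedigree.csv"
    with open(ped, "w") as fh:
        fh.write("id,sire,dam,sex,breed,wagyu_fraction\n")
        for ident, _, _ in rows:
            fh.write(f"{ident},0,0,U,Wagyu,1.0\n")

    geno = out_dir / "genotypes.csv"
    with open(geno, "w") as fh:
        fh.write("animal," + ",".join(f"{l}_1,{l}_2" for l in loci) + "\n")
        for ident, _, calls in rows:
            cells = []
            for locus in loci:
                pair = calls[locus]
                cells.extend(pair if pair is not None else ("", ""))
            fh.write(f"{ident}," + ",".join(cells) + "\n")

    pheno = out_dir / "phenotypes.csv"
    with open(pheno, "w") as fh:
        fh.write("animal,tm,dof,depot,marbling_score\n")
        for ident, tm, _ in rows:
            fh.write(f"{ident},{tm},300,intramuscular,\n")

    return ped, geno, pheno
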