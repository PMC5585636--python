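"""Segregation-based phasing through a three-generation pedigree.

A maternal grandsire homozygous for 60.10.S.10 lets the whole 20 Mb
haplotype be traced intact into an otherwise ambiguous calf.
"""

from hapmarble import Animal, Genotype, Pedigree, default_schema, phase_pedigree
from hapmarble.schema import SEGMENTS

schema = default_schema()
LOCI = SEGMENTS["S-T"].loci  # MPRIP, TCAP, SREBF1, NT5M


def gt(animal_id, *pairs):
    return Genotype(animal_id, dict(zip(LOCI, pairs)))


pedigree = Pedigree(
    [
        Animal("grandsire", sex="M", breed="Wagyu", wagyu_fraction=1.0),
        Animal("granddam", sex="F", breed="Wagyu", wagyu_fraction=1.0),
        Animal("sire", sex="M", breed="Wagyu", wagyu_fraction=1.0),
        Animal("dam", sire_id="grandsire", dam_id="granddam", sex="F",
               breed="Wagyu", wagyu_fraction=1.0),
        Animal("calf", sire_id="sire", dam_id="dam", breed="Wagyu",
               wagyu_fraction=1.0),
    ]
)
genotypes = {
    "grandsire": gt("grandsire", ("60", "60"), ("10", "10"), ("S", "S"), ("10", "10")),
    "granddam": gt("granddam", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20")),
    "sire": gt("sire", ("40", "40"), ("20", "20"), ("L", "L"), ("20", "20")),
    "dam": gt("dam", ("30", "60"), ("10", "20"), ("S", "L"), ("10", "20")),
    "calf": gt("calf", ("40", "60"), ("10", "20"), ("S", "L"), ("10", "20")),
}

results = phase_pedigree(pedigree, genotypes, schema)
for animal_id, r in results.items():
    print(f"{animal_id:>10}: {r.diplotype}  [{r.provenance[0].value}]")
print(
    "\nThe dam and calf are heterozygous at every locus (8 candidate pairs\n"
    "each on their own), yet segregation resolves both: the grandsire's\n"
    "60.10.S.10 passes intact to the calf."
)
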