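"""Haplotype designations, the combinatorial space, and breed specificity.

Parses dotted haplotype strings for the bovine C19 marbling block,
counts the theoretical haplotype space, and classifies haplotypes as
Wagyu-specific, Bos indicus-specific, common or unclassified.
"""

from hapmarble import (
    classify_haplotype,
    count_haplotype_space,
    default_schema,
    parse_haplotype,
)

schema = default_schema()

# The SREBF1-to-GH segment: allele counts 3 x 5 x 7 x 2 x 3.
space = count_haplotype_space([3, 5, 7, 2, 3])
print(f"possible haplotypes under free recombination: {space}")
print("(only ~14 occur commonly in real herds: the ancestral haplotypes)\n")

for text in ["60.10.S.10", "30.20.S.20", "70.20.S.24", "30.20.L.20", "30.10.L.10"]:
    h = parse_haplotype(text, schema)
    print(f"{text:>12}  ->  {classify_haplotype(h).value}")
print(
    "\nwagyu_specific haplotypes mark the marbling breed; the numeric rule\n"
    "(MPRIP > 60 or NT5M > 22) marks Bos indicus ancestry."
)
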