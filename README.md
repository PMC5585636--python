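# hapmarble

Ancestral-haplotype analysis of marbling genetics in cattle.

Fine marbling — intramuscular deposition of low-melting-temperature,
monounsaturated fat — is the defining trait of Wagyu beef. Within a ~20 Mb
block of bovine chromosome 19 bounded by *SREBF1* and the FASN-adjacent
SCT-FSN marker, multi-megabase **conserved ancestral haplotypes** segregate
intact through pedigrees; only a handful of the 630 combinatorially possible
marker-allele combinations ever occur, and their frequencies differ sharply
between breeds. `hapmarble` is a library for working with these haplotypes
end to end, aimed at quantitative geneticists and livestock researchers:

- **Haplotype data model** — dotted designations such as `60.10.S.10`
  (alleles at MPRIP, TCAP, SREBF1, NT5M), haplotype-space counting, and
  breed-specificity classification (Wagyu-specific list; *Bos indicus* rule
  MPRIP > 60 or NT5M > 22).
- **Pedigree phasing** — diplotypes inferred only from evidence that forces
  them: homozygosity, a single heterozygous locus, or Mendelian segregation
  with no intra-block recombination; optional breed-frequency imputation is
  always flagged. A brute-force enumeration oracle bounds every answer.
- **Breed frequencies and W plots** — per-breed haplotype frequencies over
  resolved chromosomes, and the partition into shared versus breed-specific
  haplotypes.
- **Association statistics** — allele-occurrence contingency tables of fat
  melting temperature (Tm) dichotomized at 37 °C, with first-principles
  Fisher exact and Pearson chi-squared tests, group summaries and Student's
  *t*.
- **Kinetic desaturation model** — the decline of Tm with days on feed
  (DOF) as slow induction of the SCD desaturase:
  `dF/dt = a`, `dU/dt = E`, `dE/dt = bS − cE` with `S = F − U` and
  `Tm = T_Δ·(S/F) + T_U`; simulation, steady-state analysis
  (`S* = ac/b`, `E* = a`), lowess-style smoothing, and least-squares
  parameter fitting.
- **Synthetic data generator** — breed haplotype pools, Mendelian pedigree
  simulation and genotype-dependent Tm phenotypes, so every stage is
  testable without herd records.

## Worked example

Feed the published long-fed Wagyu allele-count cells through the
association module (`python examples/04_tm_association.py`):

```
TCAP alleles:
Tm              10    20   Total
<37degC         55    75     130
>=37degC        74    60     134
Total          129   135     264
Fisher exact p = 0.0374
```

Each of the 132 animals contributes two allele counts; the TCAP 20 allele
is over-represented among the cold (< 37 °C) carcasses and the exact test
rejects independence at the 5% level. The same script reproduces the other
cohort tables: SREBF1 Fisher p = 0.25, NT5M χ² = 4.32 (p ≈ 0.1), MPRIP
χ² = 6.5 on 258 alleles (three phenotyped animals were untyped there).

The kinetic model ties that association to feeding time
(`python examples/05_desaturation_model.py`):

```
fast (TCAP 20/20-like): b=0.001, c=0.1; steady state S*=100.0, E*=1.0
  Tm (degC) at DOF 0/100/200/300: 44.00 / 39.35 / 36.23 / 34.49
slow (TCAP 10/10-like): b=0.0001, c=0.01; steady state S*=100.0, E*=1.0
  Tm (degC) at DOF 0/100/200/300: 44.00 / 42.20 / 38.85 / 35.84
```

Both genotypes start at the same Tm and share the same long-feed floor
(`S* = ac/b = 100` for both parameter sets); the fast enzyme response
reaches cold fat with fewer days on feed. Fitting the free rate constants
`(b, c)` to a noisy synthetic scatter (n = 120, σ = 0.3 °C) recovers them
within a few percent.

The other examples cover haplotype parsing and classification (`01`),
three-generation segregation phasing (`02`), and breed frequency
estimation with the W-plot partition (`03`). A thin CLI wraps the same
library calls:

```bash
hapmarble all --preset wagyu_vs_simmental --seed 1 --out runs/demo
```

chains simulate → phase → freq → wplot → assoc → tmfit and writes
TSV/JSON artifacts plus a run manifest per stage.

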