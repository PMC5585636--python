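# Methods

## The haplotype block and its data model

The analysis concerns a ~20 Mb block of bovine chromosome 19 bounded by
*SREBF1* and the FASN-adjacent SCT-FSN marker, typed at six PCR markers
(SREBF1, NT5M, MPRIP, TCAP, GH, SCT-FSN in physical order). Haplotype
*designations* deliberately differ from physical order: the primary S-T
designation writes MPRIP.TCAP.SREB.NT5M to foreground the conserved
MPRIP–TCAP sub-block, and the extended designation appends GH and SCT-FSN
as `MPRIP.TCAP_GH SCT-FSN`. The schema therefore stores physical position
separately from display order, with display order a per-segment convention
table. Allele labels are opaque strings; the breed-specificity rule that
compares MPRIP and NT5M numerically parses labels on demand and fails
loudly on non-numeric ones (SREBF1/GH/SCT-FSN alleles are letters).

The default schema lists only documented allele labels (MPRIP 30/40/60/70,
NT5M 10/20/22/24, TCAP 10/20, SREBF1 S/L, GH A/B/C, SCT-FSN S/L). MPRIP
carries at least seven alleles in practice; unlisted labels are accepted
via user extension rather than invented. Marker positions in the default
schema are representative Mb coordinates consistent with the 5.24 Mb
MPRIP–TCAP spacing; they matter only for the recombination option of the
simulator.

Breed classification is total and priority-ordered: the enumerated
Wagyu-specific list ({60.10.S.10, 30.20.S.20, 30.10.S.20}) wins over the
numeric *Bos indicus* rule (MPRIP > 60 or NT5M > 22), which wins over the
configurable all-breed ("common") set. The explicit list beats the numeric
rule because the list is enumerative while the rule is a heuristic; with
the default lists the two cannot collide, but user-extended schemas can
make them.

## Phasing

Ancestral haplotypes are assumed to transmit whole — no recombination
within the block during phasing. This is the premise of the analysis
(conserved, non-recombinant haplotypes), not an approximation made for
convenience; the simulator can inject recombinants to probe robustness,
and a genotype that admits no recombination-free explanation against its
relatives is left unresolved rather than force-phased.

Phase is asserted only when forced: complete homozygosity, exactly one
heterozygous locus, or pedigree segregation. The engine is constraint
propagation over exact candidate sets: each typed animal starts with the
full enumeration of haplotype pairs consistent with its genotype (2^(k−1)
unordered pairs for k heterozygous loci, refused above k = 12), and the
sets are pruned to a fixed point breadth-first by generation — downward, a
child's pair must be composable from its parents' transmittable
haplotypes; upward, a parent must be able to serve every typed child.
Determinism follows from the fixed iteration order. The enumeration
routine doubles as the independent oracle: every phased answer is, by
construction and by test, a member of the enumerated set, and every
observed-provenance phase equals the simulated truth on synthetic data.

Breed-frequency imputation of residual ambiguity is off by default and
always flagged `frequency_imputed` (maximum frequency product, ties broken
lexicographically), preserving the distinction between empirically
observed and imputed haplotypes; downstream frequency estimation excludes
imputed and partial copies unless asked otherwise. Mendelian checking
reports a violation only when no assignment of one allele from each typed
parent explains a child's pair — missing data is never evidence.

## Frequencies and W plots

Frequencies are computed over chromosomes, not animals (two per animal,
matching allele-count accounting elsewhere), and only over resolved
chromosomes: unresolved or partial copies leave both numerator and
denominator, so per-breed frequencies sum to one exactly over what was
counted. A breed with nothing resolved is flagged empty rather than
yielding NaNs.

"Common" is operationalized as frequency above 5% in at least one breed.
"Not found in the other breed" is operationalized as frequency below a
specificity floor (default 1%), because absence from a sample is not
absence from a breed. The W-plot partition is disjoint and exhaustive by
construction — A-specific iff common in A and below the floor in B,
symmetrically for B, shared otherwise — and mirror-symmetric under breed
swap. Entries are laid out shared-first, then A-specific, then B-specific,
each by descending frequency, a stable deterministic order. Plotting is a
convenience on top of the TSV data contract, not part of it.

## Association statistics

Tm is dichotomized at a convenience cutoff, default 37 °C (`below` strict,
`at_or_above` inclusive, matching the published row labels). The counting
unit is the allele occurrence: each animal typed at a locus contributes
its two labels to its Tm-class row, so grand totals are twice the number
of typed, phenotyped animals, and totals legitimately differ between loci
of one cohort when typing is incomplete.

Fisher's exact test enumerates the hypergeometric support with margins
fixed, computing point probabilities via log-gamma; the two-sided p-value
follows the sum-of-small-probabilities convention (all tables with point
probability at most the observed one, with a 1e-7 relative tie tolerance),
which matches the published values. One-sided alternatives are available.
The Pearson chi-squared statistic uses margin-derived expected counts with
no continuity correction anywhere — the published statistics are
uncorrected — and its upper-tail p-value is the regularized incomplete
gamma Q(df/2, x/2). No multiple-testing correction is applied across
loci; raw p-values are reported as such. Group summaries use the sample
standard deviation (n−1) over √n for the SEM, undefined at n = 1; the
two-sample test is classical pooled-variance Student's t, with the
zero-variance degenerate cases (p = 1 at equal means, p → 0 flagged at
unequal means) handled explicitly.

## The desaturation model

De novo fat is produced saturated at constant rate *a*; the desaturase
pool *E* is induced by saturated fat *S* and decays; unsaturated fat *U*
grows in proportion to *E*:

    dF/dt = a,   dU/dt = E,   dE/dt = bS − cE,   S = F − U,
    Tm = T_Δ·(S/F) + T_U.

The (S, E) subsystem is affine linear with steady state S* = ac/b,
E* = a, so the two preset parameter sets — fast (b = 0.001, c = 0.1) and
slow (b = 0.0001, c = 0.01) — share S* = 100: the model-level counterpart
of the observed common long-feed Tm floor. The slow preset has c² < 4b
(complex eigenvalues) and approaches the floor with a damped overshoot.
Starting from E(0) = 0 the Tm curve declines slowly at first and then
faster as enzyme accumulates.

Units and defaults: time is days (days on feed); *a* = 1 fixes the mass
unit; F(0) = 1, U(0) = E(0) = 0; T_Δ = 14 °C and T_U = 30 °C make the
default curve span ≈ 44 → 30 °C, consistent with observed subcutaneous and
intramuscular Tm ranges (≈ 33–42 °C). All are configurable; the enzyme
unit is arbitrary, fixed by dU/dt = E. The Tm mapping is read as the
product form T_Δ·(S/F) + T_U, the only form consistent with Tm falling in
proportion to the unsaturated fraction and bounded in [T_U, T_U + T_Δ].

Integration is fixed-step classical Runge–Kutta (default 0.25 day): the
system is non-stiff at these parameter scales, and the fixed step makes
results bit-deterministic. The matrix-exponential closed form of the
(S, E) subsystem serves as the analytic test oracle (agreement ≤ 1e-6 on
[0, 300] for both presets; conservation S + U = F and F = F₀ + at hold to
1e-9 relative). Should roundoff push U past F it is clamped and logged;
the clamp never triggers at the preset scales.

Fitting minimizes the residual sum of squares of model Tm at the observed
DOF (Levenberg–Marquardt, rate constants on a log10 scale to stay
positive, one simulation per objective evaluation with linear
interpolation). Under-determined problems — fewer observations than free
parameters plus one, or a single distinct DOF — are refused. The smoother
is locally weighted linear regression with tricube weights; the span is a
bandwidth in DOF days by default (a fraction-of-points mode is provided),
since the published smoothing span of 100 reads most naturally in x-axis
units. Local linear regression reproduces straight-line data exactly for
any span, which pins down the contract.

Whether the published preset parameters were fitted or chosen by visual
similarity is unknowable; they are treated here as named presets, not
estimates.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
founder chromosomes drawn i.i.d. from per-breed haplotype pools, whole-
haplotype Mendelian transmission (optional recombination at a uniformly
chosen physical boundary per meiosis), locus-wise missingness, and Tm
phenotypes from the kinetic model with TCAP-genotype-dependent rate
constants plus additive sire offsets and Gaussian noise. Heterozygote
kinetics default to the geometric mean of the homozygote rate constants —
a modelling convention, configurable and recorded in the manifest, since
no heterozygote kinetics are documented.

No numeric haplotype frequencies are published for real herds, so the
default pools are explicitly illustrative: they reproduce the documented
*structure* — about 14 common haplotypes across the two breeds, the named
Wagyu-specific haplotypes present only in the Wagyu pool at a combined
frequency near 0.45, the shared 30.20.L.20 / 40.20.L.20 common to both —
not measured values. Consequently, passing closure tests demonstrate that
the pipeline recovers what the generator put in (phasing truth, pool
frequencies, breed-specific placement, genotype–phenotype association),
not that real herds have these frequencies.

Phenotype defaults are chosen to match the descriptive statistics of the
source herds: noise sd 1.0 °C (the thermocycler Tm assay is highly
reproducible; this is residual biological plus measurement variation),
sire offset sd 0.75 °C so that extreme sires among a handful differ by
about 2 °C, and per-scenario feeding windows — 300 ± 20 days for the
long-fed full-blood cohort, mean 104 (range 17–288) for the short-fed
variable-DOF herd, and a mid-window truncated normal (mean 150, sd 50,
range 30–300) for the two-breed comparison, where the kinetic curves
straddle the 37 °C cutoff and the dichotomy is informative. Scenario
sizes (a few hundred animals, 132-animal association cohorts) mirror the
source cohorts while keeping the default test run quick.

Real sire effects could be additive or haplotype-mediated; both modes
exist (explicit per-sire offsets or i.i.d. draws), with additive i.i.d.
offsets the default.

## Degenerate inputs and tie-breaks

Validation errors are raised (never silently coerced) for: unknown allele
labels or segments, wrong token counts, non-positive allele counts,
thresholds outside (0, 1), a specificity floor at or above the common
threshold, all-zero or negative contingency tables, zero margins, groups
of size one where an SEM is required, non-monotone time grids, and pool
frequencies not summing to one. Ties in frequency imputation break
lexicographically on the haplotype string; W-plot layout and phasing
iteration order are fixed; every stochastic routine takes an explicit
generator or seed. Scenario files are byte-reproducible for a given seed
(the scenario manifest excludes wall-clock time; per-run CLI manifests
carry timestamps and are not part of that contract).

## Known limitations

- Phasing is combinatorial, not statistical: no EM/HMM population
  phasing, no genotype imputation, no likelihood-based pedigree
  reconstruction. Animals whose ambiguity is not resolved by forced
  evidence stay unresolved unless frequency imputation is explicitly
  enabled.
- The published group means and distributions from private herd records
  are not reproducible; property-based closures on synthetic data stand
  in for them, with the limits noted above.
- The desaturation model is a two-pool abstraction; it does not model SCD
  transcription, SREBF1 regulation, depot differences or lipid chemistry,
  and its Tm mapping is linear in the saturated fraction by construction.
- The upward constraint in pedigree phasing treats each parent–child pair
  against the other parent's transmittable set; joint consistency across
  full sibships beyond that relaxation is not enforced (it would only
  tighten already-rare ambiguous cases).
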