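"""Segregation-based phasing against the brute-force enumeration oracle."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from hapmarble import (
    Animal,
    Genotype,
    Pedigree,
    Provenance,
    check_mendelian,
    enumerate_consistent_diplotypes,
    phase_pedigree,
    phase_trio,
    phase_unrelated,
)
from hapmarble.haplotype import OBSERVED_PROVENANCES
from hapmarble.phasing import MendelianError, TransmissionConstraint
from hapmarble.schema import SEGMENTS
from hapmarble.synthetic import ScenarioConfig, WAGYU_POOL, simulate_pedigree_genotypes

ST_LOCI = SEGMENTS["S-T"].loci


def gt(animal_id, mprip, tcap, sreb, nt5m):
    calls = dict(zip(ST_LOCI, [mprip, tcap, sreb, nt5m]))
    return Genotype(animal_id, calls)


def trio_pedigree():
    return Pedigree(
        [
            Animal("sire", sex="M"),
            Animal("dam", sex="F"),
            Animal("kid", sire_id="sire", dam_id="dam"),
        ]
    )


class TestCheckMendelian:
    def test_forced_violation(self):
        genotypes = {
            "kid": Genotype("kid", {"TCAP": ("10", "10")}),
            "sire": Genotype("sire", {"TCAP": ("20", "20")}),
            "dam": Genotype("dam", {"TCAP": ("10", "20")}),
        }
        violations = check_mendelian(trio_pedigree(), genotypes)
        assert len(violations) == 1
        assert violations[0].locus == "TCAP"
        assert violations[0].animal_id == "kid"

    def test_consistent_trio(self):
        genotypes = {
            "kid": Genotype("kid", {"TCAP": ("10", "20")}),
            "sire": Genotype("sire", {"TCAP": ("10", "10")}),
            "dam": Genotype("dam", {"TCAP": ("20", "20")}),
        }
        assert check_mendelian(trio_pedigree(), genotypes) == []

    def test_missing_parent_is_not_evidence(self):
        genotypes = {
            "kid": Genotype("kid", {"TCAP": ("10", "10")}),
            "dam": Genotype("dam", {"TCAP": ("20", "20")}),
        }
        # dam alone cannot supply both 10s only if the sire also couldn't;
        # the untyped sire leaves one 10 unexplained-but-possible... but the
        # dam must transmit one allele, and 10 is not in her pair.
        assert len(check_mendelian(trio_pedigree(), genotypes)) == 1
        genotypes["dam"] = Genotype("dam", {"TCAP": ("10", "20")})
        assert check_mendelian(trio_pedigree(), genotypes) == []

    def test_matches_exhaustive_transmission_enumeration(self, rng):
        alleles = ["10", "20", "30"]

        def random_pair():
            return tuple(sorted(rng.choice(alleles, size=2)))

        for _ in range(200):
            child, sire, dam = random_pair(), random_pair(), random_pair()
            genotypes = {
                "kid": Genotype("kid", {"L": child}),
                "sire": Genotype("sire", {"L": sire}),
                "dam": Genotype("dam", {"L": dam}),
            }
            oracle_ok = any(
                tuple(sorted((s, d))) == child
                for s, d in itertools.product(sire, dam)
            )
            found = check_mendelian(trio_pedigree(), genotypes)
            assert (found == []) == oracle_ok


class TestEnumeration:
    def test_no_heterozygous_locus_single_pair(self, schema):
        pairs = enumerate_consistent_diplotypes(
            gt("a", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20")), schema
        )
        assert len(pairs) == 1

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_unordered_pair_count_is_2_to_k_minus_1(self, schema, k):
        calls = {
            "MPRIP": ("30", "40"),
            "TCAP": ("10", "20"),
            "SREBF1": ("L", "S"),
            "NT5M": ("10", "20"),
        }
        loci = ST_LOCI[:k]
        full = {
            l: (calls[l] if l in loci else (calls[l][0], calls[l][0]))
            for l in ST_LOCI
        }
        pairs = enumerate_consistent_diplotypes(Genotype("a", full), schema)
        assert len(pairs) == 2 ** (k - 1)

    def test_constraint_can_empty_the_set(self, schema):
        g = gt("a", ("30", "60"), ("10", "10"), ("S", "S"), ("10", "10"))
        from hapmarble import parse_haplotype

        forbidden = frozenset({parse_haplotype("40.20.L.20", schema)})
        pairs = enumerate_consistent_diplotypes(
            g, schema, constraints=TransmissionConstraint(sire=forbidden)
        )
        assert pairs == set()

    def test_refuses_large_enumeration(self, schema):
        g = gt("a", ("30", "60"), ("10", "20"), ("S", "L"), ("10", "20"))
        with pytest.raises(ValueError):
            enumerate_consistent_diplotypes(g, schema, max_het=3)


class TestPhaseUnrelated:
    def test_all_homozygous(self, schema):
        r = phase_unrelated(
            gt("a", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20")), schema
        )
        assert r.is_resolved
        assert str(r.diplotype) == "30.20.L.20/30.20.L.20"
        assert r.provenance[0] == Provenance.OBSERVED_HOMOZYGOUS

    def test_single_heterozygous_locus(self, schema):
        r = phase_unrelated(
            gt("a", ("30", "60"), ("10", "10"), ("S", "S"), ("10", "10")), schema
        )
        assert r.is_resolved
        assert {str(h) for h in r.diplotype.haplotypes} == {"30.10.S.10", "60.10.S.10"}
        assert r.provenance[0] == Provenance.SINGLE_HETEROZYGOUS_LOCUS

    def test_fully_heterozygous_unresolved_with_eight_candidates(self, schema):
        r = phase_unrelated(
            gt("a", ("30", "60"), ("10", "20"), ("S", "L"), ("10", "20")), schema
        )
        assert not r.is_resolved
        assert len(r.candidates) == 8  # 2^4 ordered = 8 unordered

    def test_missing_locus_marks_partial(self, schema):
        r = phase_unrelated(
            gt("a", ("30", "30"), None, ("L", "L"), ("20", "20")), schema
        )
        assert r.partial
        assert r.is_resolved  # phased over the typed loci
        assert "?" in str(r.diplotype)


class TestPhaseTrio:
    def test_unique_solution_from_spec_example(self, schema):
        sire = gt("s", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20"))
        dam = gt("d", ("30", "60"), ("10", "20"), ("S", "L"), ("10", "20"))
        child = gt("c", ("30", "60"), ("10", "20"), ("S", "L"), ("10", "20"))
        # Dam is ambiguous alone, but a homozygous sire forces the child's
        # paternal haplotype, and brute force leaves one unordered pair.
        r = phase_trio(child, sire, dam, schema)
        # Paternal 30.20.L.20 forced; maternal must be 60.10.S.10.
        assert r.is_resolved
        assert {str(h) for h in r.diplotype.haplotypes} == {"30.20.L.20", "60.10.S.10"}
        assert r.provenance[0] == Provenance.SEGREGATION

    def test_child_of_homozygous_parents(self, schema):
        hom = gt("p", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20"))
        child = gt("c", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20"))
        r = phase_trio(child, hom, hom, schema)
        assert str(r.diplotype) == "30.20.L.20/30.20.L.20"

    def test_fully_heterozygous_trio_unresolved(self, schema):
        het = gt("x", ("30", "60"), ("10", "20"), ("S", "L"), ("10", "20"))
        r = phase_trio(het, het, het, schema)
        assert not r.is_resolved
        assert len(r.candidates) > 1

    def test_mendelian_violation_raises(self, schema):
        sire = gt("s", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20"))
        dam = gt("d", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20"))
        child = gt("c", ("60", "60"), ("20", "20"), ("L", "L"), ("20", "20"))
        with pytest.raises(MendelianError):
            phase_trio(child, sire, dam, schema)


class TestPhasePedigree:
    def test_three_generation_haplotype_traced_intact(self, schema):
        """A homozygous maternal grandsire's haplotype passes intact to the
        calf and is recovered by segregation."""
        animals = [
            Animal("grandsire", sex="M"),
            Animal("granddam", sex="F"),
            Animal("sire", sex="M"),
            Animal("dam", sire_id="grandsire", dam_id="granddam", sex="F"),
            Animal("calf", sire_id="sire", dam_id="dam"),
        ]
        genotypes = {
            "grandsire": gt("grandsire", ("60", "60"), ("10", "10"), ("S", "S"), ("10", "10")),
            "granddam": gt("granddam", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20")),
            "sire": gt("sire", ("40", "40"), ("20", "20"), ("L", "L"), ("20", "20")),
            "dam": gt("dam", ("30", "60"), ("10", "20"), ("S", "L"), ("10", "20")),
            "calf": gt("calf", ("40", "60"), ("10", "20"), ("S", "L"), ("10", "20")),
        }
        results = phase_pedigree(Pedigree(animals), genotypes, schema)
        assert all(r.is_resolved for r in results.values())
        calf = results["calf"].diplotype
        assert {str(h) for h in calf.haplotypes} == {"60.10.S.10", "40.20.L.20"}
        assert results["calf"].provenance[0] == Provenance.SEGREGATION
        dam = results["dam"].diplotype
        assert "60.10.S.10" in {str(h) for h in dam.haplotypes}

    def test_unrelated_homozygous_animals_all_phased(self, schema):
        animals = [Animal(f"a{i}", sex="U") for i in range(5)]
        genotypes = {
            a.id: gt(a.id, ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20"))
            for a in animals
        }
        results = phase_pedigree(Pedigree(animals), genotypes, schema)
        assert all(
            r.provenance[0] == Provenance.OBSERVED_HOMOZYGOUS
            for r in results.values()
        )

    def test_mendelian_violation_left_unresolved(self, schema):
        animals = [
            Animal("s", sex="M"),
            Animal("d", sex="F"),
            Animal("k", sire_id="s", dam_id="d"),
        ]
        genotypes = {
            "s": gt("s", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20")),
            "d": gt("d", ("30", "30"), ("20", "20"), ("L", "L"), ("20", "20")),
            "k": gt("k", ("60", "60"), ("10", "10"), ("S", "S"), ("10", "10")),
        }
        results = phase_pedigree(Pedigree(animals), genotypes, schema)
        assert not results["k"].is_resolved
        assert results["k"].violations

    def test_simulated_recovery_rate(self, schema):
        """On a 200-plus-animal three-generation pedigree with no missing
        data, phasing recovers at least 95% of the diplotypes the
        enumeration oracle shows to be uniquely resolvable."""
        config = ScenarioConfig(
            seed=424242,
            pools=(WAGYU_POOL,),
            founders_per_breed=60,
            offspring_schedule=(80, 80),
        )
        sim = simulate_pedigree_genotypes(config)
        results = phase_pedigree(sim.pedigree, sim.genotypes, schema)
        resolvable = recovered = 0
        for animal_id, r in results.items():
            truth = sim.true_diplotypes[animal_id]
            oracle = enumerate_consistent_diplotypes(
                sim.genotypes[animal_id], schema
            )
            if len(oracle) == 1:
                resolvable += 1
                if r.is_resolved and r.diplotype.haplotypes == truth.haplotypes:
                    recovered += 1
        assert resolvable > 0
        assert recovered / resolvable >= 0.95

    def test_frequency_imputation_flagged_and_consistent(self, schema):
        from hapmarble.breed_freq import FreqTable
        from collections import Counter

        table = FreqTable(
            counts={"Wagyu": Counter({"60.10.S.10": 50, "30.20.L.20": 30,
                                      "30.10.S.20": 10, "60.20.L.10": 10})},
            chromosomes={"Wagyu": 100},
        )
        animals = [Animal("a", breed="Wagyu", wagyu_fraction=1.0)]
        genotypes = {
            "a": gt("a", ("30", "60"), ("10", "20"), ("S", "L"), ("10", "20"))
        }
        results = phase_pedigree(
            Pedigree(animals), genotypes, schema, freq_table=table
        )
        r = results["a"]
        assert r.is_resolved
        assert r.provenance[0] == Provenance.FREQUENCY_IMPUTED
        assert {str(h) for h in r.diplotype.haplotypes} == {"60.10.S.10", "30.20.L.20"}
        assert r.diplotype.matches_genotype(genotypes["a"].calls)


class TestOracleContainmentProperty:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_phase_output_within_enumeration_and_exact_when_observed(
        self, schema, seed
    ):
        """Phased diplotypes always lie in the enumeration oracle's set, and
        observed-provenance phases equal the simulated truth."""
        config = ScenarioConfig(
            seed=seed,
            pools=(WAGYU_POOL,),
            founders_per_breed=8,
            offspring_schedule=(10,),
        )
        sim = simulate_pedigree_genotypes(config)
        results = phase_pedigree(sim.pedigree, sim.genotypes, schema)
        for animal_id, r in results.items():
            oracle = enumerate_consistent_diplotypes(sim.genotypes[animal_id], schema)
            truth = sim.true_diplotypes[animal_id]
            if r.is_resolved:
                assert r.diplotype.haplotypes in oracle
                assert r.diplotype.matches_genotype(sim.genotypes[animal_id].calls)
                if r.provenance[0] in OBSERVED_PROVENANCES:
                    assert r.diplotype.haplotypes == truth.haplotypes
            else:
                assert set(r.candidates) <= oracle
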