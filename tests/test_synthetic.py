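"""Synthetic generator: founder sampling, transmission, phenotypes, presets."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from hapmarble import (
    BreedPool,
    DofDistribution,
    check_mendelian,
    generate_scenario,
    sample_founder_diplotypes,
    simulate_pedigree_genotypes,
    simulate_tm_phenotypes,
)
from hapmarble.synthetic import ScenarioConfig, WAGYU_POOL


class TestFounderSampling:
    def test_degenerate_pool(self, schema, rng):
        pool = BreedPool("X", {"30.20.L.20": 1.0})
        ds = sample_founder_diplotypes(pool, 5, rng, schema)
        haps = [str(h) for d in ds for h in d.haplotypes]
        assert haps == ["30.20.L.20"] * 10

    def test_empirical_frequency_converges(self, schema):
        rng = np.random.default_rng(31)
        pool = BreedPool("X", {"30.20.L.20": 0.5, "60.10.S.10": 0.5})
        ds = sample_founder_diplotypes(pool, 10_000, rng, schema)
        haps = [str(h) for d in ds for h in d.haplotypes]
        freq = haps.count("30.20.L.20") / len(haps)
        assert 0.48 <= freq <= 0.52  # ~99% binomial interval at n = 20000

    def test_invalid_pool_rejected(self):
        with pytest.raises(ValueError):
            BreedPool("X", {"30.20.L.20": 0.9})
        with pytest.raises(ValueError):
            BreedPool("X", {})


class TestPedigreeSimulation:
    def test_homozygous_sires_always_transmit_their_haplotype(self, schema):
        config = ScenarioConfig(
            seed=5,
            pools=(BreedPool("X", {"60.10.S.10": 1.0}),),
            founders_per_breed=6,
            offspring_schedule=(20,),
        )
        sim = simulate_pedigree_genotypes(config)
        for animal in sim.pedigree.by_generation():
            if animal.sire_id:
                haps = {str(h) for h in sim.true_diplotypes[animal.id].haplotypes}
                assert "60.10.S.10" in haps

    def test_no_recombination_children_carry_parental_haplotypes(self, schema):
        config = ScenarioConfig(
            seed=6, pools=(WAGYU_POOL,), founders_per_breed=12,
            offspring_schedule=(30, 30),
        )
        sim = simulate_pedigree_genotypes(config)
        for animal in sim.pedigree.by_generation():
            if not animal.sire_id:
                continue
            parental = set()
            for parent_id in (animal.sire_id, animal.dam_id):
                parental.update(sim.true_diplotypes[parent_id].haplotypes)
            assert set(sim.true_diplotypes[animal.id].haplotypes) <= parental

    def test_recombination_can_create_novel_haplotypes(self, schema):
        config = ScenarioConfig(
            seed=7, pools=(WAGYU_POOL,), founders_per_breed=20,
            offspring_schedule=(200,), recombination_rate=0.5,
        )
        sim = simulate_pedigree_genotypes(config)
        novel = 0
        for animal in sim.pedigree.by_generation():
            if not animal.sire_id:
                continue
            parental = set()
            for parent_id in (animal.sire_id, animal.dam_id):
                parental.update(sim.true_diplotypes[parent_id].haplotypes)
            novel += not (
                set(sim.true_diplotypes[animal.id].haplotypes) <= parental
            )
        assert novel > 0

    def test_mendelian_consistent_by_construction(self, schema):
        config = ScenarioConfig(
            seed=8, pools=(WAGYU_POOL,), founders_per_breed=40,
            offspring_schedule=(80, 80),
        )
        sim = simulate_pedigree_genotypes(config)
        assert len(sim.pedigree) >= 200
        assert check_mendelian(sim.pedigree, sim.genotypes) == []

    def test_missingness_applied(self, schema):
        config = ScenarioConfig(
            seed=9, pools=(WAGYU_POOL,), founders_per_breed=30,
            offspring_schedule=(50,), missingness=0.2,
        )
        sim = simulate_pedigree_genotypes(config)
        n_missing = sum(
            1
            for gt in sim.genotypes.values()
            for call in gt.calls.values()
            if call is None
        )
        n_calls = sum(len(gt.calls) for gt in sim.genotypes.values())
        assert 0.1 < n_missing / n_calls < 0.3


class TestPhenotypes:
    @staticmethod
    def diplotypes_for(config, seed=11):
        return simulate_pedigree_genotypes(config)

    def test_fast_genotype_is_colder_mid_feeding(self, schema):
        config = ScenarioConfig(
            seed=11, pools=(WAGYU_POOL,), founders_per_breed=60,
            offspring_schedule=(60,), noise_sd=0.0, sire_effect_sd=0.0,
            dof=DofDistribution(120.0, 0.0, 120.0, 120.0),
        )
        sim = simulate_pedigree_genotypes(config)
        rng = np.random.default_rng(1)
        records = simulate_tm_phenotypes(sim.true_diplotypes, config, rng)
        by_genotype = {}
        for r in records:
            d = sim.true_diplotypes[r.animal_id]
            key = "/".join(sorted(h.allele("TCAP") for h in d.haplotypes))
            by_genotype.setdefault(key, []).append(r.tm)
        assert max(by_genotype["20/20"]) < min(by_genotype["10/10"])

    def test_zero_dof_genotypes_identical(self, schema):
        config = ScenarioConfig(
            seed=12, pools=(WAGYU_POOL,), founders_per_breed=40,
            offspring_schedule=(10,), noise_sd=0.0, sire_effect_sd=0.0,
            dof=DofDistribution(0.0, 0.0, 0.0, 0.0),
        )
        sim = simulate_pedigree_genotypes(config)
        rng = np.random.default_rng(2)
        records = simulate_tm_phenotypes(sim.true_diplotypes, config, rng)
        tms = {r.tm for r in records}
        assert len(tms) == 1  # shared initial state -> identical initial Tm

    def test_sire_offsets_recovered_in_progeny_means(self, schema):
        config = ScenarioConfig(
            seed=13,
            pools=(BreedPool("X", {"30.20.L.20": 1.0}),),
            founders_per_breed=40,
            offspring_schedule=(400,),
            noise_sd=0.4,
            sire_offsets={"X-G0-0000": 0.0, "X-G0-0001": -2.0},
            dof=DofDistribution(300.0, 10.0, 280.0, 320.0),
        )
        sim = simulate_pedigree_genotypes(config)
        rng = np.random.default_rng(3)
        offspring = [a.id for a in sim.pedigree.by_generation()
                     if a.sire_id in ("X-G0-0000", "X-G0-0001")]
        records = simulate_tm_phenotypes(
            sim.true_diplotypes, config, rng, pedigree=sim.pedigree, ids=offspring
        )
        means = {}
        for r in records:
            sire = sim.pedigree[r.animal_id].sire_id
            means.setdefault(sire, []).append(r.tm)
        diff = np.mean(means["X-G0-0000"]) - np.mean(means["X-G0-0001"])
        sem = 0.4 * np.sqrt(1 / len(means["X-G0-0000"]) + 1 / len(means["X-G0-0001"]))
        assert abs(diff - 2.0) < 4 * sem + 0.05

    def test_unmapped_genotype_errors(self, schema):
        config = ScenarioConfig(
            seed=14, pools=(WAGYU_POOL,), founders_per_breed=10,
            offspring_schedule=(5,), genotype_params={"20/20": None},
        )
        sim = simulate_pedigree_genotypes(config)
        with pytest.raises(KeyError):
            simulate_tm_phenotypes(
                sim.true_diplotypes, config, np.random.default_rng(0)
            )


class TestScenarios:
    def test_same_seed_byte_identical(self, tmp_path):
        def digest(d: Path) -> dict:
            return {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(d.iterdir())
            }

        generate_scenario("crossbred_f1", seed=3, out_dir=tmp_path / "a")
        generate_scenario("crossbred_f1", seed=3, out_dir=tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_mayura_preset_long_fed(self):
        bundle = generate_scenario("mayura_300dof", seed=4)
        dofs = [r.dof for r in bundle.phenotypes]
        assert len(bundle.phenotypes) == 132
        assert min(dofs) >= 280 and max(dofs) <= 320

    def test_melaleuka_preset_variable_dof(self):
        bundle = generate_scenario("melaleuka_variable_dof", seed=4)
        dofs = [r.dof for r in bundle.phenotypes]
        assert min(dofs) >= 17 and max(dofs) <= 288
        assert np.std(dofs) > 20

    def test_crossbred_f1_half_wagyu(self):
        bundle = generate_scenario("crossbred_f1", seed=5)
        f1 = [a for a in bundle.pedigree.by_generation() if a.breed == "F1"]
        assert f1 and all(a.wagyu_fraction == 0.5 for a in f1)
        for a in f1:
            assert bundle.pedigree[a.sire_id].breed == "Wagyu"
            assert bundle.pedigree[a.dam_id].breed == "Simmental"

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="wagyu_vs_simmental"):
            generate_scenario("nope", seed=0)

    def test_manifest_records_seed_and_config_hash(self, tmp_path):
        bundle = generate_scenario("mayura_300dof", seed=21, out_dir=tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 21
        assert manifest["preset"] == "mayura_300dof"
        assert len(manifest["config_sha256"]) == 64
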