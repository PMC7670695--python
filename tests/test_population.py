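"""Herd geography, breeding scenarios and the multi-generation study run."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import spatialbv as sbv
from spatialbv import (BreedingScenario, TraitArchitecture, assign_founders,
                       breed_generation, layout, pedigree_A,
                       run_study_population, sample_herd_sizes,
                       simulate_founders)
from spatialbv.population import PedigreeRecorder

ZTP_MEAN = 1.5 / (1 - np.exp(-1.5))     # 1.9310, closed form


class TestHerdSizes:
    def test_zero_never_occurs(self):
        sizes = sample_herd_sizes(100_000, 1.5, seed=1)
        assert sizes.min() >= 1

    def test_mean_matches_truncated_poisson(self):
        sizes = sample_herd_sizes(200_000, 1.5, seed=2)
        se = sizes.std() / np.sqrt(sizes.size)
        assert abs(sizes.mean() - ZTP_MEAN) < 4 * se

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            sample_herd_sizes(10, 0.0)


class TestLayout:
    def test_zero_location_variance_collapses_to_centres(self):
        lay = layout(5, 4, location_variance=0.0, seed=3)
        np.testing.assert_allclose(lay.herd_coords,
                                   lay.village_coords[lay.herd_to_village])

    def test_mean_herd_distance_is_rayleigh(self):
        v = 3.5e-4
        lay = layout(100, 20, location_variance=v, seed=4)
        d = np.linalg.norm(lay.herd_coords - lay.village_coords[lay.herd_to_village],
                           axis=1)
        # |BVN(0, v I)| is Rayleigh(sqrt(v)): mean sqrt(pi v / 2)
        expected = np.sqrt(np.pi * v / 2)
        assert d.mean() == pytest.approx(expected, rel=0.05)

    def test_deterministic_and_sized(self):
        a, b = layout(10, 20, seed=5), layout(10, 20, seed=5)
        np.testing.assert_array_equal(a.herd_coords, b.herd_coords)
        np.testing.assert_array_equal(a.herd_sizes, b.herd_sizes)
        assert a.n_herds == 200


@pytest.fixture(scope="module")
def small_founders(tiny_gmap):
    return simulate_founders(400, tiny_gmap, seed=10)


@pytest.fixture(scope="module")
def small_arch(tiny_gmap):
    return TraitArchitecture.sample(tiny_gmap,
                                    np.random.default_rng(10))


class TestAssignFounders:
    def test_top_ranked_males_are_the_bulls(self, small_founders, small_arch):
        lay = layout(4, 5, seed=11)
        scenario = BreedingScenario.for_connectedness("weak", 4)
        seed = 12
        cohort, _ = assign_founders(small_founders, lay, scenario, small_arch,
                                    seed)
        # mirror the implementation's first rng draw to recover the sexes
        rng = np.random.default_rng(seed)
        sex = np.where(rng.random(small_founders.n_founders) < 0.5, "M", "F")
        tbv = sbv.true_breeding_values(small_founders.haplotypes, small_arch,
                                       small_founders.gmap)
        top = np.sort(tbv[sex == "M"])[-scenario.n_bulls:]
        bull_tbv = np.sort(np.concatenate([
            sbv.true_breeding_values(cohort.village_bull_haps, small_arch,
                                     small_founders.gmap),
            sbv.true_breeding_values(cohort.ai_bull_haps, small_arch,
                                     small_founders.gmap)]))
        np.testing.assert_allclose(bull_tbv, top)

    def test_cow_count_conserved(self, small_founders, small_arch):
        lay = layout(4, 5, seed=13)
        scenario = BreedingScenario.for_connectedness("weak", 4)
        cohort, _ = assign_founders(small_founders, lay, scenario, small_arch, 14)
        assert cohort.n_cows == lay.herd_sizes.sum()
        counts = np.bincount(cohort.cow_herd, minlength=lay.n_herds)
        np.testing.assert_array_equal(counts, lay.herd_sizes)

    def test_strong_scenario_all_service_from_national_pool(self, small_founders,
                                                            small_arch):
        lay = layout(4, 5, seed=15)
        scenario = BreedingScenario.for_connectedness("strong", 4)
        cohort, _ = assign_founders(small_founders, lay, scenario, small_arch, 16)
        assert cohort.village_bull_id.size == 0
        assert cohort.ai_bull_id.size == scenario.n_ai_bulls == 4
        assert cohort.herd_is_ai.all()

    def test_too_few_males_fails(self, tiny_gmap, small_arch):
        few = simulate_founders(6, tiny_gmap, seed=17)
        lay = layout(4, 5, seed=17)
        with pytest.raises(ValueError, match="bulls"):
            assign_founders(few, lay, BreedingScenario.for_connectedness("weak", 4),
                            small_arch, 18)


class TestBreedGeneration:
    def _setup(self, connectedness, seed, founders, arch):
        lay = layout(4, 5, seed=seed)
        scenario = BreedingScenario.for_connectedness(connectedness, 4)
        cohort, rec = assign_founders(founders, lay, scenario, arch, seed)
        return lay, scenario, cohort, rec

    def test_weak_all_village_calves_share_one_sire(self, small_founders,
                                                    small_arch, tiny_gmap):
        lay, scenario, cohort, rec = self._setup("weak", 21, small_founders,
                                                 small_arch)
        breed_generation(cohort, scenario, lay, tiny_gmap, small_arch, rec,
                         np.random.default_rng(22))
        ped = rec.frame()
        calves = ped[ped.generation == 1]
        village = lay.herd_to_village[calves["herd"].to_numpy() - 1]
        for v in range(4):
            assert calves.loc[village == v, "sire"].nunique() == 1

    def test_intermediate_ai_fraction(self, small_founders, small_arch):
        lay, scenario, cohort, _ = self._setup("intermediate", 23,
                                               small_founders, small_arch)
        assert cohort.herd_is_ai.sum() == round(0.25 * lay.n_herds)

    def test_offspring_tbv_centred_on_midparent(self, small_arch, tiny_gmap):
        lay = layout(30, 20, seed=24)
        founders = simulate_founders(3000, tiny_gmap, seed=24)
        scenario = BreedingScenario.for_connectedness("weak", 30)
        cohort, rec = assign_founders(founders, lay, scenario, small_arch, 25)
        rng = np.random.default_rng(26)
        nxt, (f_ids, f_tbv, _, _) = breed_generation(
            cohort, scenario, lay, tiny_gmap, small_arch, rec, rng,
            keep_male_haps=True)
        ped = rec.frame().set_index("id")
        sire_tbv = dict(zip(
            np.concatenate([cohort.village_bull_id, cohort.ai_bull_id]),
            np.concatenate([
                sbv.true_breeding_values(cohort.village_bull_haps, small_arch, tiny_gmap),
                sbv.true_breeding_values(cohort.ai_bull_haps, small_arch, tiny_gmap)])))
        dam_tbv = dict(zip(cohort.cow_id, cohort.cow_tbv))
        assert f_ids.size >= 500     # ~1160 matings, half female calves
        parents = ped.loc[f_ids]
        mid = np.array([(sire_tbv[s] + dam_tbv[d]) / 2
                        for s, d in zip(parents.sire, parents.dam)])
        # deviations from midparent are Mendelian sampling with mean zero
        dev = f_tbv - mid
        z = dev.mean() / (dev.std() / np.sqrt(dev.size))
        assert abs(z) < 3

    def test_herd_stable_down_maternal_line(self, small_founders, small_arch,
                                            tiny_gmap):
        lay, scenario, cohort, rec = self._setup("weak", 27, small_founders,
                                                 small_arch)
        breed_generation(cohort, scenario, lay, tiny_gmap, small_arch, rec,
                         np.random.default_rng(28))
        ped = rec.frame()
        herd_of = dict(zip(ped.id, ped.herd))
        calves = ped[ped.generation == 1]
        assert all(herd_of[d] == h for d, h in zip(calves.dam, calves.herd))


@pytest.fixture(scope="module")
def small_study(tiny_gmap, small_arch):
    founders = simulate_founders(1200, tiny_gmap, seed=31)
    lay = layout(10, 20, seed=31)
    scenario = BreedingScenario.for_connectedness("weak", 10)
    return run_study_population(scenario, lay, founders, small_arch, seed=32,
                                n_prediction=100)


class TestStudyPopulation:
    def test_training_tbv_scaled_exactly(self, small_study):
        tbv = small_study.phenotyped["tbv"].to_numpy()
        assert tbv.mean() == pytest.approx(0.0, abs=1e-12)
        assert tbv.var() == pytest.approx(0.1, abs=1e-12)

    def test_prediction_cohort_size_and_default(self, tiny_gmap, small_arch,
                                                small_study):
        assert len(small_study.prediction) == 100
        founders = simulate_founders(3000, tiny_gmap, seed=33)
        lay = layout(30, 20, seed=33)
        scenario = BreedingScenario.for_connectedness("weak", 30)
        study = run_study_population(scenario, lay, founders, small_arch,
                                     seed=34)   # default n_prediction
        assert len(study.prediction) == 200

    def test_pedigree_truncated_at_generation_eight(self, small_study):
        ped = small_study.pedigree
        early = ped[ped.generation < 8]
        # only phenotyped animals (retained dams) may predate the cut-off
        assert set(early.id) <= set(small_study.phenotyped.id)
        assert (early[["sire", "dam"]].to_numpy() == 0).all()

    def test_same_seed_reproduces_everything(self, tiny_gmap, small_arch):
        founders = simulate_founders(900, tiny_gmap, seed=35)
        lay = layout(8, 15, seed=35)
        scenario = BreedingScenario.for_connectedness("intermediate", 8)
        a = run_study_population(scenario, lay, founders, small_arch, seed=36,
                                 n_prediction=50)
        b = run_study_population(scenario, lay, founders, small_arch, seed=36,
                                 n_prediction=50)
        pd.testing.assert_frame_equal(a.pedigree, b.pedigree)
        pd.testing.assert_frame_equal(a.phenotyped, b.phenotyped)
        np.testing.assert_array_equal(a.snp_dosages, b.snp_dosages)


def test_connectedness_controls_relationship_structure(tiny_gmap, small_arch):
    """Weak mating keeps relatedness within villages; strong AI spreads it."""
    within, between = {}, {}
    for connectedness in ("weak", "strong"):
        founders = simulate_founders(1200, tiny_gmap, seed=41)
        lay = layout(10, 20, seed=41)
        scenario = BreedingScenario.for_connectedness(connectedness, 10)
        study = run_study_population(scenario, lay, founders, small_arch,
                                     seed=42, n_prediction=50)
        A = pedigree_A(study.pedigree)
        ids = study.phenotyped["id"].to_numpy()
        idx = A.index_of(ids)
        sub = A.matrix[np.ix_(idx, idx)]
        village = lay.herd_to_village[study.phenotyped["herd"].to_numpy() - 1]
        same = village[:, None] == village[None, :]
        off = ~np.eye(len(ids), dtype=bool)
        within[connectedness] = sub[same & off].mean()
        between[connectedness] = sub[~same].mean()
    # formulated multiplicatively: between-village relatedness can be ~0
    assert within["weak"] > 3 * between["weak"]
    assert within["strong"] < 1.3 * between["strong"]
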