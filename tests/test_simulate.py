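import numpy as np
import pandas as pd
import pytest

import keycontrib as kc
from keycontrib.simulate import UNKNOWN_PARENT, check_pedigree

from conftest import SMALL_DESIGN


class TestPedigree:
    def test_study_design_counts(self):
        ped = kc.simulate_pedigree(5, seed=0)
        assert len(ped) == 5100
        by_gen = ped.groupby(["generation", "sex"]).size().unstack()
        for g in range(5):
            assert by_gen.loc[g, "M"] == 20
            assert by_gen.loc[g, "F"] == 1000
        check_pedigree(ped)

    def test_single_generation_is_founders_only(self):
        ped = kc.simulate_pedigree(1, seed=3)
        assert len(ped) == 1020
        assert (ped["sire"] == UNKNOWN_PARENT).all()
        assert (ped["dam"] == UNKNOWN_PARENT).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_offspring_generation_size(self, seed):
        # 1,000 dams leave one female; 20 of them an extra male: 1,020 offspring
        ped = kc.simulate_pedigree(2, seed=seed)
        offspring = ped[ped["generation"] == 1]
        assert len(offspring) == 1020
        assert (offspring["sex"] == "M").sum() == 20

    def test_every_sire_mates_fifty_dams(self):
        ped = kc.simulate_pedigree(2, seed=5)
        offspring = ped[ped["generation"] == 1]
        dams_per_sire = offspring.groupby("sire")["dam"].nunique()
        assert len(dams_per_sire) == 20
        assert (dams_per_sire == 50).all()

    def test_rejects_inconsistent_design(self):
        with pytest.raises(ValueError):
            kc.SimDesign(n_males=3, n_females=100, dams_per_sire=50)


class TestFounderHaplotypes:
    def test_constant_half_frequency(self):
        smap = kc.snp_map(kc.SimDesign(n_chromosomes=1, snps_per_chrom=1))
        alleles, _ = kc.simulate_founder_haplotypes(smap, 1020, seed=0, maf_range=(0.5, 0.5))
        freq = alleles.mean()
        # binomial s.e. sqrt(0.25 / 2040) ~ 0.011
        assert abs(freq - 0.5) < 4 * 0.011

    def test_degenerate_frequency_rejected(self):
        smap = kc.snp_map(SMALL_DESIGN)
        with pytest.raises(ValueError):
            kc.simulate_founder_haplotypes(smap, 10, seed=0, maf_range=(0.0, 0.0))

    def test_study_scale_dimensions(self):
        smap = kc.snp_map(kc.SimDesign())
        assert len(smap) == 10_000
        alleles, freqs = kc.simulate_founder_haplotypes(smap, 1020, seed=1)
        assert alleles.shape == (2040, 10_000)
        assert freqs.min() >= 0.05 and freqs.max() <= 0.95


class TestGeneDrop:
    def test_child_of_founders_carries_parent_labels(self, small_pop):
        ped = small_pop.pedigree
        child = ped[ped["generation"] == 1].iloc[0]
        index = {x: i for i, x in enumerate(small_pop.ancestry.ids)}
        for hap, parent in ((0, child["sire"]), (1, child["dam"])):
            parent_labels = set()
            for c in range(SMALL_DESIGN.n_chromosomes):
                for h in (0, 1):
                    parent_labels |= set(small_pop.ancestry.tracks[index[parent]][h][c][1])
            for c in range(SMALL_DESIGN.n_chromosomes):
                child_labels = set(small_pop.ancestry.tracks[index[child["id"]]][hap][c][1])
                assert child_labels <= parent_labels

    def test_tracks_tile_chromosomes(self, small_pop):
        anc = small_pop.ancestry
        for i in range(0, anc.n_individuals, 37):
            for h in (0, 1):
                for c, length in enumerate(anc.chrom_lengths):
                    ends, labels = anc.tracks[i][h][c]
                    assert ends[-1] == length
                    assert np.all(np.diff(ends) > 0)
                    assert len(ends) == len(labels)
                    # consecutive segments come from different founder haplotypes
                    assert np.all(np.diff(labels) != 0)

    def test_mean_crossovers_per_morgan(self):
        # one founder couple, many offspring, one 1-Morgan chromosome; with
        # two distinct source haplotypes every crossover starts a new segment,
        # so segments - 1 counts crossovers: mean must approach Poisson(1).
        design = kc.SimDesign(
            n_males=1, n_females=1, dams_per_sire=1, two_offspring_dams=0,
            n_chromosomes=1, chrom_length_bp=100_000_000, snps_per_chrom=10,
        )
        rows = [
            {"id": "sire", "sire": UNKNOWN_PARENT, "dam": UNKNOWN_PARENT, "sex": "M", "generation": 0},
            {"id": "dam", "sire": UNKNOWN_PARENT, "dam": UNKNOWN_PARENT, "sex": "F", "generation": 0},
        ]
        n_gametes = 6000
        for i in range(n_gametes // 2):
            rows.append({"id": f"c{i}", "sire": "sire", "dam": "dam", "sex": "F", "generation": 1})
        ped = pd.DataFrame(rows)
        anc = kc.drop_ancestry(ped, seed=42, design=design)
        counts = [
            len(anc.tracks[i][h][0][0]) - 1
            for i in range(2, anc.n_individuals)
            for h in (0, 1)
        ]
        assert abs(np.mean(counts) - 1.0) < 4 / np.sqrt(n_gametes)

    def test_full_design_dimensions(self, study_pop):
        assert len(study_pop.pedigree) == 5100
        assert study_pop.ancestry.n_individuals == 5100
        assert len(study_pop.snp_map) == 10_000


class TestTrueIbd:
    def test_founders_unrelated_and_diagonal_one(self, small_exact_G, small_pop):
        founders = small_pop.ids_of(generations=[0])
        sub = small_exact_G.subset(founders)
        off = sub.values[~np.eye(sub.n, dtype=bool)]
        assert np.allclose(off, 0.0)
        assert np.allclose(np.diag(sub.values), 1.0)

    def test_symmetry_and_range(self, small_exact_G):
        v = small_exact_G.values
        assert np.allclose(v, v.T)
        off = v[~np.eye(v.shape[0], dtype=bool)]
        assert off.min() >= 0.0 and off.max() <= 1.0

    def test_duplicated_individual_shares_everything(self, small_pop):
        anc = small_pop.ancestry
        dup = kc.AncestryTracks(
            ids=["a", "a_copy"],
            chrom_lengths=anc.chrom_lengths,
            tracks=[anc.tracks[0], anc.tracks[0]],
        )
        G = kc.true_ibd_matrix(dup)
        assert G.values[0, 1] == pytest.approx(1.0)

    def test_parent_offspring_entry_is_one(self, small_pop, small_exact_G):
        # the transmitted gamete matches one parental haplotype everywhere,
        # so under union counting every parent-offspring pair shares 1.0
        ped = small_pop.pedigree
        index = {x: i for i, x in enumerate(small_exact_G.ids)}
        children = ped[ped["generation"] == 1].head(100)
        for row in children.itertuples(index=False):
            assert small_exact_G.values[index[row.id], index[row.sire]] == pytest.approx(1.0)
            assert small_exact_G.values[index[row.id], index[row.dam]] == pytest.approx(1.0)

    def test_full_sib_sharing_three_quarters(self):
        # sire-side and dam-side sharing are each 1/2 and independent:
        # union expectation 1 - 1/4 = 3/4; Monte Carlo over 200 sib pairs
        rows = []
        pairs = []
        for fam in range(200):
            rows += [
                (f"s{fam}", UNKNOWN_PARENT, UNKNOWN_PARENT, "M", 0),
                (f"d{fam}", UNKNOWN_PARENT, UNKNOWN_PARENT, "F", 0),
                (f"a{fam}", f"s{fam}", f"d{fam}", "M", 1),
                (f"b{fam}", f"s{fam}", f"d{fam}", "F", 1),
            ]
            pairs.append((f"a{fam}", f"b{fam}"))
        ped = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation"])
        design = kc.SimDesign(
            n_males=1, n_females=1, dams_per_sire=1, two_offspring_dams=0,
            n_chromosomes=5, chrom_length_bp=100_000_000, snps_per_chrom=10,
        )
        anc = kc.drop_ancestry(ped, seed=77, design=design)
        G = kc.true_ibd_matrix(anc, grid_points_per_chrom=50)
        index = {x: i for i, x in enumerate(G.ids)}
        values = [G.values[index[a], index[b]] for a, b in pairs]
        assert abs(np.mean(values) - 0.75) < 0.05

    def test_grid_matches_exact(self, small_pop, small_exact_G):
        grid = kc.true_ibd_matrix(small_pop.ancestry, grid_points_per_chrom=100)
        assert np.abs(grid.values - small_exact_G.values).max() < 0.05


class TestSubstreamReproducibility:
    def test_same_seed_same_population(self):
        a = kc.simulate_population(2, seed=9, design=SMALL_DESIGN)
        b = kc.simulate_population(2, seed=9, design=SMALL_DESIGN)
        assert a.pedigree.equals(b.pedigree)
        assert np.array_equal(a.haplotypes.alleles, b.haplotypes.alleles)

    def test_alleles_do_not_disturb_ancestry(self):
        a = kc.simulate_population(2, seed=9, design=SMALL_DESIGN, with_alleles=False)
        b = kc.simulate_population(2, seed=9, design=SMALL_DESIGN, with_alleles=True)
        ga = kc.true_ibd_matrix(a.ancestry, grid_points_per_chrom=20)
        gb = kc.true_ibd_matrix(b.ancestry, grid_points_per_chrom=20)
        assert np.array_equal(ga.values, gb.values)
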