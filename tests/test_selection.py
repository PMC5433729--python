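import itertools

import numpy as np
import pandas as pd
import pytest

import keycontrib as kc
from keycontrib.selection import captured_variance

from conftest import random_psd


def _ped(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation"])


class TestSelectCon:
    def test_top_k_equals_key_contributors(self):
        rng = np.random.default_rng(0)
        G = random_psd(rng, 12)
        scores = kc.contribution_scores(G, k=4)
        sel = kc.select_con(scores, 4)
        assert sel.selected == scores.key_contributors

    def test_seven_sire_design(self):
        # sheep-like design: 7 founder sires with unequal progeny group sizes
        rows = [(f"sire{i}", "0", "0", "M", 0) for i in range(7)]
        rows += [(f"dam{i}", "0", "0", "F", 0) for i in range(70)]
        sizes = [20, 14, 12, 9, 7, 5, 3]
        d = 0
        for s, size in enumerate(sizes):
            for _ in range(size):
                rows.append((f"off{d}", f"sire{s}", f"dam{d}", "F", 1))
                d += 1
        ped = _ped(rows)
        anc = kc.drop_ancestry(ped, seed=4, design=kc.SimDesign(
            n_males=7, n_females=70, dams_per_sire=10, two_offspring_dams=0,
            n_chromosomes=3, chrom_length_bp=100_000_000, snps_per_chrom=100,
        ))
        G = kc.true_ibd_matrix(anc, grid_points_per_chrom=100)
        keep = [x for x in G.ids if not x.startswith("dam")]
        G = G.subset(keep)
        scores = kc.contribution_scores(G, k=7)
        assert set(kc.select_con(scores, 7).selected) == {f"sire{i}" for i in range(7)}

    def test_n_too_large(self):
        rng = np.random.default_rng(1)
        scores = kc.contribution_scores(random_psd(rng, 5), k=2)
        with pytest.raises(ValueError):
            kc.select_con(scores, 6)


class TestSelectRel:
    def test_single_pick_matches_brute_force(self):
        rng = np.random.default_rng(2)
        G = random_psd(rng, 10)
        sel = kc.select_rel(G, 1)
        best = max(G.ids, key=lambda c: captured_variance(G, [c]))
        assert sel.selected == [best]

    def test_pair_matches_exhaustive_search(self):
        # family-structured toys: greedy coincides with the exhaustive optimum
        rng = np.random.default_rng(3)
        for _ in range(5):
            v = np.eye(6)
            for fam in ([0, 1, 2], [3, 4]):
                for i in fam:
                    for j in fam:
                        if i != j:
                            v[i, j] = 0.5
            noise = 0.02 * rng.standard_normal((6, 6))
            v = v + (noise + noise.T) / 2
            np.fill_diagonal(v, np.diag(v) + 0.1)
            G = kc.RelationshipMatrix(v, [f"i{j}" for j in range(6)])
            sel = kc.select_rel(G, 2)
            best_pair = max(
                itertools.combinations(G.ids, 2),
                key=lambda pair: captured_variance(G, list(pair)),
            )
            assert set(sel.selected) == set(best_pair)

    def test_duplicate_is_never_selected_next(self):
        rng = np.random.default_rng(4)
        base = random_psd(rng, 6).values
        v = base.copy()
        v[5] = v[4]
        v[:, 5] = v[:, 4]
        v[5, 5] = v[4, 4]
        G = kc.RelationshipMatrix(v, [f"i{j}" for j in range(6)])
        sel = kc.select_rel(G, 3)
        assert not {"i4", "i5"} <= set(sel.selected)

    def test_objective_nondecreasing(self):
        rng = np.random.default_rng(5)
        G = random_psd(rng, 15)
        sel = kc.select_rel(G, 8)
        assert (np.diff(sel.scores) >= -1e-10).all()


class TestSelectPed:
    def test_single_sire_first_with_half(self):
        rows = [("s", "0", "0", "M", 0)]
        rows += [(f"d{i}", "0", "0", "F", 0) for i in range(6)]
        rows += [(f"c{i}", "s", f"d{i}", "F", 1) for i in range(6)]
        ped = _ped(rows)
        sel = kc.select_ped(ped, [f"c{i}" for i in range(6)], 1)
        assert sel.selected == ["s"]
        assert sel.scores[0] == pytest.approx(0.5)

    def test_sixty_forty_order(self):
        rows = [("s1", "0", "0", "M", 0), ("s2", "0", "0", "M", 0)]
        rows += [(f"d{i}", "0", "0", "F", 0) for i in range(10)]
        for i in range(10):
            sire = "s1" if i < 6 else "s2"
            rows.append((f"c{i}", sire, f"d{i}", "F", 1))
        ped = _ped(rows)
        sel = kc.select_ped(ped, [f"c{i}" for i in range(10)], 2)
        assert sel.selected == ["s1", "s2"]
        assert sel.scores[0] == pytest.approx(0.3)
        assert sel.scores[1] == pytest.approx(0.2)

    def test_marginal_contributions_partition(self):
        rows = [("s", "0", "0", "M", 0), ("d", "0", "0", "F", 0)]
        rows += [(f"c{i}", "s", "d", "F", 1) for i in range(4)]
        ped = _ped(rows)
        sel = kc.select_ped(ped, [f"c{i}" for i in range(4)], 6)
        assert (sel.scores >= -1e-12).all()
        assert sel.scores.sum() <= 1.0 + 1e-9

    def test_unknown_reference_raises(self):
        ped = _ped([("a", "0", "0", "M", 0)])
        with pytest.raises(KeyError):
            kc.select_ped(ped, ["zzz"], 1)


class TestSelectRandom:
    def test_seed_reproducible(self):
        ids = [f"i{j}" for j in range(30)]
        assert kc.select_random(ids, 5, seed=7).selected == kc.select_random(ids, 5, seed=7).selected

    def test_all_ids(self):
        ids = list("abcde")
        assert sorted(kc.select_random(ids, 5, seed=0).selected) == ids

    def test_uniform_inclusion_frequency(self):
        ids = [f"i{j}" for j in range(100)]
        rng = np.random.default_rng(8)
        hits = 0
        draws = 10_000
        for _ in range(draws):
            hits += "i13" in kc.select_random(ids, 10, rng).selected
        assert abs(hits / draws - 0.10) < 0.01


class TestOverlapReport:
    def test_identical_sets(self):
        a = kc.SelectionResult("Con", list("abc"), np.zeros(3), 3)
        b = kc.SelectionResult("Ped", list("abc"), np.zeros(3), 3)
        rep = kc.overlap_report([a, b])
        full = rep[(rep["Con"]) & (rep["Ped"])]["count"].iloc[0]
        assert full == 3
        assert rep["count"].sum() == 3

    def test_disjoint_sets(self):
        a = kc.SelectionResult("Con", list("abc"), np.zeros(3), 3)
        b = kc.SelectionResult("Ran", list("xyz"), np.zeros(3), 3)
        rep = kc.overlap_report([a, b])
        assert rep[(rep["Con"]) & (rep["Ran"])]["count"].iloc[0] == 0

    def test_three_way_hand_enumeration(self):
        a = kc.SelectionResult("Con", list("abcde"), np.zeros(5), 5)
        b = kc.SelectionResult("Ped", list("cdefg"), np.zeros(5), 5)
        c = kc.SelectionResult("Rel", list("efghi"), np.zeros(5), 5)
        rep = kc.overlap_report([a, b, c]).set_index(["Con", "Ped", "Rel"])["count"]
        assert rep.loc[(True, True, True)] == 1   # {e}
        assert rep.loc[(True, True, False)] == 2  # {c, d}
        assert rep.loc[(False, True, True)] == 2  # {f, g}
        assert rep.loc[(True, False, False)] == 2  # {a, b}
        assert rep.loc[(False, False, True)] == 2  # {h, i}
        assert rep.loc[(False, True, False)] == 0
        assert rep.loc[(True, False, True)] == 0

    def test_one_founder_star_pedigree_all_strategies_agree(self, small_pop):
        # collapse design: a single sire fathering every reference individual
        rows = [("s", "0", "0", "M", 0)]
        rows += [(f"d{i}", "0", "0", "F", 0) for i in range(8)]
        rows += [(f"c{i}", "s", f"d{i}", "F", 1) for i in range(8)]
        ped = _ped(rows)
        anc = kc.drop_ancestry(ped, seed=1, design=kc.SimDesign(
            n_males=1, n_females=8, dams_per_sire=8, two_offspring_dams=0,
            n_chromosomes=2, chrom_length_bp=100_000_000, snps_per_chrom=100,
        ))
        G = kc.true_ibd_matrix(anc, grid_points_per_chrom=50)
        scores = kc.contribution_scores(G, k=1)
        con = kc.select_con(scores, 1).selected
        rel = kc.select_rel(G, 1).selected
        peds = kc.select_ped(ped, list(G.ids), 1).selected
        assert con == rel == peds == ["s"]
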