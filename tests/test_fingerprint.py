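"""Candidate filtering and minimal discriminating SNP-panel selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from germcore import fingerprint as fp
from germcore import genotype_matrix as gm
from tests.conftest import make_matrix

# Frozen instance: 6 accessions x 8 candidate loci whose unique minimum
# discriminating subset is {l0, l2, l7} (verified by exhaustive search).
UNIQUE_MIN3 = np.array([
    [2, 2, 1, 1, 1, 1, 0, 1],
    [2, 1, 0, 1, 1, 2, 0, 0],
    [1, 2, 1, 1, 1, 1, 0, 0],
    [2, 1, 2, 0, 1, 2, 1, 0],
    [0, 1, 1, 0, 0, 2, 0, 1],
    [2, 2, 1, 1, 1, 1, 0, 0],
], dtype=np.int8)


def random_instance(rng, n=10, n_cand=12):
    while True:
        dos = rng.integers(0, 3, (n, n_cand)).astype(np.int8)
        if len(np.unique(dos, axis=0)) == n:
            return make_matrix(dos)


class TestCandidateFilter:
    def test_single_missing_call_excludes_locus(self):
        m = make_matrix([[0, 0], [1, 1], [2, -1], [1, 1], [0, 0],
                         [2, 2], [1, 1], [0, 0], [2, 2], [1, 1]])
        assert fp.candidate_filter(m) == ["l0"]

    def test_maf_exactly_at_threshold_retained(self):
        dos = np.zeros((10, 1), dtype=np.int8)
        dos[0] = 1  # MAF = 0.05
        assert fp.candidate_filter(make_matrix(dos)) == ["l0"]

    def test_non_snp_loci_excluded(self):
        m = make_matrix([[0, 0], [1, 1], [2, 2], [1, 1]],
                        is_snp=[True, False])
        assert fp.candidate_filter(m) == ["l0"]

    def test_matches_column_scan_on_generator_output(self, small_panel):
        got = set(fp.candidate_filter(small_panel))
        expect = set()
        dos = small_panel.dosages
        for j, lid in enumerate(small_panel.loci.index):
            col = dos[:, j]
            if (col == gm.MISSING).any():
                continue
            if not small_panel.loci.iloc[j]["is_snp"]:
                continue
            p = col.sum() / (2 * len(col))
            if min(p, 1 - p) >= 0.05:
                expect.add(lid)
        assert got == expect

    def test_empty_candidate_set_is_an_error(self):
        m = make_matrix([[-1], [0], [1]])
        with pytest.raises(ValueError, match="candidate"):
            fp.candidate_filter(m)


class TestResolvedPairs:
    def test_all_candidates_resolve_distinct_accessions(self, small_panel):
        full_loci = list(small_panel.loci.index)
        count, total = fp.resolved_pairs(small_panel, full_loci)
        n = small_panel.n_samples
        assert count == total == n * (n - 1) // 2

    def test_uniform_heterozygous_locus_resolves_nothing(self):
        m = make_matrix(np.ones((6, 1)))
        assert fp.resolved_pairs(m, ["l0"]) == (0, 15)

    def test_matches_double_loop_brute_force(self):
        rng = np.random.default_rng(23)
        m = random_instance(rng, n=10, n_cand=30)
        loci = list(m.loci.index)
        for _ in range(10):
            subset = [loci[i] for i in
                      rng.choice(30, rng.integers(1, 10), replace=False)]
            sub = m.take_loci(subset)
            expect = sum(
                1 for i, j in itertools.combinations(range(10), 2)
                if (sub.dosages[i] != sub.dosages[j]).any())
            assert fp.resolved_pairs(m, subset)[0] == expect


class TestExhaustiveMin:
    def test_finds_unique_size3_optimum(self):
        m = make_matrix(UNIQUE_MIN3)
        panel = fp.exhaustive_min(m, list(m.loci.index))
        assert panel.loci == ["l0", "l2", "l7"]
        assert panel.resolved_fraction == 1.0

    def test_size_one_solution_returned_directly(self):
        m = make_matrix([[0, 1], [1, 1], [2, 1]])
        panel = fp.exhaustive_min(m, list(m.loci.index))
        assert panel.loci == ["l0"]

    def test_never_larger_than_greedy(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            m = random_instance(rng, n=8, n_cand=10)
            cands = list(m.loci.index)
            ex = fp.exhaustive_min(m, cands)
            gr = fp.greedy_select(m, cands)
            assert len(ex.loci) <= len(gr.loci)

    def test_no_solution_raises_not_loops(self):
        dos = np.array([[0, 1, 2], [0, 1, 2], [1, 0, 2]], dtype=np.int8)
        m = make_matrix(dos)
        with pytest.raises(fp.UnresolvableAccessionsError) as exc:
            fp.exhaustive_min(m, list(m.loci.index))
        assert ("s0", "s1") in exc.value.pairs

    def test_guard_on_candidate_count(self):
        rng = np.random.default_rng(1)
        m = random_instance(rng, n=5, n_cand=25)
        with pytest.raises(ValueError, match="guard"):
            fp.exhaustive_min(m, list(m.loci.index))


class TestGreedySelect:
    def test_always_valid_when_solution_exists(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = random_instance(rng)
            panel = fp.greedy_select(m, list(m.loci.index))
            assert panel.resolved_fraction == 1.0
            codes = list(panel.codes.values())
            assert len(set(codes)) == len(codes)

    def test_set_cover_logarithmic_bound(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            m = random_instance(rng, n=10, n_cand=12)
            cands = list(m.loci.index)
            gr = fp.greedy_select(m, cands)
            ex = fp.exhaustive_min(m, cands)
            n_pairs = 45
            assert len(gr.loci) <= len(ex.loci) * (1 + math.log(n_pairs))

    def test_frozen_instance_within_one_of_optimum(self):
        m = make_matrix(UNIQUE_MIN3)
        panel = fp.greedy_select(m, list(m.loci.index))
        assert panel.resolved_fraction == 1.0
        assert len(panel.loci) in (3, 4)


class TestGaSelect:
    def test_two_accessions_need_one_locus(self):
        m = make_matrix([[0, 1, 1], [0, 2, 1]])
        panel = fp.ga_select(m, list(m.loci.index))
        assert len(panel.loci) == 1
        assert panel.resolved_fraction == 1.0

    def test_recovers_unique_minimum_across_seeds(self):
        m = make_matrix(UNIQUE_MIN3)
        cands = list(m.loci.index)
        sizes = []
        for seed in range(15):
            panel = fp.ga_select(m, cands, fp.GaParams(seed=seed))
            assert panel.resolved_fraction == 1.0
            sizes.append(len(panel.loci))
        assert sizes.count(3) >= 14

    def test_seeded_bit_reproducibility(self):
        rng = np.random.default_rng(77)
        m = random_instance(rng, n=12, n_cand=20)
        cands = list(m.loci.index)
        p1 = fp.ga_select(m, cands, fp.GaParams(seed=5))
        p2 = fp.ga_select(m, cands, fp.GaParams(seed=5))
        assert p1.loci == p2.loci
        assert p1.ga_generations == p2.ga_generations

    def test_pruned_panel_has_no_redundant_locus(self):
        rng = np.random.default_rng(19)
        m = random_instance(rng, n=12, n_cand=25)
        cands = list(m.loci.index)
        panel = fp.ga_select(m, cands, fp.GaParams(seed=0))
        for drop in panel.loci:
            rest = [l for l in panel.loci if l != drop]
            count, total = fp.resolved_pairs(m, rest)
            assert count < total  # every locus is load-bearing

    def test_no_solution_reports_closest_pairs(self):
        dos = np.array([[0, 1], [0, 1], [2, 0]], dtype=np.int8)
        with pytest.raises(fp.UnresolvableAccessionsError):
            fp.ga_select(make_matrix(dos), ["l0", "l1"])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="population_size"):
            fp.GaParams(population_size=1)
        with pytest.raises(ValueError, match="crossover"):
            fp.GaParams(crossover_rate=1.5)


class TestFingerprintTable:
    def test_homozygote_codes(self):
        m = make_matrix([[0], [2]])
        panel = fp.greedy_select(m, ["l0"])
        assert panel.codes == {"s0": "A", "s1": "B"}

    def test_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        m = random_instance(rng)
        panel = fp.greedy_select(m, list(m.loci.index))
        table = fp.fingerprint_table(m, panel)
        path = tmp_path / "fp.tsv"
        table.to_csv(path, sep="\t", index_label="locus_id")
        again = pd.read_csv(path, sep="\t", index_col=0)
        assert again.equals(table)
        # decode letters back to dosages
        decode = {"A": 0, "H": 1, "B": 2}
        sub = m.take_loci(panel.loci)
        for i, s in enumerate(m.sample_ids):
            assert [decode[c] for c in again[s]] == sub.dosages[i].tolist()

    def test_unknown_panel_loci_rejected(self):
        m = make_matrix([[0], [2]])
        panel = fp.greedy_select(m, ["l0"])
        panel.loci = ["does_not_exist"]
        with pytest.raises(KeyError):
            fp.fingerprint_table(m, panel)
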