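"""Signature scanning, alignment statistics, NJ trees and grouping."""

import math

import numpy as np
import pytest

from cypmine import (
    AlignmentBlock, DistanceMatrix, ProteinRecord, SignatureProfile,
    assign_groups, bootstrap_support, column_conservation, filter_candidates,
    identity_matrix, nj_tree, protein_distances, random_tree, scan_signatures,
    simulate_alignment_on_tree, tree_distance_matrix,
)
from cypmine.family_mining import DEFAULT_PROFILES
from cypmine.io_core import AMINO_ACIDS


def brute_force_scan(seq: str, profile: SignatureProfile) -> list[int]:
    """Independent sliding-window matcher used as the oracle."""
    pos = profile.positions()
    return [i for i in range(len(seq) - len(pos) + 1)
            if all(seq[i + j] in pos[j] for j in range(len(pos)))]


class TestScanSignatures:
    def test_heme_hit_at_literal_match(self):
        p = ProteinRecord("p", "MMM" + "FSAGRRICLG" + "MMM")
        hits = scan_signatures(p)
        assert hits["heme"] == [3]

    def test_perf_matches_both_f_and_w(self):
        assert scan_signatures(ProteinRecord("p", "AAPERWAA"))["perf"] == [2]
        assert scan_signatures(ProteinRecord("p", "AAPERFAA"))["perf"] == [2]
        assert scan_signatures(ProteinRecord("p", "AAPERYAA"))["perf"] == []

    def test_i_helix_first_position_a_or_g(self):
        assert scan_signatures(ProteinRecord("p", "MAGMDTM"))["i_helix"] == [1]
        assert scan_signatures(ProteinRecord("p", "MGGMDTM"))["i_helix"] == [1]
        assert scan_signatures(ProteinRecord("p", "MCGMDTM"))["i_helix"] == []

    def test_gapped_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_signatures(ProteinRecord("p", "AC-DE"))

    @pytest.mark.parametrize("profile", DEFAULT_PROFILES,
                             ids=[p.name for p in DEFAULT_PROFILES])
    def test_matches_brute_force_on_long_random_sequence(self, rng, profile):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=10_000))
        p = ProteinRecord("p", seq)
        assert scan_signatures(p, (profile,))[profile.name] == \
            brute_force_scan(seq, profile)


def protein_with_all_motifs(length: int, rng) -> str:
    seq = list(rng.choice(list(AMINO_ACIDS), size=length))
    for i, motif in enumerate(["FSAGRRICLG", "AGMDT", "EAAR", "PERF"]):
        start = 20 + 40 * i
        seq[start:start + len(motif)] = list(motif)
    return "".join(seq)


class TestFilterCandidates:
    def test_typical_full_length_protein_passes(self, rng):
        p = ProteinRecord("p1", protein_with_all_motifs(505, rng))
        (call,) = filter_candidates([p])
        assert call.passed and call.length == 505

    def test_short_protein_fails_on_length(self, rng):
        p = ProteinRecord("p1", protein_with_all_motifs(300, rng))
        (call,) = filter_candidates([p])
        assert not call.passed and "length" in call.fail_reasons

    def test_missing_motif_reported(self, rng):
        seq = protein_with_all_motifs(500, rng).replace("PERF", "PAAA")
        (call,) = filter_candidates([ProteinRecord("p1", seq)])
        assert not call.passed and "missing_perf" in call.fail_reasons

    def test_exact_duplicates_collapsed(self, rng):
        seq = protein_with_all_motifs(480, rng)
        calls = filter_candidates([ProteinRecord("a", seq),
                                   ProteinRecord("b", seq)])
        assert len(calls) == 1 and calls[0].duplicates == ["b"]

    def test_empty_input_gives_empty_output(self):
        assert filter_candidates([]) == []

    def test_confusion_matrix_diagonal_on_synthetic_truth(self, small_config):
        from cypmine import simulate_protein_set

        proteins, truth = simulate_protein_set(small_config)
        calls = {c.protein_id: c.passed for c in filter_candidates(proteins)}
        for row in truth.itertuples():
            assert calls[row.protein_id] == row.is_family


class TestIdentityMatrix:
    def test_identical_pair_is_100(self):
        aln = AlignmentBlock([ProteinRecord("a", "ACDEF"),
                              ProteinRecord("b", "ACDEF")])
        assert identity_matrix(aln).get("a", "b") == 100.0

    def test_three_of_four_is_75(self):
        aln = AlignmentBlock([ProteinRecord("a", "AAAA"),
                              ProteinRecord("b", "AAAT")])
        assert identity_matrix(aln).get("a", "b") == 75.0

    def test_gap_columns_excluded(self):
        aln = AlignmentBlock([ProteinRecord("a", "A-CD"),
                              ProteinRecord("b", "AAC-")])
        # comparable columns: 1 and 3 (0-based 0 and 2), both matches
        assert identity_matrix(aln).get("a", "b") == 100.0

    def test_no_comparable_columns_flagged(self):
        aln = AlignmentBlock([ProteinRecord("a", "AA--"),
                              ProteinRecord("b", "--CC")])
        m = identity_matrix(aln)
        assert ("a", "b") in m.undefined
        assert np.isnan(m.get("a", "b"))

    def test_matches_brute_force_counting(self, rng):
        rows = ["".join(rng.choice(list(AMINO_ACIDS + "-"), size=60))
                for _ in range(5)]
        aln = AlignmentBlock([ProteinRecord(f"p{i}", s)
                              for i, s in enumerate(rows)])
        m = identity_matrix(aln)
        for i in range(5):
            for j in range(i + 1, 5):
                pairs = [(a, b) for a, b in zip(rows[i], rows[j])
                         if a != "-" and b != "-"]
                expected = 100.0 * sum(a == b for a, b in pairs) / len(pairs)
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identity_equals_100_times_one_minus_p_distance_when_gap_free(self, rng):
        rows = ["".join(rng.choice(list(AMINO_ACIDS), size=50))
                for _ in range(4)]
        aln = AlignmentBlock([ProteinRecord(f"p{i}", s)
                              for i, s in enumerate(rows)])
        ident = identity_matrix(aln).values
        p = protein_distances(aln, "p_distance").values
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(ident[off], 100.0 * (1.0 - p[off]))


class TestColumnConservation:
    def test_invariant_column_is_log2_20_bits(self):
        aln = AlignmentBlock([ProteinRecord(f"p{i}", "W") for i in range(5)])
        (freqs, info), = column_conservation(aln)
        assert freqs == {"W": 1.0}
        assert info == pytest.approx(math.log2(20), abs=1e-12)

    def test_uniform_column_is_zero_bits(self):
        aln = AlignmentBlock([ProteinRecord(f"p{i}", aa)
                              for i, aa in enumerate(AMINO_ACIDS)])
        (_, info), = column_conservation(aln)
        assert info == pytest.approx(0.0, abs=1e-12)

    def test_all_gap_column_flagged_none(self):
        aln = AlignmentBlock([ProteinRecord("a", "A-"),
                              ProteinRecord("b", "C-")])
        assert column_conservation(aln)[1] == ({}, None)

    def test_matches_direct_entropy_formula(self, rng):
        col = rng.choice(list(AMINO_ACIDS), size=30)
        aln = AlignmentBlock([ProteinRecord(f"p{i}", c)
                              for i, c in enumerate(col)])
        (freqs, info), = column_conservation(aln)
        h = -sum((list(col).count(a) / 30) * math.log2(list(col).count(a) / 30)
                 for a in set(col))
        assert info == pytest.approx(math.log2(20) - h, abs=1e-12)
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)


class TestProteinDistances:
    def test_identical_pair_zero_under_both_models(self):
        aln = AlignmentBlock([ProteinRecord("a", "ACDEF"),
                              ProteinRecord("b", "ACDEF")])
        assert protein_distances(aln, "p_distance").get("a", "b") == 0.0
        assert protein_distances(aln, "poisson").get("a", "b") == 0.0

    def test_poisson_at_half_is_ln2(self):
        aln = AlignmentBlock([ProteinRecord("a", "AACC"),
                              ProteinRecord("b", "AAGG")])
        assert protein_distances(aln, "poisson").get("a", "b") == \
            pytest.approx(math.log(2), abs=1e-12)

    def test_saturated_poisson_flagged_infinite(self):
        aln = AlignmentBlock([ProteinRecord("a", "AAAA"),
                              ProteinRecord("b", "CCCC")])
        m = protein_distances(aln, "poisson")
        assert math.isinf(m.get("a", "b"))
        assert ("a", "b") in m.undefined

    def test_p_distance_matches_closed_form_expectation(self):
        # two leaves at branch lengths t1, t2: under the uniform-target
        # substitution model the chance both ends agree is
        # 1/20 + (19/20) * prod_b (20 exp(-t_b) - 1)/19, so
        # E[p] = (19/20) (1 - lambda); check the simulation within 3 sigma
        from cypmine import Tree, TreeNode

        t1, t2 = 0.3, 0.5
        tree = Tree(TreeNode(children=[
            TreeNode(label="A", length=t1), TreeNode(label="B", length=t2),
            TreeNode(label="C", length=0.1)]))
        L = 20_000
        aln = simulate_alignment_on_tree(tree, L, seed=11)
        lam = ((20 * math.exp(-t1) - 1) / 19) * ((20 * math.exp(-t2) - 1) / 19)
        p_exp = (19 / 20) * (1 - lam)
        p_obs = protein_distances(aln, "p_distance").get("A", "B")
        sigma = math.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) <= 3 * sigma


class TestNjTree:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        t = nj_tree(d)
        lengths = {n.label: n.length for n in t.leaves()}
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(int(rng.integers(4, 9)), rng)
        rec = nj_tree(tree_distance_matrix(tree))
        assert rec.bipartitions() == tree.bipartitions()
        pt, pr = tree.path_lengths(), rec.path_lengths()
        assert all(abs(pt[k] - pr[k]) < 1e-9 for k in pt)

    def test_identical_rows_joined_first(self):
        # B and C are indistinguishable: Q is minimal and the tie breaks by
        # label order, so they become siblings
        d = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array([[0, 5, 5, 8], [5, 0, 2, 7], [5, 2, 0, 7],
                      [8, 7, 7, 0]], float))
        t = nj_tree(d)
        # the B|C vs A|D split may be canonicalised from either side
        assert t.bipartitions() & {frozenset({"B", "C"}), frozenset({"A", "D"})}

    def test_infinite_entry_rejected(self):
        vals = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], vals))

    def test_agrees_with_independent_nj_implementation(self, rng):
        # cross-check topology against scikit-bio's neighbor joining
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        tree = random_tree(7, rng)
        aln = simulate_alignment_on_tree(tree, 2000, seed=3)
        d = protein_distances(aln, "p_distance")
        ours = nj_tree(d)
        sk_tree = skbio_nj(SkbioDM(d.values, ids=d.labels))
        from cypmine import read_newick

        theirs = read_newick(str(sk_tree), from_string=True)
        assert ours.bipartitions() == theirs.bipartitions()


class TestBootstrap:
    def _aln(self, rng, length=800):
        tree = random_tree(6, rng)
        return simulate_alignment_on_tree(tree, length, seed=5)

    def _supports(self, tree):
        out = []

        def walk(n):
            if n.support is not None:
                out.append(n.support)
            for c in n.children:
                walk(c)

        walk(tree.root)
        return out

    def test_single_replicate_supports_are_0_or_100(self, rng):
        t = bootstrap_support(self._aln(rng), B=1, seed=0)
        assert set(self._supports(t)) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self, rng):
        aln = self._aln(rng)
        t1 = bootstrap_support(aln, B=25, seed=9)
        t2 = bootstrap_support(aln, B=25, seed=9)
        assert self._supports(t1) == self._supports(t2)

    def test_strong_signal_gives_full_support(self, rng):
        aln = self._aln(rng, length=5000)
        t = bootstrap_support(aln, B=100, seed=1)
        assert all(s >= 99.0 for s in self._supports(t))

    def test_invariant_to_leaf_order_permutation(self, rng):
        aln = self._aln(rng)
        shuffled = AlignmentBlock(list(reversed(aln.records)))
        s1 = sorted(self._supports(bootstrap_support(aln, B=25, seed=4)))
        s2 = sorted(self._supports(bootstrap_support(shuffled, B=25, seed=4)))
        assert s1 == s2


class TestAssignGroups:
    def _matrix(self, pairs, labels):
        n = len(labels)
        vals = np.zeros((n, n))
        for (a, b), v in pairs.items():
            i, j = labels.index(a), labels.index(b)
            vals[i, j] = vals[j, i] = v
        return DistanceMatrix(labels, vals, kind="percent_identity")

    def test_high_identity_pair_shares_family_and_subfamily(self):
        m = self._matrix({("a", "b"): 95.7, ("a", "c"): 20, ("b", "c"): 20},
                         ["a", "b", "c"])
        g = assign_groups(m)
        assert g["a"] == g["b"]
        assert g["a"][0] != g["c"][0]

    def test_low_identity_pair_split_into_families(self):
        m = self._matrix({("a", "b"): 13.7}, ["a", "b"])
        g = assign_groups(m)
        assert g["a"][0] != g["b"][0]

    def test_subfamilies_refine_families_on_random_matrices(self, rng):
        labels = [f"p{i}" for i in range(12)]
        sym = rng.uniform(0, 100, size=(12, 12))
        vals = np.triu(sym, 1)
        vals = vals + vals.T
        g = assign_groups(DistanceMatrix(labels, vals,
                                         kind="percent_identity"))
        by_sub = {}
        for member, (fam, sub) in g.items():
            by_sub.setdefault(sub, set()).add(fam)
        assert all(len(fams) == 1 for fams in by_sub.values())
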