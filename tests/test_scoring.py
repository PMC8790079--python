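"""Alignment scoring, clustering, delta scores: closed forms and oracles."""

from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from maprove.interchange import ProteinVariantRecord
from maprove.scoring import (
    ScoringConfig,
    ScoringError,
    align_score,
    build_supporting_set,
    classify,
    cluster_support_report,
    delta_score,
    gene_level_score,
    greedy_cluster,
    percent_identity,
    select_top_clusters,
    summarize_by_variant_type,
)
from conftest import make_result

B62 = substitution_matrices.load("BLOSUM62")


def oracle_align(a: str, b: str, gap_open: float = 10.0, gap_ext: float = 1.0) -> float:
    """Independent brute-force scorer: recursion over alignment paths.

    Same semantics as the production aligner, derived separately: the shorter
    sequence is consumed end to end, terminal overhangs of the longer are
    free, a gap run of length L costs open + (L-1)*ext, equal lengths align
    globally.
    """
    if len(a) == len(b):
        s, l, free = a, b, False
    elif len(a) < len(b):
        s, l, free = a, b, True
    else:
        s, l, free = b, a, True

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, last: str) -> float:
        if i == len(s):
            if j == len(l):
                return 0.0
            if free:
                return 0.0
            L = len(l) - j
            return -(gap_ext * L if last == "Y" else gap_open + gap_ext * (L - 1))
        if j == len(l):
            L = len(s) - i
            return -(gap_ext * L if last == "X" else gap_open + gap_ext * (L - 1))
        best = float(B62[s[i], l[j]]) + rec(i + 1, j + 1, "M")
        cost_x = gap_ext if last == "X" else gap_open
        best = max(best, -cost_x + rec(i + 1, j, "X"))
        cost_y = gap_ext if last == "Y" else gap_open
        best = max(best, -cost_y + rec(i, j + 1, "Y"))
        return best

    if free:
        return max(rec(0, j0, "S") for j0 in range(len(l) + 1))
    return rec(0, 0, "S")


class TestAlignScore:
    def test_self_score_is_diagonal_sum(self, scoring_config):
        expected = sum(float(B62[c, c]) for c in "MKWLV")  # 5+5+11+4+4
        assert align_score("MKWLV", "MKWLV", scoring_config) == expected == 29.0

    def test_symmetry_on_random_pairs(self, rng, scoring_config):
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(30):
            a = "".join(rng.choice(aa, size=int(rng.integers(3, 15))))
            b = "".join(rng.choice(aa, size=int(rng.integers(3, 15))))
            assert align_score(a, b, scoring_config) == align_score(b, a, scoring_config)

    def test_matches_bruteforce_oracle_small(self, rng, scoring_config):
        # exhaustive path-enumeration oracle on lengths <= 8, 4-letter alphabet
        alphabet = np.array(list("ACDE"))
        pairs = []
        for _ in range(120):
            a = "".join(rng.choice(alphabet, size=int(rng.integers(1, 9))))
            b = "".join(rng.choice(alphabet, size=int(rng.integers(1, 9))))
            pairs.append((a, b))
        pairs += [("A", "A"), ("A", "C"), ("AC", "A"), ("ACDE", "AE"), ("AA", "AAAA")]
        for a, b in pairs:
            got = align_score(a, b, scoring_config)
            want = oracle_align(a, b)
            assert got == pytest.approx(want, abs=1e-9), (a, b)

    def test_unknown_residue_rejected(self, scoring_config):
        with pytest.raises(ScoringError, match="unknown residue"):
            align_score("MK1", "MK", scoring_config)

    def test_empty_sequence_rejected(self, scoring_config):
        with pytest.raises(ScoringError):
            align_score("", "MK", scoring_config)


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        assert greedy_cluster(["MKWLV", "MKWLV"], 0.75) == [[0, 1]]

    def test_disjoint_sequences_two_clusters(self):
        clusters = greedy_cluster(["MMMMM", "WWWWW"], 0.75)
        assert len(clusters) == 2

    def test_agrees_with_greedy_rule_oracle(self, rng):
        # independent re-simulation of the greedy rule (sort by length,
        # first-fit against the founding representative) on <= 6 sequences
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(25):
            template = "".join(rng.choice(aa, size=12))
            seqs = []
            for _ in range(int(rng.integers(2, 7))):
                s = list(template)
                for pos in rng.choice(12, size=int(rng.integers(0, 7)), replace=False):
                    s[pos] = str(rng.choice(aa))
                seqs.append("".join(s))
            got = greedy_cluster(seqs, 0.75)
            order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i]))
            want: list[list[int]] = []
            for i in order:
                for cl in want:
                    if percent_identity(seqs[cl[0]], seqs[i]) >= 0.75:
                        cl.append(i)
                        break
                else:
                    want.append([i])
            assert got == want


class TestSelectTopClusters:
    def test_both_kept_higher_identity_first(self):
        seqs = ["MKWLV", "MKWAV", "AAAAA"]
        clusters = [[2], [0, 1]]
        sel = select_top_clusters(clusters, seqs, "MKWLV", 30)
        assert sel == [1, 0]

    def test_cap_and_tie_break_order(self):
        seqs = ["MKWLV"] * 31
        clusters = [[i] for i in range(31)]
        sel = select_top_clusters(clusters, seqs, "MKWLV", 30)
        assert sel == list(range(30))  # equal identity: founding order

    def test_removing_unselected_cluster_leaves_score_unchanged(self, scoring_config):
        query = "MKWLVMKWLV"
        near = [query, query[:-1] + "A"]
        far = ["AAAAAGGGGG"]
        cfg = ScoringConfig(max_clusters=1)
        full = build_supporting_set("p", query, near + far, cfg)
        pruned = build_supporting_set("p", query, near, cfg)
        var = ProteinVariantRecord("p", "W3A", len(query), query[:2] + "A" + query[3:])
        assert delta_score(query, var, full, cfg).score == \
            delta_score(query, var, pruned, cfg).score


class TestDeltaScore:
    def test_identity_variant_scores_zero(self, scoring_config):
        q = "MKWLV"
        ss = build_supporting_set("p", q, [q, q], scoring_config)
        var = ProteinVariantRecord("p", "syn", len(q), q)
        res = delta_score(q, var, ss, scoring_config)
        assert res.score == 0.0
        assert res.classification == "neutral"

    def test_substitution_closed_form_support_equals_query(self, scoring_config):
        # support = one copy of the query: score = B62(A,W) - B62(W,W) = -14
        q = "MKWLV"
        ss = build_supporting_set("p", q, [q], scoring_config)
        res = delta_score(q, "W3A", ss, scoring_config)
        assert res.score == float(B62["A", "W"] - B62["W", "W"]) == -14.0
        assert res.classification == "deleterious"

    def test_closed_form_independent_of_copy_number(self, scoring_config):
        q = "MKWLV"
        for n in (1, 3, 7):
            ss = build_supporting_set("p", q, [q] * n, scoring_config)
            res = delta_score(q, "W3A", ss, scoring_config)
            assert res.score == -14.0

    def test_mild_scores_are_neutral_at_default_threshold(self):
        assert classify(0.5, -2.5) == "neutral"
        assert classify(-0.2, -2.5) == "neutral"
        assert classify(-2.5, -2.5) == "neutral"   # strict inequality
        assert classify(-2.6, -2.5) == "deleterious"

    def test_empty_supporting_set_unscored(self, scoring_config):
        ss = build_supporting_set("p", "MKWLV", [], scoring_config)
        res = delta_score("MKWLV", "W3A", ss, scoring_config)
        assert not res.scored and res.score is None

    def test_degenerate_mutant_unscored(self, scoring_config):
        q = "MKWLV"
        ss = build_supporting_set("p", q, [q], scoring_config)
        var = ProteinVariantRecord("p", "M1_V5del", len(q), "")
        res = delta_score(q, var, ss, scoring_config)
        assert "unscored" in res.flags

    def test_input_order_invariance(self, rng, scoring_config):
        q = "MKWLVACDEF"
        seqs = []
        for _ in range(6):
            s = list(q)
            for pos in rng.choice(len(q), size=2, replace=False):
                s[pos] = str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")))
            seqs.append("".join(s))
        var = ProteinVariantRecord("p", "W3A", len(q), q[:2] + "A" + q[3:])
        ss1 = build_supporting_set("p", q, seqs, scoring_config)
        base = delta_score(q, var, ss1, scoring_config).score
        for _ in range(3):
            perm = list(rng.permutation(len(seqs)))
            ss2 = build_supporting_set("p", q, [seqs[i] for i in perm], scoring_config)
            assert delta_score(q, var, ss2, scoring_config).score == pytest.approx(base, abs=1e-9)

    def test_matches_straightline_oracle(self, rng, scoring_config):
        # independent recomputation: same cluster structure, oracle aligner,
        # explicit mean-of-means loops
        q = "MKWLVACD"
        seqs = []
        for _ in range(5):
            s = list(q)
            for pos in rng.choice(len(q), size=int(rng.integers(0, 3)), replace=False):
                s[pos] = str(rng.choice(list("ACDE")))
            seqs.append("".join(s))
        ss = build_supporting_set("p", q, seqs, scoring_config)
        mutant = q[:2] + "A" + q[3:]
        var = ProteinVariantRecord("p", "W3A", len(q), mutant)
        got = delta_score(q, var, ss, scoring_config).score
        deltas = []
        for ci in ss.selected:
            qm = np.mean([oracle_align(q, seqs[i]) for i in ss.clusters[ci]])
            mm = np.mean([oracle_align(mutant, seqs[i]) for i in ss.clusters[ci]])
            deltas.append(mm - qm)
        assert got == pytest.approx(float(np.mean(deltas)), abs=1e-9)

    def test_sweeping_threshold_never_changes_scores(self, scoring_config):
        q = "MKWLV"
        ss = build_supporting_set("p", q, [q], scoring_config)
        scores = set()
        for thr in (-10.0, -2.5, -0.1):
            cfg = ScoringConfig(threshold=thr)
            scores.add(delta_score(q, "W3A", ss, cfg).score)
        assert scores == {-14.0}


class TestGeneLevelScore:
    def test_minimum_wins_and_classification_recomputed(self):
        rs = [make_result(-2.7), make_result(-1.0)]
        best = gene_level_score(rs)
        assert best.score == -2.7
        assert best.classification == "deleterious"

    def test_single_transcript_is_itself(self):
        r = make_result(0.3)
        assert gene_level_score([r]) is r

    def test_min_of_mixed_signs(self):
        rs = [make_result(0.2), make_result(-0.1)]
        assert gene_level_score(rs).score == -0.1

    def test_all_unscored_stays_unscored(self):
        rs = [make_result(None), make_result(None)]
        assert not gene_level_score(rs).scored


class TestSummaries:
    def test_variant_type_rows(self):
        rs = [
            make_result(-3.0, variant="A2V"),
            make_result(-1.0, variant="A2V"),
            make_result(-4.0, variant="A2_K3del"),
            make_result(-800.0, variant="A2_K9delinsW"),
            make_result(None, variant="A2V"),
        ]
        table = summarize_by_variant_type(rs)
        assert int(table["count"].sum()) == 4  # unscored excluded
        sub = table[table["type"] == "single aa substitution"].iloc[0]
        assert (sub["count"], sub["max_score"], sub["min_score"]) == (2, -1.0, -3.0)
        assert table[table["type"] == "complex"].iloc[0]["min_score"] == -800.0

    def test_cluster_support_report_counts(self):
        rs = [make_result(-1.0, n_clusters=10, flags=("few_clusters", "few_support"))] * 3 \
            + [make_result(-1.0)] * 7
        rep = cluster_support_report(rs)
        assert rep["n_few_clusters"] == 3
        assert rep["pct_few_clusters"] == 30
        assert rep["n_unscored"] == 0
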