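"""KL divergence, perspective-taking scores, redundancy and assembly.

The independent oracle throughout is a naive per-term base-2 summation in
Python floats, kept free of the vectorised implementation path.
"""

import math

import numpy as np
import pytest

from dyadkl.corpus_io import extract_dyad_interactions, label_interactions
from dyadkl.corpus_io import SignificanceRegistry
from dyadkl.entropy_features import (
    AbsoluteContinuityError,
    DyadFeatures,
    SupportMismatchError,
    assemble_features,
    dyad_divergences,
    feature_table,
    kl_divergence,
    perspective_scores,
    redundancy,
)
from dyadkl.topic_model import (
    DisjointSupportError,
    Lexicon,
)

from conftest import episode_corpus, make_dist, random_dist


def naive_kl(p, q):
    """Independent brute-force oracle: plain python loop, base-2 logs."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log2(pi / qi)
    return total


class TestKLDivergence:
    @pytest.mark.parametrize("p,q,expected", [
        ([0.5, 0.5], [0.5, 0.5], 0.0),
        ([0.5, 0.5], [0.25, 0.75], 0.2075187496),   # direct summation
        ([1.0, 0.0], [0.5, 0.5], 1.0),              # zero-term convention
    ])
    def test_worked_examples(self, p, q, expected):
        assert kl_divergence(make_dist(p), make_dist(q)) == \
            pytest.approx(expected, abs=1e-9)

    def test_mismatched_supports_rejected(self):
        with pytest.raises(SupportMismatchError):
            kl_divergence(make_dist([1.0], ("a",)), make_dist([1.0], ("b",)))

    def test_absolute_continuity_enforced(self):
        P = make_dist([0.5, 0.5], ("a", "b"))
        Q = make_dist([1.0, 0.0], ("a", "b"))
        with pytest.raises(AbsoluteContinuityError):
            kl_divergence(P, Q)

    def test_gibbs_inequality_and_oracle_agreement(self):
        """1000 random shared-support pairs: D >= 0, equality iff P = Q,
        and agreement with the naive summation to 1e-12."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            k = int(rng.integers(2, 195))
            P, Q = random_dist(rng, k), random_dist(rng, k)
            d = kl_divergence(P, Q)
            assert d >= 0.0
            assert d == pytest.approx(naive_kl(P.probs, Q.probs), abs=1e-12)
            if not np.allclose(P.probs, Q.probs):
                assert d > 0.0
            assert kl_divergence(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_asymmetry_witness(self):
        rng = np.random.default_rng(9)
        found = False
        for _ in range(20):
            P, Q = random_dist(rng, 10), random_dist(rng, 10)
            if abs(kl_divergence(P, Q) - kl_divergence(Q, P)) > 1e-6:
                found = True
                break
        assert found, "KL should not be symmetric on random pairs"


class TestPerspectiveScores:
    G = make_dist([0.5, 0.5])
    C = make_dist([0.25, 0.75])
    GC = make_dist([0.4, 0.6])

    def test_worked_example(self):
        pg, pc = perspective_scores(self.G, self.C, self.GC)
        assert pg == pytest.approx(0.23774437, abs=1e-6)
        assert pc == pytest.approx(0.15849626, abs=1e-6)

    def test_all_equal_vanishes(self):
        pg, pc = perspective_scores(self.G, self.G, self.G)
        assert pg == pytest.approx(0.0, abs=1e-12)
        assert pc == pytest.approx(0.0, abs=1e-12)

    def test_sum_identity_on_random_triples(self):
        """persp_g + persp_c = D(G||C) + D(C||G) to 1e-9 (path algebra)."""
        rng = np.random.default_rng(77)
        for _ in range(300):
            k = int(rng.integers(2, 60))
            G, C, GC = (random_dist(rng, k) for _ in range(3))
            pg, pc = perspective_scores(G, C, GC)
            d = dyad_divergences(G, C, GC)
            assert pg + pc == pytest.approx(d["d_g_c"] + d["d_c_g"], abs=1e-9)

    def test_scores_may_be_negative(self):
        rng = np.random.default_rng(5)
        seen_negative = False
        for _ in range(50):
            G, C, GC = (random_dist(rng, 8) for _ in range(3))
            pg, pc = perspective_scores(G, C, GC)
            if pg < 0 or pc < 0:
                seen_negative = True
                break
        assert seen_negative


class TestRedundancy:
    def test_worked_example(self):
        rho, capped = redundancy(TestPerspectiveScores.G,
                                 TestPerspectiveScores.C,
                                 TestPerspectiveScores.GC)
        assert rho == pytest.approx(33.0845, rel=1e-4)
        assert not capped

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            k = int(rng.integers(2, 40))
            G, C, GC = (random_dist(rng, k) for _ in range(3))
            r1, _ = redundancy(G, C, GC)
            r2, _ = redundancy(C, G, GC)
            assert r1 == pytest.approx(r2, rel=1e-9)

    def test_degenerate_triple_capped(self):
        D = make_dist([0.3, 0.7])
        rho, capped = redundancy(D, D, D, epsilon=1e-9)
        assert capped and rho == pytest.approx(1e9)

    def test_epsilon_must_be_positive(self):
        D = make_dist([0.5, 0.5])
        with pytest.raises(ValueError):
            redundancy(D, D, D, epsilon=0.0)


def _toy_labelled():
    """A: 'sa sa tb' / B: 'tb uc' / A: 'sa' — all hand-countable."""
    lex = Lexicon({"s": {"sa"}, "t": {"tb"}, "u": {"uc"}})
    corpus = episode_corpus(["A", "B", "A"], ["sa sa tb", "tb uc", "sa"])
    inter = extract_dyad_interactions(corpus)
    labelled, _ = label_interactions(inter, SignificanceRegistry({"A": {"B"}}))
    return lex, labelled


class TestAssembleFeatures:
    def test_end_to_end_hand_oracle(self):
        lex, labelled = _toy_labelled()
        feats = assemble_features(labelled[0], labelled, lex)
        # hand counts: G = {s:3, t:1}; C = {t:1, u:1}; GC = {s:3, t:2, u:1}
        d_gc_g = naive_kl([0.6, 0.4], [0.75, 0.25])      # common {s,t}
        d_gc_c = naive_kl([2 / 3, 1 / 3], [0.5, 0.5])    # common {t,u}
        assert feats.d_gc_g == pytest.approx(d_gc_g, abs=1e-12)
        assert feats.d_gc_c == pytest.approx(d_gc_c, abs=1e-12)
        assert feats.d_c_g == pytest.approx(0.0, abs=1e-12)  # common {t} only
        assert feats.d_g_c == pytest.approx(0.0, abs=1e-12)
        assert feats.persp_g == pytest.approx(d_gc_c - d_gc_g, abs=1e-12)
        assert feats.persp_c == pytest.approx(d_gc_g - d_gc_c, abs=1e-12)
        assert feats.rho == pytest.approx(1 / abs(d_gc_g - d_gc_c), rel=1e-9)
        assert feats.total_words == 6
        assert feats.label == "significant"

    def test_gc_identical_to_g_gives_zero(self):
        lex = Lexicon({"s": {"aa"}, "t": {"bb"}})
        corpus = episode_corpus(["A", "B"], ["aa bb", "aa bb"])
        inter = extract_dyad_interactions(corpus)
        labelled, _ = label_interactions(inter, SignificanceRegistry({"A": {"B"}}))
        feats = assemble_features(labelled[0], labelled, lex)
        assert feats.d_gc_g == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_error_carries_dyad_identity(self):
        lex = Lexicon({"s": {"aa"}, "t": {"bb"}})
        corpus = episode_corpus(["A", "B"], ["aa aa", "bb bb"])
        inter = extract_dyad_interactions(corpus)
        labelled, _ = label_interactions(inter, SignificanceRegistry({"A": {"B"}}))
        with pytest.raises(DisjointSupportError, match=r"\(A, B\)"):
            assemble_features(labelled[0], labelled, lex)

    def test_table_has_canonical_columns(self):
        lex, labelled = _toy_labelled()
        frame = feature_table(labelled, lex)
        assert list(frame.columns)[:11] == [
            "main", "partner", "label", "total_words",
            "d_gc_g", "d_gc_c", "d_c_g", "d_g_c",
            "persp_g", "persp_c", "rho"]
        assert len(frame) == 1

    def test_exclude_focal_changes_global(self):
        from dyadkl.corpus_io import Corpus, Utterance
        lex = Lexicon({"s": {"aa"}, "t": {"bb"}, "u": {"cc"}})
        corpus = Corpus([
            Utterance(1, 1, 0, "A", "aa bb"),
            Utterance(1, 1, 1, "B", "bb cc"),
            Utterance(1, 1, 2, "A", "bb cc"),
            Utterance(1, 2, 0, "A", "bb bb"),
            Utterance(1, 2, 1, "C", "aa bb"),
            Utterance(1, 3, 0, "B", "bb cc"),
            Utterance(1, 3, 1, "C", "aa"),
        ])
        inter = extract_dyad_interactions(corpus)
        focal = next(i for i in inter if i.pair == frozenset({"A", "B"}))
        incl = assemble_features(focal, inter, lex)
        excl = assemble_features(focal, inter, lex, exclude_focal=True)
        assert incl.d_gc_g != pytest.approx(excl.d_gc_g)

    def test_invariants_enforced_on_construction(self):
        with pytest.raises(ValueError, match="negative"):
            DyadFeatures("A", "B", None, 10, -0.1, 0.2, 0.3, 0.4,
                         0.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="identity"):
            DyadFeatures("A", "B", None, 10, 0.1, 0.2, 0.3, 0.4,
                         1.0, 1.0, 1.0)


class TestGlobalSupportVariant:
    def test_three_way_support_runs_and_differs(self):
        rng = np.random.default_rng(3)
        G, C, GC = (random_dist(rng, 12) for _ in range(3))
        pair = dyad_divergences(G, C, GC)
        glob = dyad_divergences(G, C, GC, global_support=True)
        assert set(pair) == set(glob)
        # full shared support: both reduce to the same values
        for key in pair:
            assert pair[key] == pytest.approx(glob[key], abs=1e-12)
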