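import numpy as np
import pytest

from meftop.features_sse import (
    SSE,
    SSE_FEATURE_NAMES,
    correspond_sses,
    f_sse,
    identify_sses,
    normalize_strength,
    sse_contact_strength_model,
    sse_contact_strength_sequence,
    sse_distance_similarity,
    sse_features,
    sse_length_ratios,
    sse_pair_distance_model,
    sse_pair_distance_sequence,
)
from meftop.target_profile import ProfileNoise, profile_from_structure

from conftest import model_from_ca


class TestIdentifySSEs:
    def test_mixed_string(self):
        sses = identify_sses("CCHHHHHCCEEEECC")
        assert sses == [SSE("H", 3, 7), SSE("E", 10, 13)]

    def test_minimum_length_rule(self):
        assert identify_sses("HHHC") == []

    def test_state_change_terminates_run(self):
        assert identify_sses("HHHHEEEE") == [SSE("H", 1, 4), SSE("E", 5, 8)]

    def test_matches_bruteforce_on_random_strings(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            ss = "".join(rng.choice(list("HEC"), n))
            got = identify_sses(ss)
            # brute force: scan every maximal run
            expected = []
            i = 0
            while i < n:
                j = i
                while j < n and ss[j] == ss[i]:
                    j += 1
                if ss[i] in "HE" and j - i >= 4:
                    expected.append(SSE(ss[i], i + 1, j))
                i = j
            assert got == expected

    def test_invariant_to_coil_content(self):
        a = identify_sses("CCCHHHHHCCCEEEEECC")
        b = identify_sses("CHHHHHCEEEEEC".replace("C", "CCC"))
        assert [(s.kind, s.length) for s in a] == [(s.kind, s.length) for s in b]


class TestCorrespondence:
    def test_identical_lists_identity_pairing(self):
        sses = [SSE("H", 3, 9), SSE("E", 15, 20)]
        assert correspond_sses(sses, sses) == [(0, 0), (1, 1)]

    def test_unmatched_target_excluded(self):
        model = [SSE("H", 3, 7)]
        target = [SSE("H", 4, 8), SSE("E", 20, 24)]
        assert correspond_sses(model, target) == [(0, 0)]

    def test_tie_prefers_earlier_target(self):
        model = [SSE("H", 10, 14)]
        target = [SSE("H", 8, 12), SSE("H", 12, 16)]
        assert correspond_sses(model, target) == [(0, 0)]

    def test_order_preserving_no_crossing(self):
        model = [SSE("H", 5, 9), SSE("E", 30, 35)]
        target = [SSE("H", 28, 33), SSE("E", 40, 45)]
        pairs = correspond_sses(model, target)
        for (m1, t1), (m2, t2) in zip(pairs, pairs[1:]):
            assert m2 > m1 and t2 > t1

    def test_empty_lists(self):
        assert correspond_sses([], [SSE("H", 1, 5)]) == []
        assert correspond_sses([SSE("H", 1, 5)], []) == []


class TestContactStrength:
    def make_paired_strands(self):
        """Two 4-residue strands 4.8 A apart (antiparallel register)."""
        ca1 = np.stack([np.zeros(4), np.zeros(4), 3.3 * np.arange(4)], axis=1)
        ca2 = ca1 + [4.8, 0, 0]
        ca2 = ca2[::-1]
        loop = np.array([[1.0, 4.0, 10.5], [3.5, 4.5, 11.0]])  # 2 linkers (ignored)
        ca = np.vstack([ca1, loop, ca2])
        return model_from_ca(ca)

    def test_model_strength_counts_pairs(self):
        model = self.make_paired_strands()
        sses = [SSE("E", 1, 4), SSE("E", 7, 10)]
        s = sse_contact_strength_model(sses, model, threshold=8.5)
        # brute force count over the SCM (=CA here) pairs with separation >= 6
        scm = model.scm_coords
        cnt = 0
        for i in range(0, 4):
            for j in range(6, 10):
                if abs(i - j) >= 6 and np.linalg.norm(scm[i] - scm[j]) < 8.5:
                    cnt += 1
        assert cnt >= 3
        assert s[0, 1] == cnt and s[1, 0] == cnt

    def test_sequence_strength_sums_probabilities(self):
        n = 16
        c = np.zeros((n, n))
        sses = [SSE("E", 1, 4), SSE("E", 13, 16)]
        for i in range(0, 4):
            for j in range(12, 16):
                c[i, j] = c[j, i] = 0.5
        s = sse_contact_strength_sequence(sses, c)
        assert s[0, 1] == pytest.approx(8.0)

    def test_band_exclusion_in_strength(self):
        # all cross pairs are within the distance cut, but only the three
        # pairs with separation >= 6 -- (1,7), (1,8), (2,8) -- may count
        model = model_from_ca(np.stack([0.5 * np.arange(8), np.zeros(8), np.zeros(8)], axis=1))
        sses = [SSE("H", 1, 4), SSE("H", 5, 8)]
        s = sse_contact_strength_model(sses, model, threshold=8.5)
        assert s[0, 1] == 3.0


class TestFsse:
    def test_identical_matrices(self):
        s = np.array([[0.0, 2.0], [1.5, 0.0]])
        assert f_sse(s, s) == pytest.approx(1.0)

    def test_zero_model_vs_nonzero_target(self):
        t = np.array([[0.0, 2.0], [1.5, 0.0]])
        assert f_sse(t, np.zeros((2, 2))) == 0.0

    def test_single_pair_half_agreement(self):
        c = np.array([[0.0, 2.0], [2.0, 0.0]])
        n = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert f_sse(c, n) == pytest.approx(0.5)

    def test_single_sse_no_pairs(self):
        assert f_sse(np.zeros((1, 1)), np.zeros((1, 1))) == 0.0


class TestPairDistance:
    def test_ideal_contact_gives_d0(self):
        n = 12
        c = np.zeros((n, n))
        c[0, 8] = c[8, 0] = 1.0
        sses = [SSE("E", 1, 4), SSE("E", 9, 12)]
        d = sse_pair_distance_sequence(sses, c)
        assert d[0, 1] == pytest.approx(3.8)

    def test_no_contact_gives_dm(self):
        sses = [SSE("E", 1, 4), SSE("E", 9, 12)]
        d = sse_pair_distance_sequence(sses, np.zeros((12, 12)))
        assert d[0, 1] == pytest.approx(8.0)

    def test_model_minimum_distance(self):
        ca1 = np.stack([np.zeros(4), np.zeros(4), 3.3 * np.arange(4)], axis=1)
        ca2 = ca1 + [4.8, 0, 0]
        model = model_from_ca(np.vstack([ca1, ca2]))
        sses = [SSE("E", 1, 4), SSE("E", 5, 8)]
        d = sse_pair_distance_model(sses, model)
        assert d[0, 1] == pytest.approx(4.8)

    def test_distance_similarity(self):
        d1 = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert sse_distance_similarity(d1, d1) == pytest.approx(1.0)
        d2 = np.array([[0.0, 9.0], [9.0, 0.0]])
        assert sse_distance_similarity(d1, d2, sigma=4.0) == pytest.approx(np.exp(-1.0))
        d3 = np.array([[0.0, 500.0], [500.0, 0.0]])
        assert sse_distance_similarity(d1, d3) == pytest.approx(0.0, abs=1e-12)


class TestLengthRatios:
    def test_equal_lengths(self):
        sses = [SSE("H", 1, 8), SSE("E", 12, 16)]
        assert sse_length_ratios(sses, sses, [(0, 0), (1, 1)]) == (1.0, 1.0)

    def test_hand_computed(self):
        model = [SSE("H", 1, 4), SSE("E", 10, 17)]
        target = [SSE("H", 1, 8), SSE("E", 10, 17)]
        r1, r2 = sse_length_ratios(model, target, [(0, 0), (1, 1)])
        assert r1 == pytest.approx(12 / 16)
        assert r2 == pytest.approx((0.5 + 1.0) / 2)

    def test_single_skewed_pair(self):
        model = [SSE("H", 1, 4)]
        target = [SSE("H", 1, 16)]
        assert sse_length_ratios(model, target, [(0, 0)]) == (0.25, 0.25)

    def test_no_pairs(self):
        assert sse_length_ratios([], [], []) == (0.0, 0.0)


class TestSSEFeatureSet:
    def test_exactly_six_features(self, mixed_native):
        prof = profile_from_structure(mixed_native, seed=0)
        feats = sse_features(prof, mixed_native)
        assert list(feats) == SSE_FEATURE_NAMES
        assert len(feats) == 6

    def test_maximal_on_native_with_clean_profile(self, mixed_native):
        prof = profile_from_structure(mixed_native, noise=ProfileNoise.zero(), seed=0)
        feats = sse_features(prof, mixed_native)
        for name in ("f_sse", "sse_cn_cosine", "sse_cn_correlation",
                     "sse_len_ratio_total", "sse_len_ratio_mean"):
            assert feats[name] == pytest.approx(1.0), name

    def test_no_sses_falls_back_to_zero(self):
        rng = np.random.default_rng(0)
        coil = model_from_ca(np.cumsum(rng.normal(0, 2.2, (30, 3)), axis=0))
        from meftop.io_structures import annotate
        annotate(coil)
        prof = profile_from_structure(coil, seed=1)
        feats = sse_features(prof, coil)
        if not identify_sses(coil.ss_string) or not identify_sses(prof.ss_pred):
            assert all(v == 0.0 for v in feats.values())
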