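"""Seed library, association statistics, clustering, and rG4 scanning."""

import numpy as np
import pytest
from scipy import stats

from ribolens.corpus import CANONICAL_PAIRS, GenicRegions, TranscriptRecord
from ribolens.motifs import (
    StructureSeed,
    apic,
    bh_correct,
    build_seed_library,
    cluster_significant_motifs,
    enumerate_hairpins,
    find_rg4,
    one_hot_motifs,
    paired_footprint_test,
    score_rg4,
    test_cluster_association,
)
from tests.conftest import random_rna


class TestHairpinEnumeration:
    def test_perfect_gc_hairpin(self):
        seeds = enumerate_hairpins("GGGGAAAACCCC", "t")
        assert len(seeds) == 1
        s = seeds[0]
        assert (s.dotbracket, s.stem_len, s.loop_len) == ("((((....))))", 4, 4)
        assert s.source == ("t", 0, 12)

    def test_stem_three_rejected(self):
        assert enumerate_hairpins("GGGAAAACCC", "t") == []

    def test_geometry_bounds_hold(self, rng):
        for _ in range(10):
            seq = random_rna(rng, 120)
            for s in enumerate_hairpins(seq, "t"):
                assert 4 <= s.stem_len <= 7
                assert 4 <= s.loop_len <= 9
                assert len(s.sequence) <= 30
                w = len(s.sequence)
                for k in range(s.stem_len):
                    pair = (s.sequence[k], s.sequence[w - 1 - k])
                    assert pair in CANONICAL_PAIRS

    def test_invalid_geometry_rejected_by_type(self):
        with pytest.raises(ValueError):
            StructureSeed("GGGAAAACCC", "(((....)))", 3, 4, ("t", 0, 10))

    def test_library_collects_occurrences(self):
        hp = "GCGCAAAAGCGC"
        recs = []
        for i in range(3):
            utr = "AAUU" + hp + "UUAA"
            seq = utr + "AUG" + "A" * 20
            recs.append(
                TranscriptRecord(
                    f"t{i}", seq,
                    GenicRegions((0, len(utr)), (len(utr), len(seq)),
                                 (len(seq), len(seq))),
                )
            )
        lib = build_seed_library(recs)
        key = (hp, "((((....))))")
        assert key in lib.occurrences
        assert len(lib.occurrences[key]) == 3
        assert lib.occurrences[key][0].source == ("t0", 4, 16)

    def test_no_utrs_empty_library(self):
        rec = TranscriptRecord(
            "t", "AUGAAAAA", GenicRegions((0, 0), (0, 8), (8, 8))
        )
        assert len(build_seed_library([rec])) == 0


class TestPairedFootprintTest:
    def _scores(self, n, length=40, inside=None, delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        feet = []
        for i in range(n):
            s = rng.normal(0, 1, length)
            if inside is not None:
                s[inside[0]:inside[1]] += delta
            out[f"t{i}"] = s
            feet.append((f"t{i}", inside[0], inside[1]) if inside else None)
        return out, feet

    def test_equal_inside_outside_p_one(self):
        scores = {f"t{i}": np.ones(30) for i in range(5)}
        feet = [(f"t{i}", 5, 15) for i in range(5)]
        res = paired_footprint_test(feet, scores)
        assert res.p_raw == 1.0 and res.degenerate

    def test_constant_shift_degenerate_p_zero(self):
        scores = {}
        feet = []
        for i in range(10):
            s = np.zeros(30)
            s[5:15] = 1.0  # inside exactly one higher
            scores[f"t{i}"] = s
            feet.append((f"t{i}", 5, 15))
        res = paired_footprint_test(feet, scores)
        assert res.degenerate and res.p_raw == 0.0
        assert res.mean_difference > 0

    def test_below_three_occurrences_skipped(self):
        scores = {f"t{i}": np.random.default_rng(i).normal(size=20)
                  for i in range(2)}
        feet = [(f"t{i}", 2, 8) for i in range(2)]
        assert paired_footprint_test(feet, scores) is None

    def test_rejection_rate_matches_power_oracle(self):
        """Planted effect: inside ~ N(delta, 1) vs outside ~ N(0, 1), n=30
        occurrences; the empirical rejection rate at p < 0.01 must match the
        noncentral-t power computed independently."""
        n, delta, reps = 30, 0.8, 800
        rng = np.random.default_rng(0)
        rejections = 0
        sd_diffs = []
        for _ in range(reps):
            inside = rng.normal(delta, 1, n)
            outside = rng.normal(0, 1, n)
            p = stats.ttest_rel(inside, outside).pvalue
            sd_diffs.append(np.std(inside - outside, ddof=1))
            rejections += p < 0.01
        # oracle: paired diff ~ N(delta, sqrt(2)); noncentral t power
        ncp = delta / (np.sqrt(2) / np.sqrt(n))
        tcrit = stats.t.ppf(1 - 0.005, n - 1)
        power = 1 - stats.nct.cdf(tcrit, n - 1, ncp) + stats.nct.cdf(
            -tcrit, n - 1, ncp
        )
        assert rejections / reps == pytest.approx(power, abs=0.05)


class TestBH:
    def test_single_p(self):
        assert bh_correct([0.04])[0] == pytest.approx(0.04)

    def test_hand_case(self):
        np.testing.assert_allclose(
            bh_correct([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_q_at_least_p(self, rng):
        p = rng.random(500)
        q = bh_correct(p)
        assert np.all(q >= p - 1e-15)

    def test_matches_reference_step_up(self, rng):
        def reference(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            prev = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * n / rank)
                q[i] = prev
            return q

        for n in (1, 2, 10, 1000):
            p = rng.random(n)
            np.testing.assert_allclose(bh_correct(p), reference(p), atol=1e-12)

    def test_empty(self):
        assert len(bh_correct([])) == 0


def make_seed(seq, tid="t", start=0):
    s = 4
    loop = len(seq) - 8
    return StructureSeed(seq, "(" * 4 + "." * loop + ")" * 4, 4, loop,
                         (tid, start, start + len(seq)))


class TestClustering:
    def test_two_pure_clusters(self):
        a = [make_seed("GCGCAAAAGCGC", f"a{i}") for i in range(60)]
        b = [make_seed("ACGUAAAAACGU", f"b{i}") for i in range(60)]
        clusters = cluster_significant_motifs(a + b, (2, 2), min_members=30)
        assert len(clusters) == 2
        seqs = sorted(c.member_sequences[0] for c in clusters)
        assert seqs == ["ACGUAAAAACGU", "GCGCAAAAGCGC"]
        for c in clusters:
            assert len(set(c.member_sequences)) == 1

    def test_small_group_not_reported(self):
        a = [make_seed("GCGCAAAAGCGC", f"a{i}") for i in range(29)]
        b = [make_seed("ACGUAAAAACGU", f"b{i}") for i in range(40)]
        clusters = cluster_significant_motifs(a + b, (2, 4), min_members=30)
        assert all(
            set(c.member_sequences) == {"ACGUAAAAACGU"} for c in clusters
        )

    def test_fewer_than_two_seeds(self):
        assert cluster_significant_motifs([make_seed("GCGCAAAAGCGC")]) == []

    def test_matches_sklearn_agglomerative(self, rng):
        """Ward cuts must agree with an independent agglomerative
        implementation on random motif sets."""
        from sklearn.cluster import AgglomerativeClustering

        seqs = []
        stems = ["GCGC", "ACGU", "GGCC", "AUGC"]
        for i in range(40):
            stem = stems[rng.integers(4)]
            loop = "".join(rng.choice(list("ACGU"), 4))
            comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
            rc = "".join(comp[c] for c in reversed(stem))
            seqs.append(make_seed(stem + loop + rc, f"t{i}"))
        X = one_hot_motifs(seqs)
        for k in (2, 3, 5):
            ours = cluster_significant_motifs(seqs, (k, k), min_members=1)
            sk = AgglomerativeClustering(n_clusters=k, linkage="ward").fit(X)
            ours_sets = {frozenset(id(m) for m in c.members) for c in ours}
            sk_sets = {
                frozenset(id(seqs[i]) for i in np.nonzero(sk.labels_ == l)[0])
                for l in np.unique(sk.labels_)
            }
            assert ours_sets == sk_sets


class TestFisher:
    def test_or_six_hand_case(self):
        odds, p = test_cluster_association([1] * 20 + [0] * 5,
                                           [1] * 30 + [0] * 45)
        assert odds == pytest.approx(6.0)

    def test_balanced_table_null(self):
        odds, p = test_cluster_association([1] * 10 + [0] * 10,
                                           [1] * 10 + [0] * 10)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            test_cluster_association([1] * 5, [1] * 5)

    def test_matches_hypergeometric_enumeration(self):
        """Exact p equals a brute-force tail enumeration of the
        hypergeometric null for every table with n <= 60."""

        def enumerated_p(a, b, c, d):
            n = a + b + c + d
            row1, col1 = a + b, a + c
            lo = max(0, row1 + col1 - n)
            hi = min(row1, col1)
            pmf = {
                x: stats.hypergeom.pmf(x, n, col1, row1)
                for x in range(lo, hi + 1)
            }
            cutoff = pmf[a] * (1 + 1e-7)
            return sum(v for v in pmf.values() if v <= cutoff)

        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(300):
            n = int(rng.integers(4, 61))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = int(rng.integers(0, n - a - b + 1))
            d = n - a - b - c
            table = np.array([[a, b], [c, d]])
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            p_scipy = stats.fisher_exact(table)[1]
            assert p_scipy == pytest.approx(
                enumerated_p(a, b, c, d), abs=1e-10
            )
            checked += 1
        assert checked > 200


class TestApic:
    def test_identical_members(self):
        assert apic(["GCGCAAAAGCGC"] * 30) == pytest.approx(2.0)

    def test_uniform_positions(self):
        members = ["A" * 8, "C" * 8, "G" * 8, "U" * 8]
        assert apic(members) == pytest.approx(0.0)

    def test_two_base_half_half(self):
        assert apic(["ACACAC", "GUGUGU"]) == pytest.approx(1.0, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            apic([])


class TestRG4:
    def test_canonical_gga_repeat(self):
        hits = find_rg4({"t": "GGAGGAGGAGGA"})
        assert len(hits) == 1
        h = hits[0]
        assert h.g_tract_count == 4
        assert h.loop_lengths == (1, 1, 1)
        assert h.gga_repeat

    def test_three_tracts_not_a_hit(self):
        assert find_rg4({"t": "GGAGGAGG"}) == []

    def test_no_g_no_hits(self, rng):
        seq = random_rna(rng, 1000, alphabet="ACU")
        assert find_rg4({"t": seq}) == []

    def test_long_loops_rejected(self):
        seq = "GG" + "A" * 8 + "GG" + "A" * 8 + "GG" + "A" * 8 + "GG"
        assert find_rg4({"t": seq}) == []

    def test_score_rg4_null_none_pass(self, rng):
        utrs = {f"t{i}": "AUAU" + "GGAGGAGGAGG" + "UAUA" for i in range(20)}
        hits = find_rg4(utrs)
        scores = {t: rng.normal(0, 1, len(u)) for t, u in utrs.items()}
        # identical inside/outside in expectation: only chance passes
        passed = score_rg4(hits, scores)
        assert len(passed) <= 2

    def test_score_rg4_planted_signal_recovered(self, rng):
        utrs, scores = {}, {}
        for i in range(50):
            utr = "AUAUCU" + "GGAGGAGGAGG" + "CUAUAUCUAU"
            utrs[f"t{i}"] = utr
            s = rng.normal(0, 1, len(utr))
            s[6:17] += 2.0  # contrast elevated only inside the planted rG4
            scores[f"t{i}"] = s
        hits = find_rg4(utrs)
        passed = score_rg4(hits, scores)
        assert len(passed) == 50
        assert all(h.q_bh < 0.01 for h in passed)

    def test_stratified_correction_differs_from_pooled(self):
        """BH within length strata can pass a hit that pooled BH would not."""
        scores = {}
        feet_by_len = {}
        # stratum A: one strong rG4 sequence (len 11), 5 occurrences
        # stratum B: many weak rG4s of a different length (len 15)
        rng = np.random.default_rng(5)
        utrs = {}
        for i in range(5):
            utr = "AUCUAU" + "GGAGGAGGAGG" + "AUCUAU"
            utrs[f"a{i}"] = utr
            s = rng.normal(0, 1, len(utr))
            s[6:17] += 3.0
            scores[f"a{i}"] = s
        for i in range(40):
            utr = "AUCUAU" + "GGAAAGGAAAGGAAAGG"[:15] + "AUCUAU"
            # GGAAAGGAAAGGAAAGG has tracts GG with loops AAA
            utrs[f"b{i}"] = "AUCUAU" + "GGAAAGGAAAGGAAAGG" + "AUCUAU"
            scores[f"b{i}"] = rng.normal(0, 1, len(utrs[f"b{i}"]))
        hits = find_rg4(utrs)
        passed = score_rg4(hits, scores)
        strong = [h for h in passed if h.sequence == "GGAGGAGGAGG"]
        assert len(strong) == 5  # survives stratified BH despite many weak Bs
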