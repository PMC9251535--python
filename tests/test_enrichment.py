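import numpy as np
import pytest
from scipy import stats

from regwas.enrichment import (
    GseaResult,
    NexusCall,
    bh_adjust,
    build_se_tf_set,
    collapse_tf_sets,
    gsea_collection,
    gsea_preranked,
    negative_control_tfs,
    nexus_tfs,
)
from regwas.intervals import Interval
from regwas.io_formats import GeneLocation, GeneSetCollection


def brute_force_es(ranked, members, weight):
    """Independent loop-based running-sum implementation."""
    genes = [g for g, _ in ranked]
    scores = [s for _, s in ranked]
    hits = [g in set(members) for g in genes]
    n = sum(hits)
    N = len(genes)
    nr = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    run, best, best_i = 0.0, 0.0, 0
    curve = []
    for i, (s, h) in enumerate(zip(scores, hits)):
        if h:
            run += (abs(s) ** weight) / nr if nr > 0 else 1.0 / n
        else:
            run -= 1.0 / (N - n)
        curve.append(run)
        if abs(run) > abs(best):
            best, best_i = run, i
    return best, best_i, curve


RANKED10 = [(f"g{i}", float(s)) for i, s in enumerate(range(10, 0, -1), start=1)]


class TestGseaPreranked:
    def test_perfect_enrichment_unweighted(self):
        ranked = [("a", 4.0), ("b", 3.0), ("c", 2.0), ("d", 1.0)]
        r = gsea_preranked(ranked, {"a", "b"}, weight_exponent=0.0, nperm=100,
                          seed=0, min_size=2)
        assert r.es == pytest.approx(1.0)
        assert r.leading_edge == ["a", "b"]

    def test_set_covering_whole_list_skipped(self):
        ranked = [("a", 2.0), ("b", 1.0), ("c", 0.5)]
        assert gsea_preranked(ranked, {"a", "b", "c"}, nperm=100) is None

    def test_es_matches_brute_force_on_worked_fixture(self):
        members = {"g1", "g3", "g10"}
        r = gsea_preranked(RANKED10, members, weight_exponent=1.0, nperm=100, seed=1)
        es, es_i, _ = brute_force_es(RANKED10, members, 1.0)
        assert r.es == pytest.approx(es, abs=1e-12)

    def test_es_matches_brute_force_on_random_sets(self, rng):
        genes = [f"g{i}" for i in range(60)]
        scores = np.sort(rng.uniform(0.1, 8, size=60))[::-1]
        ranked = list(zip(genes, scores.tolist()))
        for w in (0.0, 1.0):
            for _ in range(20):
                members = set(rng.choice(genes, size=rng.integers(3, 20), replace=False))
                r = gsea_preranked(ranked, members, weight_exponent=w, nperm=100, seed=0)
                es, _, _ = brute_force_es(ranked, members, w)
                assert r.es == pytest.approx(es, abs=1e-12)

    def test_sign_flip_on_reversed_list(self, rng):
        genes = [f"g{i}" for i in range(30)]
        scores = np.linspace(5, 0.5, 30)
        ranked = list(zip(genes, scores.tolist()))
        rev = list(zip(genes[::-1], scores.tolist()))
        members = set(rng.choice(genes, size=8, replace=False))
        r1 = gsea_preranked(ranked, members, weight_exponent=0.0, nperm=100, seed=0)
        r2 = gsea_preranked(rev, members, weight_exponent=0.0, nperm=100, seed=0)
        assert r1.es == pytest.approx(-r2.es, abs=1e-12)

    def test_leading_edge_is_hit_prefix(self, rng):
        genes = [f"g{i}" for i in range(50)]
        scores = np.linspace(6, 0.1, 50)
        ranked = list(zip(genes, scores.tolist()))
        for _ in range(10):
            members = set(rng.choice(genes, size=10, replace=False))
            r = gsea_preranked(ranked, members, nperm=100, seed=0)
            hits_in_order = [g for g, _ in ranked if g in members]
            if r.es >= 0:
                assert r.leading_edge == hits_in_order[: len(r.leading_edge)]
            else:
                assert r.leading_edge == hits_in_order[-len(r.leading_edge):]

    def test_same_seed_identical(self):
        members = {"g1", "g4", "g7"}
        r1 = gsea_preranked(RANKED10, members, nperm=500, seed=42)
        r2 = gsea_preranked(RANKED10, members, nperm=500, seed=42)
        assert (r1.es, r1.nes, r1.nominal_p) == (r2.es, r2.nes, r2.nominal_p)

    def test_nominal_p_floor_at_permutation_resolution(self):
        ranked = [(f"g{i}", float(100 - i)) for i in range(100)]
        r = gsea_preranked(ranked, {f"g{i}" for i in range(5)}, nperm=200, seed=0)
        assert r.nominal_p == pytest.approx(1 / 200)
        assert r.p_is_bound

    def test_null_p_uniform(self, rng):
        """Random set vs random list: nominal P is uniform."""
        genes = [f"g{i}" for i in range(80)]
        pvals = []
        for rep in range(200):
            scores = np.sort(rng.uniform(0.1, 5, size=80))[::-1]
            ranked = list(zip(genes, scores.tolist()))
            members = set(rng.choice(genes, size=10, replace=False))
            r = gsea_preranked(ranked, members, nperm=250, seed=int(rng.integers(2**31)))
            pvals.append(r.nominal_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGseaCollection:
    def _collection(self, rng, n_sets=8):
        genes = [f"g{i}" for i in range(100)]
        sets = {
            f"S{j}": sorted(rng.choice(genes, size=12, replace=False).tolist())
            for j in range(n_sets)
        }
        return genes, GeneSetCollection(sets=sets)

    def test_qvalues_in_unit_interval(self, rng):
        genes, coll = self._collection(rng)
        scores = np.sort(rng.uniform(0.1, 6, size=100))[::-1]
        ranked = list(zip(genes, scores.tolist()))
        results, _ = gsea_collection(ranked, coll, nperm=200, seed=3)
        assert results
        for r in results:
            assert 0.0 <= r.fdr_q <= 1.0

    def test_monotone_q_within_sign(self, rng):
        genes, coll = self._collection(rng, n_sets=10)
        scores = np.sort(rng.uniform(0.1, 6, size=100))[::-1]
        ranked = list(zip(genes, scores.tolist()))
        results, _ = gsea_collection(ranked, coll, nperm=200, seed=5)
        pos = sorted((r for r in results if r.nes >= 0), key=lambda r: -r.nes)
        assert all(a.fdr_q <= b.fdr_q + 1e-12 for a, b in zip(pos, pos[1:]))

    def test_invariant_to_set_declaration_order(self, rng):
        genes, coll = self._collection(rng)
        scores = np.sort(rng.uniform(0.1, 6, size=100))[::-1]
        ranked = list(zip(genes, scores.tolist()))
        r1, _ = gsea_collection(ranked, coll, nperm=150, seed=2)
        shuffled = GeneSetCollection(
            sets=dict(reversed(list(coll.sets.items())))
        )
        r2, _ = gsea_collection(ranked, shuffled, nperm=150, seed=2)
        assert [(r.set_name, r.es, r.nominal_p, r.fdr_q) for r in r1] == [
            (r.set_name, r.es, r.nominal_p, r.fdr_q) for r in r2
        ]

    def test_undersized_sets_skipped_with_reason(self, rng):
        genes = [f"g{i}" for i in range(50)]
        coll = GeneSetCollection(sets={"tiny": ["g1", "g2"], "ok": genes[:10]})
        ranked = [(g, float(50 - i)) for i, g in enumerate(genes)]
        results, skipped = gsea_collection(ranked, coll, nperm=100, seed=0)
        assert [r.set_name for r in results] == ["ok"]
        assert "tiny" in skipped


class TestBhAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_order_preserved(self, rng):
        p = rng.uniform(0.001, 1, size=20)
        q = bh_adjust(p)
        # q is aligned with p: sorting by p sorts q
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)


class TestSeTfSet:
    GENES = [
        GeneLocation("TF_OVER", "1", 10_000, 12_000, "+"),
        GeneLocation("TF_NEAR", "1", 80_000, 82_000, "+"),
        GeneLocation("TF_PROX", "1", 150_000, 152_000, "+"),
        GeneLocation("TF_FAR", "1", 900_000, 902_000, "+"),
        GeneLocation("OTHER", "1", 60_000, 62_000, "+"),
    ]
    TFS = ["TF_OVER", "TF_NEAR", "TF_PROX", "TF_FAR", "TF_NOLOC"]

    def test_three_rules(self):
        ses = [
            Interval("1", 11_000, 13_000),  # overlaps TF_OVER body
            Interval("1", 75_000, 76_000),  # nearest TSS is TF_NEAR (80,000)
            Interval("1", 120_000, 121_000),  # 29 kb from TF_PROX -> proximal
        ]
        members, prov = build_se_tf_set(self.TFS, ses, self.GENES, proximity=50_000)
        assert "TF_OVER" in members and "overlap" in prov["TF_OVER"]
        assert "TF_NEAR" in members and "nearest" in prov["TF_NEAR"]
        assert "TF_PROX" in members and "proximal" in prov["TF_PROX"]
        assert "TF_FAR" not in members and "TF_NOLOC" not in members

    def test_nearest_rule_ignores_non_tf_winner(self):
        # SE closest to OTHER (not a TF): nearest rule contributes nothing
        ses = [Interval("1", 63_000, 64_000)]
        members, _ = build_se_tf_set(self.TFS, ses, self.GENES, proximity=5_000)
        assert members == []

    def test_matches_brute_force_three_rule_oracle(self, rng):
        genes = [
            GeneLocation(f"G{i:02d}", "1", int(p), int(p) + 2_000, "+")
            for i, p in enumerate(sorted(rng.integers(10_000, 2_000_000, size=30)))
        ]
        tfs = [g.gene_id for g in genes[::2]]
        ses = [
            Interval("1", int(s), int(s) + 3_000)
            for s in rng.integers(0, 2_000_000, size=10)
        ]
        prox = 40_000
        members, _ = build_se_tf_set(tfs, ses, genes, proximity=prox)

        def dist(tss, se):
            t = tss - 1
            if se.start <= t < se.end:
                return 0
            return se.start - t if t < se.start else t - (se.end - 1)

        oracle = set()
        for tf in tfs:
            g = next(x for x in genes if x.gene_id == tf)
            for se in ses:
                overlap = g.start - 1 < se.end and se.start < g.end
                nearest = (
                    min(genes, key=lambda x: (dist(x.tss, se), x.gene_id)).gene_id == tf
                )
                if overlap or nearest or dist(g.tss, se) <= prox:
                    oracle.add(tf)
        assert set(members) == oracle


class TestCollapseAndNexus:
    @staticmethod
    def result(name, p, nes=1.0, q=0.1):
        return GseaResult(
            set_name=name, es=max(-1.0, min(1.0, nes / 2)), nes=nes,
            nominal_p=p, fdr_q=q, leading_edge=[], set_size_used=10,
        )

    def test_min_p_represents_tf(self):
        results = [self.result("A_01", 0.2), self.result("A_02", 0.01)]
        best = collapse_tf_sets(results, {"A_01": "A", "A_02": "A"})
        assert best["A"].set_name == "A_02"

    def test_single_set_identity(self):
        results = [self.result("B_01", 0.3)]
        best = collapse_tf_sets(results, {"B_01": "B"})
        assert best["B"].set_name == "B_01"

    def test_tie_prefers_larger_abs_nes_then_name(self):
        results = [
            self.result("C_01", 0.05, nes=1.0),
            self.result("C_02", 0.05, nes=-2.0),
        ]
        best = collapse_tf_sets(results, {"C_01": "C", "C_02": "C"})
        assert best["C"].set_name == "C_02"

    def test_matches_group_by_min_oracle(self, rng):
        results, mapping = [], {}
        for t in range(50):
            for j in range(int(rng.integers(1, 5))):
                name = f"T{t:02d}_{j}"
                results.append(self.result(name, float(rng.uniform(0, 1)),
                                           nes=float(rng.normal())))
                mapping[name] = f"T{t:02d}"
        best = collapse_tf_sets(results, mapping)
        for tf, r in best.items():
            group = [x for x in results if mapping[x.set_name] == tf]
            assert r.nominal_p == min(x.nominal_p for x in group)

    def test_nexus_predicate(self):
        collapsed = {
            "YES": self.result("YES_01", 0.01, q=0.1),
            "BAD_Q": self.result("BADQ_01", 0.04, q=0.3),
            "OFF_EDGE": self.result("OFF_01", 0.001, q=0.01),
        }
        calls = {c.tf_id: c for c in nexus_tfs(["YES", "BAD_Q"], collapsed)}
        assert calls["YES"].is_nexus
        assert not calls["BAD_Q"].is_nexus  # q >= 0.25
        assert not calls["OFF_EDGE"].is_nexus  # not on leading edge

    def test_predicate_matches_direct_evaluation(self, rng):
        collapsed = {}
        edge = set()
        for i in range(100):
            tf = f"T{i:03d}"
            collapsed[tf] = self.result(
                f"{tf}_01", float(rng.uniform(0, 0.2)), q=float(rng.uniform(0, 0.5))
            )
            if rng.random() < 0.5:
                edge.add(tf)
        calls = nexus_tfs(edge, collapsed)
        for c in calls:
            expected = (c.tf_id in edge) and c.tft_p < 0.05 and c.tft_q < 0.25
            assert c.is_nexus == expected

    def test_nexus_invariant_on_dataclass(self):
        c = NexusCall("T", True, "T_01", 0.01, 0.1)
        assert c.is_nexus
        c2 = NexusCall("T", True, "T_01", 0.06, 0.1)
        assert not c2.is_nexus

    def test_negative_controls_exclude_edge_tfs(self):
        collapsed = {
            f"T{i}": self.result(f"T{i}_01", p) for i, p in enumerate([0.9, 0.8, 0.1, 0.95])
        }
        out = negative_control_tfs(collapsed, ["T2"], n=2, order_by="p")
        assert out == ["T3", "T0"]
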