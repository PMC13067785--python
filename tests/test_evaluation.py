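"""Metrics against brute force, CI arithmetic, and the split protocols."""

import numpy as np
import pytest

from biosynkg.fusion_train import FusedEmbeddingTable, RankingResult, TrainConfig
from biosynkg.evaluation import (
    EvalReport,
    confidence_interval,
    hits_at_k,
    incremental_series,
    leave_one_genus_out,
    mean_rank,
    mrr,
    normalize_rank_score,
    permutation_baseline,
    rank_test_queries,
    temporal_protocol,
)
from biosynkg.kg_core import temporal_subgraph
from biosynkg.synthetic_data import SyntheticConfig, generate_dataset


def result_with_rank(rank: int, n: int, qid: str = "q") -> RankingResult:
    """A ranking whose single relevant candidate sits at the given rank."""
    cands = [f"c{i:03d}" for i in range(n)]
    scores = [1.0 - i / (n + 1.0) for i in range(n)]
    return RankingResult(qid, cands, scores, frozenset({cands[rank - 1]}))


class TestMetrics:
    def test_mrr_worked_example(self):
        results = [result_with_rank(r, 6, f"q{r}") for r in (1, 2, 4)]
        assert mrr(results) == pytest.approx(0.583333, abs=1e-6)

    def test_mrr_single_query_reciprocal(self):
        for k in (1, 3, 7):
            assert mrr([result_with_rank(k, 8)]) == pytest.approx(1.0 / k)

    def test_mean_rank_worked_example(self):
        results = [result_with_rank(r, 6, f"q{r}") for r in (2, 4)]
        assert mean_rank(results) == pytest.approx(3.0)

    def test_hits_worked_example(self):
        results = [result_with_rank(r, 6, f"q{r}") for r in (1, 2, 4)]
        assert hits_at_k(results, 3) == pytest.approx(2 / 3)
        assert hits_at_k(results, 6) == 1.0
        assert hits_at_k(results, 1) == pytest.approx(1 / 3)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            hits_at_k([result_with_rank(1, 3)], 0)

    def test_empty_results_rejected(self):
        for fn in (mrr, mean_rank):
            with pytest.raises(ValueError):
                fn([])

    def test_agrees_with_brute_force_on_random_rank_vectors(self):
        # independent recomputation: scan the sorted candidate list
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(2, 30))
            ranks = rng.integers(1, n + 1, size=int(rng.integers(1, 8)))
            results = [result_with_rank(int(r), n, f"q{i}") for i, r in enumerate(ranks)]
            brute_first = []
            for res in results:
                first = next(
                    i + 1 for i, c in enumerate(res.candidates) if c in res.positives
                )
                brute_first.append(first)
            assert mrr(results) == pytest.approx(np.mean([1 / r for r in brute_first]))
            assert mean_rank(results) == pytest.approx(np.mean(brute_first))
            for k in (1, 5, 10):
                assert hits_at_k(results, k) == pytest.approx(
                    np.mean([r <= k for r in brute_first])
                )

    def test_metrics_invariant_to_query_order(self):
        results = [result_with_rank(r, 9, f"q{r}") for r in (1, 3, 5, 9)]
        assert mrr(results) == mrr(results[::-1])
        assert mean_rank(results) == mean_rank(results[::-1])


class TestConfidenceInterval:
    def test_zero_variance_degenerate(self):
        lo, hi = confidence_interval([0.8, 0.8, 0.8])
        assert lo == pytest.approx(0.8) and hi == pytest.approx(0.8)
        assert hi - lo == pytest.approx(0.0, abs=1e-15)

    def test_t_quantile_hand_computation(self):
        lo, hi = confidence_interval([0.76, 0.80, 0.84], 0.95)
        assert (hi - lo) / 2 == pytest.approx(0.09935, abs=1e-4)
        assert (lo + hi) / 2 == pytest.approx(0.80)

    def test_contains_mean(self):
        vals = [0.1, 0.5, 0.3, 0.4]
        lo, hi = confidence_interval(vals)
        assert lo <= np.mean(vals) <= hi

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            confidence_interval([0.5])


class TestNormalizeRankScore:
    def test_rank_one_scores_one(self):
        res = result_with_rank(1, 4)
        for conv in ("reciprocal", "minmax"):
            scores = normalize_rank_score(res, conv)
            assert scores[res.candidates[0]] == pytest.approx(1.0)

    def test_reciprocal_convention(self):
        res = result_with_rank(2, 4)
        scores = normalize_rank_score(res)
        assert scores[res.candidates[1]] == pytest.approx(0.5)

    def test_nonincreasing_with_rank_under_both_conventions(self):
        res = result_with_rank(3, 6)
        for conv in ("reciprocal", "minmax"):
            vals = [normalize_rank_score(res, conv)[c] for c in res.candidates]
            assert vals == sorted(vals, reverse=True)


class TestEvalReport:
    def test_invariant_enforcement(self):
        bad = EvalReport("p", [{"MR": 2.0, "MRR": 0.2, "HITS@5": 0.9, "HITS@10": 0.4,
                                "HITS@20": 1.0}])
        with pytest.raises(ValueError, match="nondecreasing"):
            bad.validate()

    def test_mrr_at_least_reciprocal_mean_rank(self):
        ok = EvalReport("p", [{"MR": 4.0, "MRR": 0.4, "HITS@5": 0.5, "HITS@10": 0.6,
                               "HITS@20": 1.0}])
        ok.validate()
        bad = EvalReport("p", [{"MR": 4.0, "MRR": 0.1, "HITS@5": 0.5, "HITS@10": 0.6,
                                "HITS@20": 1.0}])
        with pytest.raises(ValueError, match="MRR"):
            bad.validate()


class TestFiltering:
    def test_training_positive_never_ranked(self, trained_small):
        g, _, model = trained_small
        table = model.fused_table()
        train_pos = {}
        for t in g.triples_with("synthesizes"):
            train_pos.setdefault(t.head, set()).add(t.tail)
        microbe = sorted(train_pos)[0]
        mats = sorted(e.id for e in g.materials())
        fake_test = {microbe: set(mats) - train_pos[microbe]}
        results = rank_test_queries(table, fake_test, mats, train_pos, filtered=True)
        for res in results:
            assert not (set(res.candidates) & train_pos[res.query_id])


class TestPerfectRanker:
    def test_oracle_scores_give_perfect_metrics(self):
        vecs = {"q": np.zeros(2), "pos": np.zeros(2), "n1": np.array([9.0, 0]),
                "n2": np.array([0, 9.0])}
        table = FusedEmbeddingTable(2, vecs)
        results = rank_test_queries(table, {"q": {"pos"}}, ["pos", "n1", "n2"], {}, True)
        assert mrr(results) == 1.0
        assert hits_at_k(results, 5) == 1.0


@pytest.fixture(scope="module")
def synth_for_protocols():
    g, truth = generate_dataset(SyntheticConfig(seed=17))
    cfg = TrainConfig(seed=2, epochs=30, snapshot_start=10)
    return g, cfg


class TestTemporalProtocol:
    def test_report_shape_and_determinism(self, synth_for_protocols):
        g, cfg = synth_for_protocols
        rep = temporal_protocol(g, cfg, 2019, runs=2)
        assert len(rep.per_run) == 2
        assert set(rep.metrics) == {"MR", "MRR", "HITS@5", "HITS@10", "HITS@20"}
        rep2 = temporal_protocol(g, cfg, 2019, runs=2)
        assert rep.per_run == rep2.per_run

    def test_empty_test_side_rejected(self, synth_for_protocols):
        g, cfg = synth_for_protocols
        with pytest.raises(ValueError):
            temporal_protocol(g, cfg, 3000, runs=1)


class TestIncrementalSeries:
    def test_nested_training_sets_and_fixed_test(self, synth_for_protocols):
        g, cfg = synth_for_protocols
        cuts = [2013, 2016, 2019]
        tr = [temporal_subgraph(g, c, "before") for c in cuts]
        keys = [set(t.key() for t in x.triples_with("synthesizes")) for x in tr]
        assert keys[0] <= keys[1] <= keys[2]
        reports, trend = incremental_series(g, cfg, cuts, runs=1)
        assert len(reports) == 3
        assert list(trend["cutoff"]) == cuts

    def test_needs_two_cutoffs(self, synth_for_protocols):
        g, cfg = synth_for_protocols
        with pytest.raises(ValueError):
            incremental_series(g, cfg, [2019], runs=1)


class TestLeaveOneGenusOut:
    def test_folds_partition_positives_without_leakage(self, synth_for_protocols):
        g, cfg = synth_for_protocols
        from biosynkg.kg_core import genus_of
        reports, manifest = leave_one_genus_out(g, cfg, runs=1)
        total = manifest["n_test_edges"].sum()
        assert total == len(g.triples_with("synthesizes"))
        # leakage audit over all folds: a fold's training side never contains
        # a synthesizes edge of any of its held-out microbes
        synth = g.triples_with("synthesizes")
        covered = set()
        for genus in reports:
            held = {t.key() for t in synth if str(genus_of(g, t.head)) == genus}
            kept = {t.key() for t in synth if str(genus_of(g, t.head)) != genus}
            held_heads = {h for h, _, _ in held}
            assert not held & kept
            assert not any(h in held_heads for h, _, _ in kept)
            covered |= held
        assert covered == {t.key() for t in synth}


class TestPermutationBaseline:
    def test_uniform_single_positive_matches_harmonic_mean(self):
        n = 10
        results = [result_with_rank(1, n)]
        rng = np.random.default_rng(0)
        base = permutation_baseline(results, rng, n_perm=4000)
        want = np.mean([1.0 / r for r in range(1, n + 1)])
        assert base["MRR"] == pytest.approx(want, rel=0.05)
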