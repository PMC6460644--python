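"""Benchmark I/O, correlation oracles, scorer evaluation, contradiction probe."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from biosentsim import (
    BagOfWordsEncoder,
    BenchmarkPair,
    CosineScorer,
    contradiction_probe,
    default_antonym_sentences,
    default_negation_sentences,
    evaluate_scorer,
    generate_antonym_pairs,
    generate_benchmark,
    generate_high_similarity_pairs,
    generate_negation_pairs,
    pearson,
    preprocess_sentence,
    read_benchmark,
    select_high_similarity_subset,
    sentence_jaccard,
    spearman,
    write_benchmark,
    GeneratorConfig,
)


def pearson_oracle(x, y):
    """Textbook covariance / (sigma_x * sigma_y), computed from raw sums."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    cov = (x * y).sum() / n - x.mean() * y.mean()
    sx = np.sqrt((x * x).sum() / n - x.mean() ** 2)
    sy = np.sqrt((y * y).sum() / n - y.mean() ** 2)
    return cov / (sx * sy)


def midrank(v):
    """Average ranks for ties, 1-based."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class TestBenchmarkIO:
    def test_roundtrip_equals_in_memory_records(self, tmp_path, benchmark_noisy):
        path = write_benchmark(benchmark_noisy, tmp_path / "bench.tsv")
        loaded = read_benchmark(path)
        assert loaded == benchmark_noisy
        assert len(loaded) == 100

    def test_gold_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pair_id\tsentence1\tsentence2\tscore\tsubset\n"
                        "p1\tfoo bar\tbaz qux\t4.3\t\n")
        with pytest.raises(ValueError, match="row 2"):
            read_benchmark(path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pair_id\tsentence1\tsentence2\tscore\tsubset\n"
                        "p1\tfoo\tbar\t1.0\t\n"
                        "only-one-column\n")
        with pytest.raises(ValueError, match="row 3"):
            read_benchmark(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("p1\tfoo\tbar\t1.0\n")
        with pytest.raises(ValueError, match="header"):
            read_benchmark(path)

    def test_gold_may_be_absent(self, tmp_path):
        path = tmp_path / "nogold.tsv"
        path.write_text("pair_id\tsentence1\tsentence2\tscore\tsubset\n"
                        "p1\tfoo bar\tbaz qux\t\tnegation\n")
        (pair,) = read_benchmark(path)
        assert pair.gold is None and pair.subset == "negation"

    def test_empty_sentence_rejected(self):
        with pytest.raises(ValueError, match="empty sentence"):
            BenchmarkPair("p1", "", "something")


class TestCorrelations:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            assert abs(pearson(x, y) - pearson_oracle(x, y)) < 1e-12

    def test_spearman_equals_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            x = rng.integers(0, 8, size=25).astype(float)  # plenty of ties
            y = rng.integers(0, 8, size=25).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            oracle = pearson_oracle(midrank(x), midrank(y))
            assert abs(spearman(x, y) - oracle) < 1e-12

    def test_spearman_monotone_invariance(self):
        x = np.linspace(0.1, 2.0, 15)
        y = np.exp(x)  # strictly monotone, nonlinear
        assert spearman(x, y) == pytest.approx(1.0)
        assert spearman(x, y[::-1]) == pytest.approx(-1.0)

    @given(
        st.lists(
            st.floats(-5, 5).map(lambda v: round(v, 3)), min_size=3, max_size=20
        )
    )
    def test_spearman_invariant_under_strictly_monotone_transform(self, xs):
        # quantized inputs keep exp() strictly monotone in floating point
        x = np.asarray(xs)
        if np.ptp(x) == 0:
            return
        y = np.arange(len(x), dtype=float)
        assert spearman(x, y) == pytest.approx(spearman(np.exp(x / 5), y), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="3 observations"):
            pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestEvaluateScorer:
    def _lookup_scorer(self, benchmark):
        gold = {(p.sentence1, p.sentence2): p.gold for p in benchmark}
        return lambda s1, s2: gold[(s1, s2)]

    def test_scorer_equal_to_gold_gives_r_one(self, benchmark_noisy):
        report = evaluate_scorer(self._lookup_scorer(benchmark_noisy), benchmark_noisy)
        assert report.pearson_r == pytest.approx(1.0)
        assert report.n_missing == 0 and report.n_pairs == 100

    def test_constant_scorer_is_error(self, benchmark_noisy):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_scorer(lambda a, b: 0.5, benchmark_noisy)

    def test_jaccard_matches_per_pair_hand_oracle(self, benchmark_sigma0):
        subset = benchmark_sigma0[:20]
        report = evaluate_scorer(sentence_jaccard, subset, "jaccard")
        golds, preds = [], []
        for p in subset:
            a = set(preprocess_sentence(p.sentence1).tokens)
            b = set(preprocess_sentence(p.sentence2).tokens)
            oracle = len(a & b) / len(a | b) if (a | b) else 0.0
            assert report.predicted[p.pair_id] == pytest.approx(oracle)
            golds.append(p.gold)
            preds.append(oracle)
        assert report.pearson_r == pytest.approx(pearson_oracle(preds, golds))

    def test_failing_pairs_counted_missing_not_imputed(self, benchmark_noisy):
        fail_ids = {p.pair_id for p in benchmark_noisy[:10]}
        lookup = self._lookup_scorer(benchmark_noisy)
        by_sent = {p.sentence1: p.pair_id for p in benchmark_noisy}

        def scorer(s1, s2):
            if by_sent[s1] in fail_ids:
                raise ValueError("unscorable")
            return lookup(s1, s2)

        report = evaluate_scorer(scorer, benchmark_noisy)
        assert report.n_missing == 10 and report.n_pairs == 90
        assert not fail_ids & set(report.predicted)

    def test_majority_missing_is_error(self, benchmark_noisy):
        def scorer(s1, s2):
            raise ValueError("nope")

        with pytest.raises(ValueError, match="unscorable"):
            evaluate_scorer(scorer, benchmark_noisy)

    def test_noise_degrades_correlation_monotonically(self, benchmark_sigma0):
        gold = {(p.sentence1, p.sentence2): p.gold for p in benchmark_sigma0}
        rs = []
        for sigma in (0.0, 0.5, 2.0):
            vals = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                scorer = lambda a, b: gold[(a, b)] + rng.normal(0, sigma)
                vals.append(evaluate_scorer(scorer, benchmark_sigma0).pearson_r)
            rs.append(np.mean(vals))
        assert rs[0] > rs[1] > rs[2]


class TestHighSimilaritySubset:
    def test_inclusive_threshold(self):
        pairs = [
            BenchmarkPair("a", "x y", "y z", gold=3.5),
            BenchmarkPair("b", "x y", "y z", gold=3.49),
            BenchmarkPair("c", "x y", "y z", gold=4.0),
            BenchmarkPair("d", "x y", "y z", gold=None),
        ]
        subset = select_high_similarity_subset(pairs)
        assert [p.pair_id for p in subset] == ["a", "c"]

    def test_size_matches_bruteforce_count(self, benchmark_noisy):
        subset = select_high_similarity_subset(benchmark_noisy)
        assert len(subset) == sum(
            1 for p in benchmark_noisy if p.gold is not None and p.gold >= 3.5
        )


@pytest.fixture(scope="module")
def subsets():
    cfg = GeneratorConfig(seed=5)
    return {
        "high_similarity": generate_high_similarity_pairs(cfg),
        "negation": generate_negation_pairs(default_negation_sentences()),
        "antonym": generate_antonym_pairs(default_antonym_sentences()),
    }


class TestContradictionProbe:

    def test_constant_encoder_gives_all_means_one(self, subsets):
        report = contradiction_probe({"const": lambda a, b: 1.0}, subsets)
        assert all(m == 1.0 for m in report.subset_means["const"].values())
        assert report.ordering_flag["const"] is False

    def test_constructed_contradiction_aware_scorer_sets_flag(self, subsets):
        # a scorer built to give contradiction pairs (near-identical wording,
        # s1 != s2) zero similarity must restore the expected ordering
        def scorer(s1, s2):
            a, b = set(s1.lower().split()), set(s2.lower().split())
            overlap = len(a & b) / len(a | b)
            return 0.0 if (s1 != s2 and overlap >= 0.75) else 0.9

        report = contradiction_probe({"aware": scorer}, subsets)
        m = report.subset_means["aware"]
        assert m["negation"] < m["high_similarity"]
        assert m["antonym"] < m["high_similarity"]
        assert report.ordering_flag["aware"] is True

    def test_bag_of_words_rates_contradictions_above_paraphrases(self, subsets):
        # the qualitative finding: lexical-overlap models score negated and
        # antonym-swapped pairs above merely-similar pairs
        all_tokens = [
            preprocess_sentence(s).tokens
            for pairs in subsets.values()
            for p in pairs
            for s in (p.sentence1, p.sentence2)
        ]
        enc = BagOfWordsEncoder.from_sentences(all_tokens)
        scorer = CosineScorer(enc, name="bow")
        report = contradiction_probe({"bow": scorer}, subsets)
        m = report.subset_means["bow"]
        assert m["negation"] > m["high_similarity"]
        assert m["antonym"] > m["high_similarity"]
        assert report.ordering_flag["bow"] is False
        assert report.subset_sizes["bow"] == {
            "high_similarity": 11, "negation": 13, "antonym": 7,
        }

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contradiction_probe({"m": lambda a, b: 1.0}, {"negation": []})

    def test_failing_pairs_skipped_and_counted(self, subsets):
        calls = {"n": 0}

        def flaky(s1, s2):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                raise ValueError("boom")
            return 0.5

        report = contradiction_probe({"flaky": flaky}, subsets)
        assert report.n_skipped["flaky"] > 0
        total_scored = sum(report.subset_sizes["flaky"].values())
        assert total_scored + report.n_skipped["flaky"] == sum(
            len(p) for p in subsets.values()
        )

    def test_report_table_renders(self, subsets):
        report = contradiction_probe({"const": lambda a, b: 1.0}, subsets)
        text = report.table()
        assert "negation" in text and "const" in text
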