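"""Split protocols, AUC machinery, ranking metrics and the benchmark loop."""

import numpy as np
import pytest

from biplink import (
    auc_pairwise,
    auroc_full,
    degree_bias_analysis,
    precision_recall_f,
    random_bipartite,
    run_benchmark,
    split_static,
    split_temporal,
    unique_disease_coverage,
)
from biplink.errors import (
    EvaluationError,
    ParameterError,
    TemporalError,
    VocabularyError,
)
from biplink.synth import default_cohort_spec, simulate_cohort


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(default_cohort_spec(n_patients=120, seed=42))


class TestStaticSplit:
    def test_sizes_90_10(self):
        net = random_bipartite(20, 10, 0.5, seed=1)
        assert net.n_links > 50
        split = split_static(net, 0.1, seed=3)
        assert len(split.probe) == round(0.1 * net.n_links)
        assert len(split.train) + len(split.probe) == net.n_links

    def test_partition_and_disjointness(self):
        net = random_bipartite(12, 8, 0.4, seed=2)
        split = split_static(net, 0.2, seed=9)
        assert split.train | split.probe == net.links
        assert not split.train & split.probe
        assert not split.nonexistent & net.links
        assert len(split.nonexistent) == 12 * 8 - net.n_links

    def test_fraction_bounds(self):
        net = random_bipartite(10, 10, 0.5, seed=0)
        with pytest.raises(ParameterError):
            split_static(net, 0.0, seed=0)
        with pytest.raises(ParameterError):
            split_static(net, 1.5, seed=0)

    def test_probe_rounds_to_zero(self):
        net = random_bipartite(2, 2, 1.0, seed=0)
        with pytest.raises(ParameterError):
            split_static(net, 0.05, seed=0)

    def test_same_seed_identical(self):
        net = random_bipartite(15, 9, 0.4, seed=4)
        assert split_static(net, 0.1, seed=11) == split_static(net, 0.1, seed=11)


class TestTemporalSplit:
    def test_probe_links_are_latest(self, cohort):
        split = split_temporal(cohort, 0.1, seed=0)
        for p, d in split.probe:
            t = cohort.timestamp(p, d)
            assert all(cohort.timestamp(p, v) <= t for v in cohort.neighbors(p))

    def test_one_probe_link_per_patient(self, cohort):
        split = split_temporal(cohort, 0.1, seed=1)
        patients = [p for p, _ in split.probe]
        assert len(patients) == len(set(patients)) == len(split.probe)

    def test_probe_size(self, cohort):
        split = split_temporal(cohort, 0.1, seed=2)
        assert len(split.probe) == round(0.1 * cohort.n_links)
        assert split.train | split.probe == cohort.links

    def test_causality_no_probe_before_training(self, cohort):
        split = split_temporal(cohort, 0.1, seed=3)
        train_by_patient = {}
        for p, d in split.train:
            train_by_patient.setdefault(p, []).append(cohort.timestamp(p, d))
        for p, d in split.probe:
            assert cohort.timestamp(p, d) >= max(train_by_patient[p])

    def test_explicit_three_date_patient(self):
        import datetime as dt

        from biplink import TemporalBipartiteNetwork

        # only p has >= 2 diagnoses, so p is the one sampled patient
        links = {("p", "d1"), ("p", "d2"), ("p", "d3")} | {
            (f"q{i}", "d1") for i in range(3)
        }
        ts = {l: dt.date(2001, 1, 1) for l in links}
        ts[("p", "d2")] = dt.date(2002, 1, 1)
        ts[("p", "d3")] = dt.date(2003, 1, 1)
        net = TemporalBipartiteNetwork(
            {"p", "q0", "q1", "q2"}, {"d1", "d2", "d3"}, links, ts
        )
        split = split_temporal(net, 1 / 6, seed=0)
        assert split.probe == frozenset({("p", "d3")})

    def test_insufficient_patients(self):
        import datetime as dt

        from biplink import TemporalBipartiteNetwork

        links = {("p", "d1"), ("p", "d2")}
        ts = {l: dt.date(2001, 1, 1) for l in links}
        net = TemporalBipartiteNetwork({"p"}, {"d1", "d2"}, links, ts)
        with pytest.raises(ParameterError):
            split_temporal(net, 0.9, seed=0)


class TestPairwiseAUC:
    def test_perfect_separation(self):
        assert auc_pairwise([2.0], [1.0]).auc == 1.0

    def test_all_ties(self):
        r = auc_pairwise([1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.auc == 0.5 and r.n_tied == r.n

    def test_decomposition(self):
        r = auc_pairwise([3.0, 1.0], [1.0, 2.0])
        # comparisons: 3>1, 3>2, 1=1, 1<2
        assert (r.n, r.n_higher, r.n_tied) == (4, 2, 1)
        assert r.auc == pytest.approx(0.625)

    def test_empty_sets_rejected(self):
        with pytest.raises(EvaluationError):
            auc_pairwise([], [1.0])

    def test_sampled_approaches_exhaustive(self):
        rng = np.random.default_rng(0)
        p, q = rng.random(300) + 0.2, rng.random(400)
        exact = auc_pairwise(p, q).auc
        approx = auc_pairwise(p, q, n_comparisons=200_000, seed=1).auc
        assert abs(exact - approx) < 0.01


class TestAUROC:
    def test_perfect(self):
        assert auroc_full([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_matches_pairwise_exhaustive(self):
        """Mann–Whitney identity: Eq.-10 AUC with all comparisons == ROC area."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            n_pos = int(rng.integers(3, 60))
            n_neg = int(rng.integers(3, 120))
            scores = rng.integers(0, 8, size=n_pos + n_neg).astype(float)  # many ties
            labels = np.r_[np.ones(n_pos), np.zeros(n_neg)]
            pairwise = auc_pairwise(scores[:n_pos], scores[n_pos:]).auc
            assert auroc_full(scores, labels) == pytest.approx(pairwise)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(5)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        assert auroc_full(-scores, labels) == pytest.approx(
            1 - auroc_full(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auroc_full([1.0, 2.0], [1, 1])


class TestPrecisionRecall:
    def test_hand_example(self):
        # 10 candidates, positives ranked 1, 2 and 4; cut at k=3
        scores = np.array([10, 9, 8, 7, 6, 5, 4, 3, 2, 1], dtype=float)
        labels = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        p, r, f = precision_recall_f(scores, labels, k=3)
        assert p == pytest.approx(2 / 3)
        assert r == pytest.approx(2 / 3)
        assert f == pytest.approx(2 / 3)  # p == r implies F == p

    def test_perfect_ranking(self):
        scores = np.array([5, 4, 3, 2, 1], dtype=float)
        labels = np.array([1, 1, 0, 0, 0], dtype=bool)
        assert precision_recall_f(scores, labels, k=2) == (1.0, 1.0, 1.0)

    def test_zero_when_no_hits(self):
        scores = np.array([5, 4, 3], dtype=float)
        labels = np.array([0, 0, 1], dtype=bool)
        p, r, f = precision_recall_f(scores, labels, k=1)
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_k_out_of_range(self):
        with pytest.raises(ParameterError):
            precision_recall_f([1.0], [True], k=2)


class TestBenchmark:
    def test_single_run_zero_sd(self):
        net = random_bipartite(15, 10, 0.4, seed=0)
        report = run_benchmark(net, ["CN", "PRA"], runs=1, seed=7)
        summary = report.summary()
        assert (summary[[c for c in summary.columns if c.endswith("_sd")]] == 0).all().all()

    def test_deterministic_given_seed(self):
        net = random_bipartite(15, 10, 0.4, seed=0)
        r1 = run_benchmark(net, ["CN", "RA"], runs=3, seed=5)
        r2 = run_benchmark(net, ["CN", "RA"], runs=3, seed=5)
        assert r1.per_run.equals(r2.per_run)

    def test_metrics_in_unit_interval(self, cohort):
        report = run_benchmark(cohort, ["CN", "PA", "TPRA"], runs=2, seed=1)
        vals = report.per_run[["auc", "auroc", "precision", "recall", "f_score"]]
        assert ((vals >= 0) & (vals <= 1)).all().all()

    def test_tpra_requires_temporal(self):
        net = random_bipartite(10, 8, 0.4, seed=0)
        with pytest.raises(TemporalError):
            run_benchmark(net, ["TPRA"], runs=1, seed=0)

    def test_unknown_index(self, cohort):
        with pytest.raises(VocabularyError):
            run_benchmark(cohort, ["SIMRANK"], runs=1, seed=0)

    def test_tpra_beats_degree_only_on_planted_cohort(self, cohort):
        """Planted transition structure rewards the temporal index over PA."""
        report = run_benchmark(cohort, ["TPRA", "PA"], runs=5, seed=3)
        assert report.mean("TPRA") > report.mean("PA")


class TestRankedAnalyses:
    def _ranked_instance(self):
        net = random_bipartite(6, 4, 0.5, seed=8)
        pairs = net.nonexistent_pairs()
        rng = np.random.default_rng(2)
        scores = rng.random(len(pairs))
        labels = rng.random(len(pairs)) < 0.3
        return net, pairs, scores, labels

    def test_single_correct_prediction_order_one(self):
        net = random_bipartite(4, 3, 0.5, seed=1)
        pairs = net.nonexistent_pairs()
        scores = np.linspace(1, 0, len(pairs))
        labels = np.zeros(len(pairs), dtype=bool)
        labels[2] = True
        df = degree_bias_analysis(pairs, scores, labels, net)
        assert len(df) == 1 and df.iloc[0]["first_correct_order"] == 1

    def test_never_correct_diseases_absent(self):
        net, pairs, scores, labels = self._ranked_instance()
        df = degree_bias_analysis(pairs, scores, labels, net)
        hit = {v for (p, v), l in zip(pairs, labels) if l}
        assert set(df["disease"]) == hit

    def test_coverage_full_fraction(self):
        net, pairs, scores, labels = self._ranked_instance()
        count, low = unique_disease_coverage(pairs, scores, labels, net, 1.0)
        assert count == len({v for (p, v), l in zip(pairs, labels) if l})
        assert 1 <= low <= len(net.v2_nodes)

    def test_coverage_single_disease(self):
        net = random_bipartite(5, 3, 0.4, seed=3)
        pairs = net.nonexistent_pairs()
        scores = np.linspace(1, 0, len(pairs))
        target = pairs[0][1]
        labels = np.array([v == target for _, v in pairs])
        for frac in (0.3, 0.7, 1.0):
            count, _ = unique_disease_coverage(pairs, scores, labels, net, frac)
            assert count == 1

    def test_no_correct_predictions(self):
        net, pairs, scores, _ = self._ranked_instance()
        labels = np.zeros(len(pairs), dtype=bool)
        assert unique_disease_coverage(pairs, scores, labels, net) == (0, 0)
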