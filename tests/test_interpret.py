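"""Fidelity, saliency, attention summaries and clinical correlation."""

import numpy as np
import pytest

from connectogat import (
    GATConfig,
    GraphSample,
    attention_summary,
    correlate_clinical,
    fidelity_scores,
    saliency_map,
    select_salient,
)
from connectogat.atlas import make_toy_atlas
from connectogat.connectomes import CohortDataset, ConnectivityMatrix, SubjectRecord
from connectogat.gat import GATModel
from connectogat.interpret import SaliencyMap

from oracles import random_graph

RNG = np.random.default_rng(77)


def tiny_model(seed=0, dropout=0.0):
    return GATModel(GATConfig(n_features=5, hidden=3, heads1=2, out_features=3,
                              readout_k=2, mlp_hidden=(6,), dropout=dropout,
                              seed=seed))


def tiny_samples(n_samples=6, n=6, f=5, seed=1):
    rng = np.random.default_rng(seed)
    return [
        GraphSample(rng.standard_normal((n, f)), random_graph(rng, n), i % 2, f"s{i}")
        for i in range(n_samples)
    ]


class StubModel:
    """Model stand-in with scripted predictions, for checking the fidelity
    arithmetic independently of any trained network."""

    class _Cfg:
        heads1 = 1

    config = _Cfg()

    def __init__(self, base_preds, masked_preds, labels):
        self.base = base_preds
        self.masked = masked_preds
        self.calls = [s for s in range(len(base_preds))]
        self._i = 0

    def forward(self, features, adjacency, **kw):
        preds = self.masked if kw.get("mask_head") is not None else self.base
        idx = int(features[0, 0])  # sample index smuggled in the features

        class Out:
            predicted = preds[idx]

        return Out()


def stub_samples(labels):
    return [
        GraphSample(np.full((2, 2), i, dtype=float), np.eye(2), int(l), f"g{i}")
        for i, l in enumerate(labels)
    ]


class TestFidelity:
    def test_hand_computed_drop_four_to_two_correct(self):
        labels = [1, 1, 0, 0]
        model = StubModel(base_preds=[1, 1, 0, 0], masked_preds=[1, 0, 1, 0],
                          labels=labels)
        res = fidelity_scores(model, stub_samples(labels), layers_heads=[(0, 0)])
        assert res.scores[(0, 0)] == pytest.approx(0.5)
        assert res.baseline_accuracy == 1.0

    def test_no_prediction_change_gives_zero_fidelity(self):
        labels = [1, 0, 1]
        model = StubModel([1, 0, 0], [1, 0, 0], labels)
        res = fidelity_scores(model, stub_samples(labels), layers_heads=[(0, 0)])
        assert res.scores[(0, 0)] == 0.0

    def test_scores_are_multiples_of_one_over_n(self):
        model = tiny_model(seed=3)
        samples = tiny_samples(5, seed=3)
        res = fidelity_scores(model, samples)
        for f in res.scores.values():
            assert abs(f) <= 1.0
            assert (f * len(samples)) == pytest.approx(round(f * len(samples)))

    def test_all_heads_scored_and_ranked(self):
        model = tiny_model(seed=4)
        samples = tiny_samples(4, seed=4)
        res = fidelity_scores(model, samples)
        assert set(res.scores) == {(0, 0), (0, 1), (1, 0)}
        ranked = res.ranked_heads()
        scores = [res.scores[k] for k in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            fidelity_scores(tiny_model(), [])


class TestSaliency:
    def test_input_independent_model_has_zero_saliency(self):
        model = tiny_model(seed=5)
        for p in range(model.config.heads1):
            model.params[f"l1h{p}.W"].data[:] = 0.0
            model.params[f"l1h{p}.a"].data[:] = 0.0
        samples = tiny_samples(4, seed=5)
        correct = [s for s in samples
                   if model.forward(s.features, s.adjacency).predicted == s.label]
        if not correct:
            pytest.skip("degenerate: no correct predictions to average")
        sal = saliency_map(model, correct)
        np.testing.assert_allclose(sal.values, 0.0, atol=1e-12)

    def test_gradient_matches_central_finite_differences(self):
        model = tiny_model(seed=6)
        s = tiny_samples(1, seed=6)[0]
        out = model.forward(s.features, s.adjacency)
        s = GraphSample(s.features, s.adjacency, out.predicted)  # force correct
        sal = saliency_map(model, [s], signed=True)
        rng = np.random.default_rng(6)
        pred = out.predicted
        for _ in range(5):
            i, j = rng.integers(s.features.shape[0]), rng.integers(5)
            step = 1e-4
            xp, xm = s.features.copy(), s.features.copy()
            xp[i, j] += step
            xm[i, j] -= step
            fd = (
                model.forward(xp, s.adjacency).probabilities[pred]
                - model.forward(xm, s.adjacency).probabilities[pred]
            ) / (2 * step)
            denom = max(abs(fd), 1e-8)
            assert abs(fd - sal.values[i, j]) / denom < 1e-4

    def test_mean_is_order_invariant(self):
        model = tiny_model(seed=7)
        samples = tiny_samples(6, seed=7)
        correct = [s for s in samples
                   if model.forward(s.features, s.adjacency).predicted == s.label]
        if len(correct) < 2:
            pytest.skip("need two correctly predicted samples")
        a = saliency_map(model, correct)
        b = saliency_map(model, list(reversed(correct)))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)
        assert a.sample_count == b.sample_count == len(correct)

    def test_no_correct_predictions_raises_with_count(self):
        model = tiny_model(seed=8)
        samples = tiny_samples(3, seed=8)
        wrong = [GraphSample(s.features, s.adjacency,
                             1 - model.forward(s.features, s.adjacency).predicted)
                 for s in samples]
        with pytest.raises(ValueError, match="3"):
            saliency_map(model, wrong)


class TestSelectSalient:
    def make(self, values):
        return SaliencyMap(np.asarray(values, dtype=float), 1)

    def test_zero_threshold_keeps_all_positive_entries(self):
        sal = self.make(np.full((3, 4), 0.5))
        assert len(select_salient(sal, 0.0)) == 12

    def test_threshold_above_max_yields_empty(self):
        sal = self.make(np.full((3, 4), 0.01))
        assert select_salient(sal, 0.5) == []

    def test_exactly_three_above_default_threshold_descending(self):
        v = np.full((4, 4), 0.001)
        v[0, 1], v[2, 3], v[3, 0] = 0.05, 0.03, 0.09
        out = select_salient(self.make(v), 0.02)
        assert [(i, j) for i, j, _ in out] == [(3, 0), (0, 1), (2, 3)]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_salient(self.make(np.zeros((2, 2))), -0.1)


class TestAttentionSummary:
    def test_single_sample_summary_equals_its_attention(self):
        model = tiny_model(seed=9)
        s = tiny_samples(1, seed=9)[0]
        out = model.forward(s.features, s.adjacency, record_attention=True)
        s = GraphSample(s.features, s.adjacency, out.predicted)
        summ = attention_summary(model, [s])
        for k, a in out.attention.items():
            np.testing.assert_allclose(summ.mean[k], a, atol=1e-12)
            np.testing.assert_allclose(summ.symmetric[k], summ.symmetric[k].T)

    def test_display_threshold_monotonically_prunes_edges(self):
        model = tiny_model(seed=10)
        s = tiny_samples(1, seed=10)[0]
        out = model.forward(s.features, s.adjacency)
        s = GraphSample(s.features, s.adjacency, out.predicted)
        counts = []
        for thr in (0.0, 0.05, 0.1, 0.3, 0.6):
            summ = attention_summary(model, [s], display_threshold=thr)
            counts.append(sum(np.count_nonzero(a) for a in summ.symmetric.values()))
        assert counts == sorted(counts, reverse=True)


class TestClinicalCorrelation:
    def make_cohort(self, n_nodes=4, n_pat=8, aao=None, origin="real"):
        atlas = make_toy_atlas(n_nodes)
        rng = np.random.default_rng(0)
        subjects, feats = [], {}
        for i in range(n_pat):
            sid = f"p{i}"
            w = np.zeros((n_nodes, n_nodes))
            clinical = {"AAO": float(aao[i])} if aao is not None else {}
            subjects.append(
                SubjectRecord(sid, 1, ConnectivityMatrix(w, "SC", sid),
                              ConnectivityMatrix(w, "FC", sid),
                              np.zeros((n_nodes, 2)), clinical, origin)
            )
            feats[sid] = rng.standard_normal((n_nodes, 3))
        return CohortDataset(subjects, atlas), feats

    def test_perfectly_linear_feature_has_unit_correlation(self):
        cohort, feats = self.make_cohort(aao=np.arange(8.0) + 40)
        for i, s in enumerate(cohort.subjects):
            feats[s.subject_id][1, 2] = s.clinical["AAO"] * 2.0 - 3.0
        res = correlate_clinical([(1, 2, 0.5)], cohort, feats, alpha=0.005,
                                 variables=("AAO",))
        row = res.rows[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["significant"]

    def test_hand_computed_pearson(self):
        cohort, feats = self.make_cohort(n_pat=5, aao=[2, 1, 4, 3, 5])
        for i, s in enumerate(cohort.subjects):
            feats[s.subject_id][0, 0] = i + 1.0  # x = 1..5 vs y = (2,1,4,3,5)
        res = correlate_clinical([(0, 0, 1.0)], cohort, feats, alpha=0.05,
                                 variables=("AAO",))
        assert res.rows[0]["r"] == pytest.approx(0.8)

    def test_zero_variance_flagged_undefined(self):
        cohort, feats = self.make_cohort(aao=np.full(8, 50.0))
        res = correlate_clinical([(0, 0, 1.0)], cohort, feats,
                                 variables=("AAO",))
        assert res.rows[0]["undefined"] and not res.rows[0]["significant"]

    def test_bonferroni_correction_demotes_marginal_p(self):
        rng = np.random.default_rng(3)
        cohort, feats = self.make_cohort(n_pat=12, aao=rng.normal(50, 5, 12))
        for i, s in enumerate(cohort.subjects):
            # moderate association: significant alone, not after x8 correction
            feats[s.subject_id][0, 0] = s.clinical["AAO"] + rng.normal(0, 4.5)
        salient = [(0, 0, 1.0)] + [(i % 4, 1 + i % 2, 0.5) for i in range(7)]
        plain = correlate_clinical(salient, cohort, feats, alpha=0.05,
                                   variables=("AAO",))
        bonf = correlate_clinical(salient, cohort, feats, alpha=0.05,
                                  variables=("AAO",), correction="bonferroni")
        target = lambda res: next(r for r in res.rows
                                  if (r["node"], r["feature"]) == (0, 0))
        if target(plain)["significant"] and target(plain)["p"] > 0.05 / 8:
            assert not target(bonf)["significant"]

    def test_unknown_correction_rejected(self):
        cohort, feats = self.make_cohort(aao=np.arange(8.0))
        with pytest.raises(ValueError, match="correction"):
            correlate_clinical([(0, 0, 1.0)], cohort, feats, correction="fdr_by")

    def test_synthetic_smote_subjects_excluded(self):
        cohort, feats = self.make_cohort(aao=np.arange(8.0), origin="smote")
        res = correlate_clinical([(0, 0, 1.0)], cohort, feats,
                                 variables=("AAO",))
        assert res.rows == []  # no real patients -> nothing to correlate
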