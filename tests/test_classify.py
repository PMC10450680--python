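"""Two-species logistic event classification."""

import numpy as np
import pytest
from scipy.stats import norm

from nanopept import evaluate, filter_events, predict, train_classifier
from nanopept.classify import ClassifierModel, stratified_split
from conftest import make_event, make_event_population


def _labeled(events_a, events_b, la="A", lb="B"):
    return [(e, la) for e in events_a] + [(e, lb) for e in events_b]


class TestFilter:
    def test_strict_bounds_exclude_endpoints(self):
        events = [make_event(iex_pct=v) for v in (50.0, 70.0, 90.0)]
        kept = filter_events(events)
        assert [e.iex_pct for e in kept] == [70.0]

    def test_empty_input(self):
        assert filter_events([]) == []

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            filter_events([], low=90.0, high=50.0)


class TestTraining:
    def test_well_separated_classes_near_perfect(self, rng):
        # 8 sigma apart in iex -> held-out accuracy above 99%
        a = make_event_population(rng, 600, iex_mu=60.0, iex_sd=1.0)
        b = make_event_population(rng, 600, iex_mu=68.0, iex_sd=1.0)
        train, test = stratified_split(_labeled(a, b), test_frac=0.2, seed=1)
        with pytest.warns(RuntimeWarning, match="separable"):
            model = train_classifier(train)
        pred, _ = predict(model, [e for e, _ in test])
        acc = np.mean([p == t for p, (_, t) in zip(pred, test)])
        assert acc > 0.99

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        events = make_event_population(rng, 4000, iex_mu=64.0, iex_sd=2.0)
        labels = np.where(rng.random(len(events)) < 0.5, "A", "B")
        pairs = list(zip(events, labels.tolist()))
        train, test = stratified_split(pairs, test_frac=0.2, seed=2)
        model = train_classifier(train)
        pred, _ = predict(model, [e for e, _ in test])
        acc = np.mean([p == t for p, (_, t) in zip(pred, test)])
        assert abs(acc - 0.5) < 0.05

    def test_duplicated_dataset_same_weights(self, rng):
        a = make_event_population(rng, 200, iex_mu=60.0, iex_sd=2.0)
        b = make_event_population(rng, 200, iex_mu=64.0, iex_sd=2.0)
        pairs = _labeled(a, b)
        m1 = train_classifier(pairs)
        m2 = train_classifier(pairs + pairs)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-5)

    def test_requires_two_classes_with_enough_events(self, rng):
        a = make_event_population(rng, 30, iex_mu=60.0, iex_sd=2.0)
        with pytest.raises(ValueError, match="two classes"):
            train_classifier([(e, "A") for e in a])
        b = make_event_population(rng, 5, iex_mu=64.0, iex_sd=2.0)
        with pytest.raises(ValueError, match="at least 10"):
            train_classifier(_labeled(a, b))


class TestPrediction:
    def test_zero_score_is_probability_half(self):
        model = ClassifierModel(
            classes=("A", "B"),
            weights=np.zeros(4),
            feature_means=np.array([60.0, 0.0, 1.5]),
            feature_scales=np.array([2.0, 0.4, 0.3]),
        )
        labels, p = predict(model, [make_event()])
        assert p[0] == pytest.approx(0.5)
        assert labels[0] == "A"  # strict > 0.5 required for the second class

    def test_class_centroid_confident(self, rng):
        a = make_event_population(rng, 400, iex_mu=58.0, iex_sd=1.5)
        b = make_event_population(rng, 400, iex_mu=70.0, iex_sd=1.5)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = train_classifier(_labeled(a, b))
        centroid_a = make_event(iex_pct=58.0, dwell_ms=1.0, sigma_b=1.5)
        labels, p = predict(model, [centroid_a])
        assert labels[0] == "A"
        assert p[0] < 0.1  # p is P(B)

    def test_feature_unit_rescaling_preserves_predictions(self, rng):
        a = make_event_population(rng, 300, iex_mu=60.0, iex_sd=2.0)
        b = make_event_population(rng, 300, iex_mu=64.0, iex_sd=2.0)
        pairs = _labeled(a, b)
        model = train_classifier(pairs)
        # dwell in seconds instead of ms: log10 shifts by -3 uniformly,
        # standardization absorbs it
        def rescale(e):
            return make_event(e.iex_pct, e.dwell_ms / 1000.0, e.sigma_b)

        pairs_s = [(rescale(e), lab) for e, lab in pairs]
        model_s = train_classifier(pairs_s)
        _, p = predict(model, [e for e, _ in pairs])
        _, p_s = predict(model_s, [e for e, _ in pairs_s])
        np.testing.assert_allclose(p, p_s, atol=1e-6)


class TestEvaluation:
    def test_all_correct_and_all_wrong(self):
        s = evaluate(["A", "B", "A"], ["A", "B", "A"])
        assert s.tpr_pct == {"A": 100.0, "B": 100.0}
        s = evaluate(["B", "B", "B"], ["A", "A", "B"])
        assert s.tpr_pct["A"] == 0.0
        assert s.counts.tolist() == [[0, 2], [0, 1]]

    def test_unknown_predicted_label_rejected(self):
        with pytest.raises(ValueError, match="not among truth"):
            evaluate(["C", "A"], ["A", "B"])
        with pytest.raises(ValueError, match="equal length"):
            evaluate(["A"], ["A", "B"])

    def test_tpr_matches_bayes_rate_for_overlapping_clusters(self, rng):
        # only iex is informative; equal-sigma Gaussians 2 sigma apart.
        # Bayes per-class rate by integration: Phi(delta / 2 sigma) = Phi(1).
        mu_a, mu_b, sd = 62.0, 66.0, 2.0
        a = make_event_population(rng, 4000, iex_mu=mu_a, iex_sd=sd)
        b = make_event_population(rng, 4000, iex_mu=mu_b, iex_sd=sd)
        train, test = stratified_split(_labeled(a, b), test_frac=0.25, seed=3)
        model = train_classifier(train)
        pred, _ = predict(model, [e for e, _ in test])
        summary = evaluate(pred, [lab for _, lab in test])
        bayes = 100.0 * norm.cdf((mu_b - mu_a) / (2 * sd))
        for cls in summary.classes:
            assert abs(summary.tpr_pct[cls] - bayes) < 3.0

    def test_three_features_match_or_beat_midpoint_rule_on_training_set(self, rng):
        # the logistic MLE optimizes likelihood, not 0-1 loss, so allow a
        # few events of slack against the one-feature midpoint rule
        a = make_event_population(rng, 2000, iex_mu=62.0, iex_sd=2.0)
        b = make_event_population(rng, 2000, iex_mu=65.0, iex_sd=2.0)
        pairs = _labeled(a, b)
        model = train_classifier(pairs)
        pred, _ = predict(model, [e for e, _ in pairs])
        truth = [lab for _, lab in pairs]
        acc_model = np.mean([p == t for p, t in zip(pred, truth)])
        mid = 63.5
        acc_mid = np.mean(
            [("A" if e.iex_pct < mid else "B") == t for (e, _), t in zip(pairs, truth)]
        )
        assert acc_model >= acc_mid - 0.01

    def test_tpr_monotone_in_class_separation(self, rng):
        tprs = []
        for delta in (2.0, 4.0, 6.0, 8.0):
            a = make_event_population(rng, 1500, iex_mu=60.0, iex_sd=2.0)
            b = make_event_population(rng, 1500, iex_mu=60.0 + delta, iex_sd=2.0)
            train, test = stratified_split(_labeled(a, b), test_frac=0.3, seed=4)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model = train_classifier(train)
            pred, _ = predict(model, [e for e, _ in test])
            summary = evaluate(pred, [lab for _, lab in test])
            tprs.append(np.mean(list(summary.tpr_pct.values())))
        assert all(b >= a for a, b in zip(tprs, tprs[1:]))
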