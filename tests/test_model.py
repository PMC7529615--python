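"""Posterior-predictive tables, reading likelihoods and histogram reports."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbce_bayes import (
    ClassConditionalModel,
    Dataset,
    abnormal_mass_difference,
    canonical_schema,
    default_config,
    feature_histograms,
    fit,
    generate,
    load_model,
    posterior_predictive,
    reading_likelihood,
    reading_log_likelihood,
    save_model,
)

from conftest import brute_force_posterior, make_dataset, random_rows

ATOL = 1e-12


def empty_model(task="severity", alpha=1.0):
    schema = canonical_schema()
    counts = {c: [[0] * K for K in schema.level_counts] for c in (1, 2)}
    return ClassConditionalModel.from_counts(schema, task, counts, alpha=alpha)


class TestFit:
    def test_empty_class_reduces_to_uniform_prior(self):
        # one class-2 reading only: class 1 tables are prior-predictive
        data = make_dataset([((1,) * 9, 2)])
        model = fit(data, "severity")
        assert posterior_predictive(model, 1, 1, 1) == pytest.approx(0.5, abs=ATOL)
        assert posterior_predictive(model, 1, 2, 3) == pytest.approx(1 / 3, abs=ATOL)

    def test_hand_tally_four_readings(self):
        # class 1: 4 readings, one with scalloping (f5 = 2): (3+1)/(4+2), (1+1)/(4+2)
        rows = [((1,) * 9, 1)] * 3 + [((1, 1, 1, 1, 2, 1, 1, 1, 1), 1)]
        model = fit(make_dataset(rows), "severity")
        probs = model.table(1, 5).probs
        assert probs == pytest.approx([2 / 3, 1 / 3], abs=ATOL)

    def test_all_18_tables_normalised(self, fixture_dataset):
        model = fit(fixture_dataset, "severity")
        assert len(model.tables) == 18
        for tab in model.tables.values():
            assert tab.probs.sum() == pytest.approx(1.0, abs=ATOL)
            assert sum(tab.counts) == tab.N

    def test_alpha_must_be_positive(self, fixture_dataset):
        for alpha in (0.0, -1.0):
            with pytest.raises(ValueError, match="alpha"):
                fit(fixture_dataset, "severity", alpha=alpha)

    def test_unlabelled_reading_rejected(self, schema):
        from sbce_bayes import Reading

        data = Dataset(schema=schema, readings=(Reading(values=(1,) * 9),))
        with pytest.raises(ValueError):
            fit(data, "severity")


class TestPosteriorPredictive:
    def test_untrained_three_level_feature_is_uniform(self):
        model = empty_model()
        for k in (1, 2, 3):
            assert posterior_predictive(model, 1, 2, k) == pytest.approx(1 / 3, abs=ATOL)

    def test_known_counts(self):
        # N = 50 readings, 40 at level 1 on a binary feature: (40+1)/(50+2)
        schema = canonical_schema()
        counts = {c: [[0] * K for K in schema.level_counts] for c in (1, 2)}
        counts[2][0] = [40, 10]
        model = ClassConditionalModel.from_counts(schema, "severity", counts)
        assert posterior_predictive(model, 2, 1, 1) == pytest.approx(41 / 52, abs=ATOL)

    def test_out_of_range_queries_rejected(self):
        model = empty_model()
        with pytest.raises(ValueError):
            posterior_predictive(model, 1, 1, 3)
        with pytest.raises(ValueError):
            posterior_predictive(model, 1, 10, 1)
        with pytest.raises(ValueError):
            posterior_predictive(model, 3, 1, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_tally(self, seed, schema):
        """Fitted tables equal an independent counting pass, exactly."""
        rng = np.random.default_rng(seed)
        rows = random_rows(rng, int(rng.integers(1, 31)))
        model = fit(make_dataset(rows), "severity")
        for c in (1, 2):
            for i, K in enumerate(schema.level_counts, start=1):
                for k in range(1, K + 1):
                    assert posterior_predictive(model, c, i, k) == brute_force_posterior(
                        rows, c, i, k, K
                    )


class TestReadingLikelihood:
    def test_untrained_model_uniform_likelihood(self):
        # eight binary features and one ternary: (1/2)^8 * (1/3) = 1/768
        model = empty_model()
        for values in [(1,) * 9, (2, 3, 2, 2, 2, 2, 2, 2, 2), (1, 2, 1, 2, 1, 2, 1, 2, 1)]:
            assert reading_likelihood(model, values, 1) == pytest.approx(1 / 768, abs=ATOL)

    def test_factorises_over_features(self, fixture_dataset):
        model = fit(fixture_dataset, "severity")
        r = fixture_dataset[3]
        for c in (1, 2):
            product = math.prod(
                posterior_predictive(model, c, i, k)
                for i, k in enumerate(r.values, start=1)
            )
            assert reading_likelihood(model, r, c) == pytest.approx(product, rel=ATOL)

    def test_log_companion_consistent(self, fixture_dataset):
        model = fit(fixture_dataset, "disease")
        for r in fixture_dataset.readings[:10]:
            for c in (1, 2):
                assert math.exp(reading_log_likelihood(model, r, c)) == pytest.approx(
                    reading_likelihood(model, r, c), rel=1e-12
                )

    def test_positive_for_unseen_patterns(self):
        # a level combination absent from training still has positive likelihood
        data = make_dataset([((1,) * 9, 1), ((1,) * 9, 2)])
        model = fit(data, "severity")
        assert reading_likelihood(model, (2, 3, 2, 2, 2, 2, 2, 2, 2), 1) > 0


class TestSmoothing:
    @given(
        counts=st.lists(st.integers(0, 50), min_size=2, max_size=4),
        alphas=st.tuples(
            st.floats(0.1, 10, allow_nan=False), st.floats(0.1, 10, allow_nan=False)
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_larger_alpha_moves_toward_uniform(self, counts, alphas):
        """For fixed counts, increasing alpha shrinks the max-norm distance
        to the uniform distribution."""
        from sbce_bayes import CategoricalPosterior

        lo, hi = sorted(alphas)
        K = len(counts)

        def dist(alpha):
            tab = CategoricalPosterior(1, 1, tuple(counts), (alpha,) * K)
            return np.abs(tab.probs - 1 / K).max()

        assert dist(hi) <= dist(lo) + ATOL


class TestHistogramReport:
    def test_untrained_model_has_zero_contrasts(self):
        diff = abnormal_mass_difference(empty_model())
        assert np.allclose(diff["abnormal_mass_difference"], 0.0, atol=ATOL)

    def test_groups_normalised(self, fixture_dataset):
        hist = feature_histograms(fit(fixture_dataset, "severity"))
        sums = hist.groupby(["feature", "class_code"])["probability"].sum()
        assert len(sums) == 18
        assert np.allclose(sums, 1.0, atol=ATOL)

    def test_recovers_generating_histogram(self):
        """Fitted histograms approach the generating lambda at large n."""
        cfg = default_config("severity", n_readings=10_000, seed=11)
        model = fit(generate(cfg), "severity")
        for c in (1, 2):
            for i in range(1, 10):
                err = np.abs(model.table(c, i).probs - cfg.lambda_true[c][i - 1]).max()
                assert err < 0.02

    def test_class_labels_match_task(self, fixture_dataset):
        hist = feature_histograms(fit(fixture_dataset, "disease"))
        assert set(hist["class_label"]) == {"SNVA", "CD"}


class TestSerialization:
    def test_round_trip(self, tmp_path, fixture_dataset):
        model = fit(fixture_dataset, "severity", alpha=2.0)
        path = tmp_path / "model.yaml"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.task == model.task
        assert loaded.alpha == model.alpha
        for key, tab in model.tables.items():
            assert loaded.tables[key].counts == tab.counts
            assert np.allclose(loaded.tables[key].probs, tab.probs, atol=ATOL)

    def test_deterministic_bytes(self, tmp_path, fixture_dataset):
        model = fit(fixture_dataset, "severity")
        p1, p2 = tmp_path / "a.yaml", tmp_path / "b.yaml"
        save_model(model, p1)
        save_model(model, p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_cross_check_against_sklearn_categorical_nb(fixture_dataset):
    """Independent route: sklearn's CategoricalNB with alpha = 1 and empirical
    class priors reproduces the naive-Bayes posterior computed here with the
    raw (unsmoothed) prior."""
    from sklearn.naive_bayes import CategoricalNB

    from sbce_bayes import ClassPrior, predict_naive_bayes

    X = np.array([r.values for r in fixture_dataset]) - 1
    y = np.array([r.class_code("severity") for r in fixture_dataset])
    min_categories = np.array(fixture_dataset.schema.level_counts)
    clf = CategoricalNB(alpha=1.0, min_categories=min_categories).fit(X, y)
    probs = clf.predict_proba(X)

    model = fit(fixture_dataset, "severity")
    from sbce_bayes import class_counts

    prior = ClassPrior("severity", class_counts(fixture_dataset, "severity"), smoothed=False)
    ours = np.array(
        [predict_naive_bayes(model, prior, r).per_class_posterior for r in fixture_dataset]
    )
    np.testing.assert_allclose(ours, probs, atol=1e-9)
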