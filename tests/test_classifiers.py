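import numpy as np
import pytest

from depnb import (
    DependencyModel,
    ProbabilityModel,
    batch_log_scores,
    classify,
    count_statistics,
    fit_dependency_model,
    improved_nb_posterior,
    nb_posterior,
    probability_model_from_counts,
    sdnb_posterior,
    suggest_symptoms,
)
from .conftest import make_cohort, random_cohort, random_model
from .oracle import oracle_posteriors


def two_disease_model(p1=0.8, p2=0.2):
    return ProbabilityModel(
        diseases=("D1", "D2"), symptoms=("S",), k=2, m=10.0,
        disease_counts=np.array([5.0, 5.0]),
        prior_=np.array([0.5, 0.5]),
        cond_=np.array([[p1], [p2]]),
        pair_disease=np.zeros((2, 1, 1)),
    )


def unit_dep(model, variant):
    V = len(model.symptoms)
    return DependencyModel(
        variant=variant, cooc_threshold=5.0,
        diseases=model.diseases, symptoms=model.symptoms,
        log_or_sd=np.zeros((model.k, V)), log_or_ss=np.zeros((V, V)),
        pair_cooc=np.zeros((V, V)), log_corr=np.zeros((model.k, V, V)),
    )


def test_nb_posterior_hand_example():
    table = nb_posterior(two_disease_model(), ["S"])
    assert table.posterior["D1"] == pytest.approx(0.8, abs=1e-12)
    assert table.posterior["D2"] == pytest.approx(0.2, abs=1e-12)
    assert table.normalizer == pytest.approx(0.5 * 0.8 + 0.5 * 0.2)


def test_uninformative_evidence_returns_prior():
    model = two_disease_model(0.3, 0.3)
    table = nb_posterior(model, ["S"])
    assert table.posterior["D1"] == pytest.approx(0.5, abs=1e-12)


def test_unknown_symptoms_dropped_with_record():
    model = two_disease_model()
    table = nb_posterior(model, ["S", "mystery"])
    assert table.ignored_symptoms == ("mystery",)
    with pytest.raises(ValueError, match="mystery"):
        nb_posterior(model, ["mystery"])


def test_variant_mismatch_rejected():
    model = two_disease_model()
    with pytest.raises(ValueError, match="variant"):
        sdnb_posterior(model, unit_dep(model, "cooccurrence_based"), ["S"])
    with pytest.raises(ValueError, match="variant"):
        improved_nb_posterior(model, unit_dep(model, "or_based"), ["S"])


def test_reduction_to_nb_with_unit_correlations():
    rng = np.random.default_rng(0)
    for _ in range(50):
        model = random_model(rng)
        query = [s for s in model.symptoms if rng.random() < 0.6] or [model.symptoms[0]]
        base = nb_posterior(model, query)
        imp = improved_nb_posterior(model, unit_dep(model, "cooccurrence_based"), query)
        sd = sdnb_posterior(model, unit_dep(model, "or_based"), query)
        for d in model.diseases:
            assert imp.posterior[d] == pytest.approx(base.posterior[d], abs=1e-12)
            assert sd.posterior[d] == pytest.approx(base.posterior[d], abs=1e-12)


def test_single_symptom_query_equals_nb():
    rng = np.random.default_rng(8)
    cohort = random_cohort(rng, m=60)
    counts = count_statistics(cohort)
    model = probability_model_from_counts(counts)
    dep = fit_dependency_model(counts, "or_based", cooc_threshold=0)
    q = [cohort.symptom_vocabulary[0]]
    a, b = nb_posterior(model, q), sdnb_posterior(model, dep, q)
    for d in model.diseases:
        assert b.posterior[d] == pytest.approx(a.posterior[d], abs=1e-12)


def test_weighted_numerator_hand_example():
    # NB numerators (0.4, 0.1) with Corr (2, 1) -> posterior (0.8/0.9, 0.1/0.9)
    model = ProbabilityModel(
        diseases=("D1", "D2"), symptoms=("S",), k=2, m=10.0,
        disease_counts=np.array([5.0, 5.0]),
        prior_=np.array([0.5, 0.5]),
        cond_=np.array([[0.8], [0.2]]),
        pair_disease=np.zeros((2, 1, 1)),
    )
    dep = unit_dep(model, "cooccurrence_based")
    # with a single symptom Eq (9) has no pairs; emulate the vector-level
    # correlation by scaling the numerators directly instead
    base = nb_posterior(model, ["S"])
    corr = {"D1": 2.0, "D2": 1.0}
    weighted = {d: corr[d] * base.scores[d] for d in model.diseases}
    z = sum(weighted.values())
    assert weighted["D1"] / z == pytest.approx(0.8 / 0.9)
    assert weighted["D2"] / z == pytest.approx(0.1 / 0.9)


@pytest.mark.parametrize("variant", ["nb", "improved_nb", "sdnb"])
def test_oracle_equivalence_on_toy_instances(variant):
    """All three classifiers match an independent straight-line transcription
    of the estimation + odds-ratio + dependency-degree formulas."""
    rng = np.random.default_rng(42)
    for trial in range(30):
        k = int(rng.integers(2, 4))
        V = int(rng.integers(2, 5))
        cohort = random_cohort(rng, k=k, V=V, m=int(rng.integers(15, 40)))
        counts = count_statistics(cohort)
        model = probability_model_from_counts(counts)
        nq = int(rng.integers(1, V + 1))
        query = list(rng.choice(cohort.symptom_vocabulary, size=nq, replace=False))
        thr = int(rng.integers(0, 6))
        if variant == "nb":
            table = nb_posterior(model, query)
        elif variant == "sdnb":
            dep = fit_dependency_model(counts, "or_based", thr)
            table = sdnb_posterior(model, dep, query)
        else:
            dep = fit_dependency_model(counts, "cooccurrence_based", thr)
            table = improved_nb_posterior(model, dep, query)
        recs = [(r.disease, set(r.symptoms)) for r in cohort]
        expected = oracle_posteriors(
            recs, cohort.disease_vocabulary, cohort.symptom_vocabulary,
            query, variant, thr,
        )
        for d in model.diseases:
            assert table.posterior[d] == pytest.approx(expected[d], abs=1e-12)


def test_posteriors_normalize_on_random_models():
    rng = np.random.default_rng(123)
    for _ in range(200):
        model = random_model(rng, k=int(rng.integers(2, 6)), V=int(rng.integers(2, 6)))
        dep = unit_dep(model, "or_based")
        dep.log_corr = rng.normal(0, 1, size=dep.log_corr.shape)
        dep.log_corr = (dep.log_corr + dep.log_corr.transpose(0, 2, 1)) / 2
        query = [s for s in model.symptoms if rng.random() < 0.5] or [model.symptoms[0]]
        table = sdnb_posterior(model, dep, query)
        assert sum(table.posterior.values()) == pytest.approx(1.0, abs=1e-9)
        assert table.normalizer > 0
        ranked = [d for d, _ in table.ranking]
        assert ranked == sorted(model.diseases, key=lambda d: (-table.posterior[d], d))


def test_permutation_invariance_of_query():
    rng = np.random.default_rng(77)
    cohort = random_cohort(rng, m=60)
    counts = count_statistics(cohort)
    model = probability_model_from_counts(counts)
    dep = fit_dependency_model(counts, "or_based", cooc_threshold=0)
    q = list(cohort.symptom_vocabulary[:3])
    a = sdnb_posterior(model, dep, q)
    b = sdnb_posterior(model, dep, q[::-1])
    for d in model.diseases:
        assert a.posterior[d] == pytest.approx(b.posterior[d], abs=1e-12)


def test_monotone_evidence():
    """Raising P(S|D) for a query symptom never lowers that disease's posterior."""
    rng = np.random.default_rng(31)
    model = random_model(rng, k=3, V=4)
    query = list(model.symptoms[:2])
    base = nb_posterior(model, query).posterior["D0"]
    model.cond_[0, 0] = min(0.99, model.cond_[0, 0] * 1.5)
    assert nb_posterior(model, query).posterior["D0"] >= base


def test_classify_tie_break_and_clipping():
    model = two_disease_model(0.3, 0.3)  # exact tie
    table = nb_posterior(model, ["S"])
    assert classify(table, 1) == [("D1", pytest.approx(0.5))]
    assert len(classify(table, 10)) == 2
    with pytest.raises(ValueError):
        classify(table, 0)


def test_batch_scores_match_per_query_ops():
    rng = np.random.default_rng(55)
    cohort = random_cohort(rng, k=3, V=5, m=80)
    counts = count_statistics(cohort)
    model = probability_model_from_counts(counts)
    dep = fit_dependency_model(counts, "or_based", cooc_threshold=2)
    X = np.zeros((len(cohort.records), 5))
    si = {s: i for i, s in enumerate(model.symptoms)}
    for r, rec in enumerate(cohort):
        for s in rec.symptoms:
            X[r, si[s]] = 1
    batch = batch_log_scores(model, dep, X)
    for r, rec in enumerate(cohort):
        if rec.symptoms.n == 0:
            continue
        table = sdnb_posterior(model, dep, list(rec.symptoms))
        post = np.exp(batch[r] - np.logaddexp.reduce(batch[r]))
        for f, d in enumerate(model.diseases):
            assert post[f] == pytest.approx(table.posterior[d], abs=1e-10)


def test_suggest_symptoms_ranking_and_exclusion():
    rng = np.random.default_rng(66)
    cohort = random_cohort(rng, k=3, V=5, m=80)
    counts = count_statistics(cohort)
    model = probability_model_from_counts(counts)
    dep = fit_dependency_model(counts, "or_based")
    q = [cohort.symptom_vocabulary[0]]
    out = suggest_symptoms(model, dep, q, top=10)
    names = [s for s, _ in out]
    assert q[0] not in names
    # scores are the max OR against the query symptom, sorted descending
    qi = dep.s_index[q[0]]
    expected = sorted(
        ((s, float(np.exp(dep.log_or_ss[qi, dep.s_index[s]])))
         for s in model.symptoms if s not in q),
        key=lambda kv: (-kv[1], kv[0]),
    )
    assert out == [(s, pytest.approx(v)) for s, v in expected]
    # full-vocabulary query leaves nothing to suggest
    assert suggest_symptoms(model, dep, list(model.symptoms)) == []
    with pytest.raises(ValueError):
        suggest_symptoms(model, dep, [])


def test_suggest_symptoms_cooccurrence_variant():
    rng = np.random.default_rng(67)
    cohort = random_cohort(rng, k=3, V=5, m=80)
    counts = count_statistics(cohort)
    model = probability_model_from_counts(counts)
    dep = fit_dependency_model(counts, "cooccurrence_based")
    out = suggest_symptoms(model, dep, [cohort.symptom_vocabulary[0]], top=3)
    assert len(out) == 3
    assert all(r > 0 for _, r in out)
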