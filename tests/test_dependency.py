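import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depnb import (
    ContingencyTable2x2,
    corr_cooccurrence,
    corr_or,
    count_statistics,
    fit_dependency_model,
    odds_ratio,
    or_symptom_disease,
    or_symptom_symptom,
    probability_model_from_counts,
    vector_dependency,
    desk_spec,
    desk_background_pairs,
    generate_cohort,
)
from .conftest import make_cohort, random_cohort


def test_odds_ratio_hand_values():
    assert odds_ratio(ContingencyTable2x2(30, 10, 20, 40)) == pytest.approx(6.0)
    assert odds_ratio(ContingencyTable2x2(25, 25, 25, 25)) == pytest.approx(1.0)
    # zero cell triggers the Haldane-Anscombe correction on all four cells
    assert odds_ratio(ContingencyTable2x2(5, 0, 5, 10)) == pytest.approx(
        (5.5 * 10.5) / (0.5 * 5.5)
    )


def test_odds_ratio_errors():
    with pytest.raises(ValueError):
        odds_ratio(ContingencyTable2x2(0, 0, 0, 0))
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 1, 1, 1)


@given(
    a=st.integers(1, 200), b=st.integers(1, 200),
    c=st.integers(1, 200), d=st.integers(1, 200),
)
@settings(deadline=None, max_examples=100, derandomize=True)
def test_odds_ratio_transpose_symmetry(a, b, c, d):
    """OR is invariant under transposing the table (swapping the two variables)."""
    t1 = odds_ratio(ContingencyTable2x2(a, b, c, d))
    t2 = odds_ratio(ContingencyTable2x2(a, c, b, d))
    assert t1 == pytest.approx(t2, rel=1e-12)
    assert t1 > 0 and math.isfinite(t1)


def test_or_symptom_disease_matches_explicit_table():
    rng = np.random.default_rng(4)
    cohort = random_cohort(rng, m=40)
    c = count_statistics(cohort)
    for s in cohort.symptom_vocabulary:
        for d in cohort.disease_vocabulary:
            expected = odds_ratio(ContingencyTable2x2(*c.cell_symptom_disease(s, d)))
            assert or_symptom_disease(c, s, d) == pytest.approx(expected)


def test_or_symptom_symptom_symmetry_and_direction():
    rows = [(f"r{i}", "D", ["a", "b"]) for i in range(6)]
    rows += [(f"q{i}", "E", []) for i in range(6)]
    c = count_statistics(make_cohort(rows, symptom_vocab=["a", "b"]))
    v = or_symptom_symptom(c, "a", "b")
    assert v == or_symptom_symptom(c, "b", "a")
    assert v > 1  # perfectly coupled pair
    with pytest.raises(ValueError):
        or_symptom_symptom(c, "a", "a")


def test_enriched_symptom_has_or_above_one():
    rows = [(f"r{i}", "D", ["s"]) for i in range(5)]
    rows += [(f"q{i}", "E", []) for i in range(5)]
    c = count_statistics(make_cohort(rows))
    assert or_symptom_disease(c, "s", "D") > 1


def test_corr_or_is_ratio_of_ors_above_threshold():
    rng = np.random.default_rng(9)
    cohort = random_cohort(rng, k=2, V=3, m=60)
    c = count_statistics(cohort)
    for s1 in cohort.symptom_vocabulary:
        for s2 in cohort.symptom_vocabulary:
            if s1 >= s2:
                continue
            for d in cohort.disease_vocabulary:
                got = corr_or(c, s1, s2, d, cooc_threshold=0)
                expected = or_symptom_symptom(c, s1, s2) / (
                    or_symptom_disease(c, s1, d) * or_symptom_disease(c, s2, d)
                )
                assert got == pytest.approx(expected, rel=1e-12)


def test_under_threshold_pairs_are_independent():
    # pair co-occurs in exactly 4 records: below the default threshold of 5
    rows = [(f"r{i}", "D", ["a", "b"]) for i in range(4)]
    rows += [(f"q{i}", "E", ["a"] if i % 2 else ["b"]) for i in range(10)]
    c = count_statistics(make_cohort(rows))
    assert c.count_pair("a", "b") == 4
    assert corr_or(c, "a", "b", "D") == 1.0
    assert corr_or(c, "a", "b", "D", cooc_threshold=4) != 1.0
    model = probability_model_from_counts(c)
    assert corr_cooccurrence(model, "a", "b", "D") == 1.0


def test_corr_cooccurrence_matches_definition_and_sign():
    rng = np.random.default_rng(14)
    cohort = random_cohort(rng, k=2, V=3, m=80)
    c = count_statistics(cohort)
    model = probability_model_from_counts(c)
    for s1 in cohort.symptom_vocabulary:
        for s2 in cohort.symptom_vocabulary:
            if s1 >= s2:
                continue
            for d in cohort.disease_vocabulary:
                got = corr_cooccurrence(model, s1, s2, d, cooc_threshold=0)
                pc = model.pair_conditional(s1, s2, d)
                prod = model.conditional(s1, d) * model.conditional(s2, d)
                assert got == pytest.approx(pc / prod, rel=1e-12)
                assert (got > 1) == (pc > prod)
                assert got > 0 and math.isfinite(got)


def test_vector_dependency_hand_values():
    pw = {
        frozenset(("a", "b")): 2.0,
        frozenset(("a", "c")): 0.5,
        frozenset(("b", "c")): 1.0,
    }
    assert vector_dependency(pw, ["a", "b", "c"]) == pytest.approx(1.0)
    assert vector_dependency({}, ["a"]) == 1.0
    assert vector_dependency({frozenset(("a", "b")): 4.0}, ["a", "b"]) == pytest.approx(4.0)


def test_vector_dependency_missing_pair_is_named():
    with pytest.raises(KeyError, match="'b'"):
        vector_dependency({}, ["a", "b"])


@given(st.lists(st.floats(0.1, 10.0), min_size=3, max_size=3), st.floats(0.5, 2.0))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_vector_dependency_permutation_and_scale(vals, c):
    pw = {
        frozenset(("a", "b")): vals[0],
        frozenset(("a", "c")): vals[1],
        frozenset(("b", "c")): vals[2],
    }
    base = vector_dependency(pw, ["a", "b", "c"])
    assert vector_dependency(pw, ["c", "a", "b"]) == pytest.approx(base, rel=1e-12)
    scaled = {k: c * v for k, v in pw.items()}
    assert vector_dependency(scaled, ["a", "b", "c"]) == pytest.approx(c * base, rel=1e-9)


def test_dependency_model_matches_pointwise_ops():
    rng = np.random.default_rng(21)
    cohort = random_cohort(rng, k=3, V=4, m=80)
    c = count_statistics(cohort)
    model = probability_model_from_counts(c)
    dep_or = fit_dependency_model(c, "or_based", cooc_threshold=3)
    dep_co = fit_dependency_model(c, "cooccurrence_based", cooc_threshold=3)
    for s1 in cohort.symptom_vocabulary:
        for s2 in cohort.symptom_vocabulary:
            if s1 >= s2:
                continue
            assert dep_or.or_symptom_symptom(s1, s2) == pytest.approx(
                or_symptom_symptom(c, s1, s2), rel=1e-9
            )
            for d in cohort.disease_vocabulary:
                assert dep_or.pair_correlation(s1, s2, d) == pytest.approx(
                    corr_or(c, s1, s2, d, 3), rel=1e-9
                )
                assert dep_co.pair_correlation(s1, s2, d) == pytest.approx(
                    corr_cooccurrence(model, s1, s2, d, 3), rel=1e-9
                )


def test_dependency_model_symmetry_and_positivity(desk_counts_null):
    counts, _ = desk_counts_null
    dep = fit_dependency_model(counts, "or_based")
    assert np.allclose(dep.log_corr, dep.log_corr.transpose(0, 2, 1))
    assert np.all(np.isfinite(dep.log_corr))
    assert np.all(np.isfinite(dep.log_or_ss))


def test_null_calibration_median_log_or(desk_counts_null):
    """With no injected couplings the typical pairwise log OR stays near 0."""
    counts, _ = desk_counts_null
    V = len(counts.symptoms)
    vals = []
    for i in range(V):
        for j in range(i + 1, V):
            vals.append(
                abs(math.log(or_symptom_symptom(counts, counts.symptoms[i], counts.symptoms[j])))
            )
    assert np.median(vals) <= 0.25


def test_independent_background_pairs_have_near_unit_or(desk_counts_null):
    counts, truth = desk_counts_null
    for s1, s2 in desk_background_pairs(truth.spec):
        assert 0.8 <= or_symptom_symptom(counts, s1, s2) <= 1.25


def test_coupled_pairs_detected_across_seeds():
    """rho=0.9 couplings show a larger odds-ratio correlation than designated
    independent background pairs for the leading disease (per seed)."""
    wins = 0
    for seed in range(5):
        spec = desk_spec(m=5000, rho=0.9, seed=seed)
        cohort, truth = generate_cohort(spec)
        c = count_statistics(cohort)
        coupled = [math.log(corr_or(c, a, b, "D000")) for a, b, _ in spec.couplings]
        bg = [
            math.log(corr_or(c, a, b, "D000"))
            for a, b in desk_background_pairs(truth.spec)
        ]
        if np.mean(coupled) > np.mean(bg):
            wins += 1
    assert wins >= 4


def test_clamp_limits_correlations():
    rng = np.random.default_rng(30)
    cohort = random_cohort(rng, k=2, V=3, m=60)
    c = count_statistics(cohort)
    dep = fit_dependency_model(c, "or_based", cooc_threshold=0, clamp=(0.5, 2.0))
    assert dep.log_corr.max() <= math.log(2.0) + 1e-12
    assert dep.log_corr.min() >= math.log(0.5) - 1e-12
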