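import numpy as np
import pytest

from depnb import (
    Cohort,
    DiagnosticRecord,
    SymptomVector,
    ProbabilityModel,
    count_statistics,
    probability_model_from_counts,
    desk_spec,
    generate_cohort,
)


def make_cohort(rows, disease_vocab=None, symptom_vocab=None):
    """rows: list of (record_id, disease, [symptoms])."""
    records = [
        DiagnosticRecord(rid, d, SymptomVector.from_iterable(syms))
        for rid, d, syms in rows
    ]
    return Cohort(records, disease_vocab, symptom_vocab)


def random_cohort(rng, k=3, V=4, m=30):
    """A small random cohort guaranteed to contain every disease and symptom."""
    diseases = [f"D{f}" for f in range(k)]
    symptoms = [f"S{v}" for v in range(V)]
    rows = []
    for r in range(m):
        d = diseases[int(rng.integers(k))]
        present = [s for s in symptoms if rng.random() < 0.45]
        rows.append((f"r{r}", d, present))
    return make_cohort(rows, diseases, symptoms)


def random_model(rng, k=4, V=5):
    """A random but valid ProbabilityModel (priors sum to 1, conds in (0,1))."""
    diseases = tuple(f"D{f}" for f in range(k))
    symptoms = tuple(f"S{v}" for v in range(V))
    prior = rng.dirichlet(np.ones(k))
    cond = rng.uniform(0.05, 0.95, size=(k, V))
    counts = rng.integers(5, 50, size=k).astype(float)
    pair = np.zeros((k, V, V))
    for f in range(k):
        M = rng.integers(0, 10, size=(V, V)).astype(float)
        M = np.triu(M, 1)
        pair[f] = M + M.T
    return ProbabilityModel(
        diseases=diseases, symptoms=symptoms, k=k, m=float(counts.sum()),
        disease_counts=counts, prior_=prior, cond_=cond, pair_disease=pair,
    )


@pytest.fixture
def tiny_cohort():
    return make_cohort(
        [
            ("r1", "flu", ["fever", "cough"]),
            ("r2", "flu", ["fever"]),
            ("r3", "flu", ["cough", "fatigue"]),
            ("r4", "cold", ["cough"]),
        ]
    )


@pytest.fixture(scope="session")
def desk_cohort_null():
    """Uncoupled desk-scale cohort (m=20,000, one fixed seed): the shared
    large fixture for calibration and recovery checks."""
    spec = desk_spec(m=20000, rho=0.0, seed=7)
    cohort, truth = generate_cohort(spec)
    return cohort, truth


@pytest.fixture(scope="session")
def desk_counts_null(desk_cohort_null):
    cohort, truth = desk_cohort_null
    return count_statistics(cohort), truth


@pytest.fixture(scope="session")
def desk_model_null(desk_counts_null):
    counts, truth = desk_counts_null
    return probability_model_from_counts(counts), truth
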