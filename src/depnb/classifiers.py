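"""Posterior computation for the three diagnostic model variants.

Given a query symptom vector S = {S_1..S_n}, each variant scores every
disease D_f with an unnormalized numerator

    score_f = Corr_{S|D_f} * P(D_f) * prod_j P(S_j | D_f)

where the dependency degree Corr is identically 1 for plain naive Bayes,
the geometric mean of co-occurrence pairwise correlations for the improved
variant, and the geometric mean of odds-ratio pairwise correlations for the
dependency-aware (SDNB) variant.  The evidence term P(S) is never estimated
from data: it is the sum of numerators over the k diseases, which makes the
posterior a proper distribution over the trained disease set.

The product runs over the symptoms *present* in the query only; absent
symptoms contribute no factor.  All products are accumulated in log-space.
Query symptoms missing from the model vocabulary are dropped with a warning
(recorded in ``PosteriorTable.ignored_symptoms``); a query with no known
symptom is an error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .cohort import SymptomVector
from .dependency import COOCCURRENCE_BASED, OR_BASED, DependencyModel
from .estimation import ProbabilityModel

__all__ = [
    "PosteriorTable",
    "nb_posterior",
    "improved_nb_posterior",
    "sdnb_posterior",
    "classify",
    "suggest_symptoms",
    "batch_log_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class PosteriorTable:
    """Normalized diagnostic posteriors for one query.

    ``normalizer`` is P(S), the sum of unnormalized numerators; ``ranking``
    sorts diseases by posterior descending with exact ties broken by disease
    identifier ascending (reproducibility).
    """

    diseases: tuple[str, ...]
    scores: dict[str, float]            # unnormalized numerators
    normalizer: float                   # P(S) = sum of scores
    posterior: dict[str, float]
    ranking: list[tuple[str, float]]
    ignored_symptoms: tuple[str, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "posteriors": self.posterior,
            "normalizer": self.normalizer,
            "ranking": [[d, p] for d, p in self.ranking],
            "ignored_symptoms": list(self.ignored_symptoms),
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), ensure_ascii=False), encoding="utf-8")
        return path


def _table_from_log_scores(
    diseases: Sequence[str], log_scores: np.ndarray, ignored: Sequence[str]
) -> PosteriorTable:
    log_z = float(logsumexp(log_scores))
    post = np.exp(log_scores - log_z)
    scores = {d: float(np.exp(log_scores[i])) for i, d in enumerate(diseases)}
    posterior = {d: float(post[i]) for i, d in enumerate(diseases)}
    ranking = sorted(posterior.items(), key=lambda kv: (-kv[1], kv[0]))
    return PosteriorTable(
        diseases=tuple(diseases),
        scores=scores,
        normalizer=float(np.exp(log_z)),
        posterior=posterior,
        ranking=ranking,
        ignored_symptoms=tuple(ignored),
    )


def _resolve_query(model: ProbabilityModel, query: SymptomVector | Iterable[str]):
    known, unknown = [], []
    for s in query:
        (known if s in model.s_index else unknown).append(s)
    if not known:
        raise ValueError(f"no query symptom is in the model vocabulary: {unknown!r}")
    if unknown:
        logger.warning("ignoring unknown query symptoms: %s", unknown)
    return known, unknown


def _nb_log_scores(model: ProbabilityModel, known: Sequence[str]) -> np.ndarray:
    idx = [model.s_index[s] for s in known]
    return np.log(model.prior_) + np.log(model.cond_[:, idx]).sum(axis=1)


def nb_posterior(
    model: ProbabilityModel, query: SymptomVector | Iterable[str]
) -> PosteriorTable:
    """Plain naive Bayes posterior (unit dependency degree)."""
    known, unknown = _resolve_query(model, query)
    return _table_from_log_scores(model.diseases, _nb_log_scores(model, known), unknown)


def _dependency_log_term(dep: DependencyModel, known: Sequence[str]) -> np.ndarray:
    """log Corr_{S|D_f} for every disease: mean of pairwise log correlations."""
    idx = [dep.s_index[s] for s in known]
    n = len(idx)
    if n <= 1:
        return np.zeros(dep.k)
    sub = dep.log_corr[np.ix_(range(dep.k), idx, idx)]
    tri = np.triu(np.ones((n, n)), k=1)
    return (sub * tri).sum(axis=(1, 2)) / (n * (n - 1) / 2)


def _weighted_posterior(
    model: ProbabilityModel,
    dep: DependencyModel,
    query: SymptomVector | Iterable[str],
    expected_variant: str,
) -> PosteriorTable:
    if dep.variant != expected_variant:
        raise ValueError(
            f"dependency model variant {dep.variant!r} does not match "
            f"required variant {expected_variant!r}"
        )
    known, unknown = _resolve_query(model, query)
    missing = [s for s in known if s not in dep.s_index]
    if missing:
        raise KeyError(f"symptoms missing from dependency model: {missing!r}")
    log_scores = _nb_log_scores(model, known)
    dep_term = _dependency_log_term(dep, known)
    order = [dep.d_index[d] for d in model.diseases]
    return _table_from_log_scores(model.diseases, log_scores + dep_term[order], unknown)


def improved_nb_posterior(
    model: ProbabilityModel,
    dep: DependencyModel,
    query: SymptomVector | Iterable[str],
) -> PosteriorTable:
    """Naive Bayes weighted by the co-occurrence dependency degree."""
    return _weighted_posterior(model, dep, query, COOCCURRENCE_BASED)


def sdnb_posterior(
    model: ProbabilityModel,
    dep: DependencyModel,
    query: SymptomVector | Iterable[str],
) -> PosteriorTable:
    """Naive Bayes weighted by the odds-ratio dependency degree."""
    return _weighted_posterior(model, dep, query, OR_BASED)


def classify(table: PosteriorTable, top: int = 1) -> list[tuple[str, float]]:
    """The ``top`` highest-posterior diseases (all of them if top > k)."""
    if top < 1:
        raise ValueError(f"top must be >= 1, got {top}")
    return table.ranking[:top]


def suggest_symptoms(
    model: ProbabilityModel,
    dep: DependencyModel,
    partial_query: SymptomVector | Iterable[str],
    top: int = 10,
) -> list[tuple[str, float]]:
    """Rank symptoms *not* in the query by association with the query symptoms.

    Relevance of candidate c is max over query symptoms q of OR(q, c) for the
    odds-ratio kernel, and max cohort-level lift P(q, c)/(P(q) P(c))
    (Haldane-smoothed cells) for the co-occurrence kernel.  Ties break
    lexicographically.
    """
    query = [s for s in partial_query]
    if not query:
        raise ValueError("partial query must contain at least one symptom")
    qidx = [dep.s_index[s] for s in query if s in dep.s_index]
    if not qidx:
        raise ValueError(f"no query symptom is in the dependency vocabulary: {query!r}")
    qset = set(query)
    candidates = [s for s in dep.symptoms if s not in qset]
    if not candidates:
        return []
    if dep.variant == OR_BASED:
        M = dep.log_or_ss
    else:
        # cohort-level lift P(q,c) / (P(q) P(c)) with half-count smoothing;
        # marginal symptom counts recovered exactly from the Laplace conditionals
        if model.pair_disease is None:
            raise ValueError("partial model: cannot rank suggestions without pair counts")
        N = model.pair_cooccurrence_counts()
        counts_sd = model.cond_ * (model.disease_counts[:, None] + model.k) - 1.0
        s_count = counts_sd.sum(axis=0)
        m = max(model.m, 1.0)
        M = np.log((N + 0.5) * m) - np.log(np.outer(s_count + 0.5, s_count + 0.5))
    scored = []
    for c in candidates:
        ci = dep.s_index[c]
        rel = float(np.exp(max(M[q, ci] for q in qidx)))
        scored.append((c, rel))
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return scored[:top]


def batch_log_scores(
    model: ProbabilityModel,
    dep: DependencyModel | None,
    X: np.ndarray,
) -> np.ndarray:
    """Vectorized unnormalized log scores for many queries at once.

    ``X`` is an (n_queries, V) 0/1 presence matrix aligned to
    ``model.symptoms``.  Equivalent to calling the per-query posterior ops row
    by row (tested), but fast enough for boosting and ROC evaluation.
    """
    X = np.asarray(X, dtype=float)
    base = np.log(model.prior_)[None, :] + X @ np.log(model.cond_).T
    if dep is None:
        return base
    order = [dep.s_index[s] for s in model.symptoms]
    n = X.sum(axis=1)
    npairs = n * (n - 1) / 2.0
    dep_term = np.zeros((X.shape[0], model.k))
    for f, d in enumerate(model.diseases):
        C = dep.log_corr[dep.d_index[d]][np.ix_(order, order)]
        dep_term[:, f] = ((X @ C) * X).sum(axis=1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        dep_term = np.where(npairs[:, None] > 0, dep_term / np.maximum(npairs, 1)[:, None], 0.0)
    return base + dep_term
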