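"""Odds-ratio and co-occurrence symptom-dependency machinery.

Naive Bayes assumes symptoms are conditionally independent given the disease.
This module quantifies how badly that assumption is violated for each symptom
pair and turns the violation into a multiplicative weight on the naive Bayes
numerator.  Two pairwise kernels are provided:

* odds-ratio based:  Corr_(Si,Sj)|Df = OR(S_i, S_j) / (OR(S_i, D_f) * OR(S_j, D_f))
  where OR(X, Y) = (a*d)/(b*c) on the cohort-level 2x2 presence/absence table;
* co-occurrence based:  Corr_(Si,Sj)|Df = P((S_i,S_j)|D_f) / (P(S_i|D_f) * P(S_j|D_f))
  with Laplace-smoothed terms (> 1 positively correlated, 1 independent).

A pair observed together in fewer than ``cooc_threshold`` training records
(default 5) is treated as independent (correlation exactly 1) as a denoising
measure.  The dependency degree of a whole symptom vector is the geometric
mean of its C(n, 2) pairwise correlations, computed in log-space so long
vectors with extreme correlations cannot under/overflow.

Zero cells are handled with the Haldane–Anscombe correction: 0.5 is added to
all four cells of a table, but only when at least one cell is zero, so fully
populated tables are never biased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np

from .cohort import SymptomVector
from .estimation import CountStatistics, ProbabilityModel, probability_model_from_counts

__all__ = [
    "ContingencyTable2x2",
    "DependencyModel",
    "odds_ratio",
    "or_symptom_disease",
    "or_symptom_symptom",
    "corr_or",
    "corr_cooccurrence",
    "vector_dependency",
    "fit_dependency_model",
]

OR_BASED = "or_based"
COOCCURRENCE_BASED = "cooccurrence_based"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cohort-level 2x2 table: a=#(X=1,Y=1), b=#(X=1,Y=0), c=#(X=0,Y=1), d=#(X=0,Y=0)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d


def odds_ratio(table: ContingencyTable2x2) -> float:
    """(a*d)/(b*c), Haldane–Anscombe corrected (+0.5 to all cells) iff a cell is 0."""
    if table.total <= 0:
        raise ValueError("empty contingency table")
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def or_symptom_disease(counts: CountStatistics, symptom: str, disease: str) -> float:
    """OR of the (S present/absent) x (disease is/is-not D_f) table; > 1 means
    S is enriched among D_f records (a risk factor)."""
    return odds_ratio(ContingencyTable2x2(*counts.cell_symptom_disease(symptom, disease)))


def or_symptom_symptom(counts: CountStatistics, s_i: str, s_j: str) -> float:
    """OR of the cohort-wide (S_i x S_j) presence table; symmetric in arguments."""
    if s_i == s_j:
        raise ValueError(f"need two distinct symptoms, got {s_i!r} twice")
    return odds_ratio(ContingencyTable2x2(*counts.cell_symptom_pair(s_i, s_j)))


def corr_or(
    counts: CountStatistics,
    s_i: str,
    s_j: str,
    disease: str,
    cooc_threshold: float = 5,
) -> float:
    """Odds-ratio pairwise correlation, or exactly 1 below the co-occurrence
    threshold."""
    if s_i == s_j:
        raise ValueError(f"need two distinct symptoms, got {s_i!r} twice")
    if counts.count_pair(s_i, s_j) < cooc_threshold:
        return 1.0
    return or_symptom_symptom(counts, s_i, s_j) / (
        or_symptom_disease(counts, s_i, disease)
        * or_symptom_disease(counts, s_j, disease)
    )


def corr_cooccurrence(
    model: ProbabilityModel,
    s_i: str,
    s_j: str,
    disease: str,
    cooc_threshold: float = 5,
) -> float:
    """Co-occurrence pairwise correlation P(pair|D)/(P(S_i|D) P(S_j|D)), or
    exactly 1 below the co-occurrence threshold."""
    if s_i == s_j:
        raise ValueError(f"need two distinct symptoms, got {s_i!r} twice")
    i, j = model._si(s_i), model._si(s_j)
    cooc = float(model.pair_cooccurrence_counts()[i, j])
    if cooc < cooc_threshold:
        return 1.0
    return model.pair_conditional(s_i, s_j, disease) / (
        model.conditional(s_i, disease) * model.conditional(s_j, disease)
    )


def vector_dependency(
    pairwise: Mapping[frozenset, float], symptoms: SymptomVector | Iterable[str]
) -> float:
    """Dependency degree of a symptom vector: the C(n,2)-th root of the product
    of all pairwise correlations (geometric mean, log-space).  Returns exactly
    1 for n <= 1 (no pairs: neutral element)."""
    syms = list(symptoms)
    n = len(syms)
    if n <= 1:
        return 1.0
    total = 0.0
    npairs = 0
    for s_i, s_j in combinations(syms, 2):
        key = frozenset((s_i, s_j))
        if key not in pairwise:
            raise KeyError(f"missing pairwise correlation for ({s_i!r}, {s_j!r})")
        total += math.log(pairwise[key])
        npairs += 1
    return math.exp(total / npairs)


def _log_or_tables(a, b, c, d):
    """Vectorized log OR with Haldane correction applied per table."""
    cells = np.stack([a, b, c, d])
    zero = cells.min(axis=0) <= 0
    corr = np.where(zero, 0.5, 0.0)
    a, b, c, d = (x + corr for x in (a, b, c, d))
    # diagonal entries of symptom-pair tables can go negative (a pair needs
    # two distinct symptoms); they are overwritten by the callers, so the log
    # may produce NaN there without consequence
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log(a) + np.log(d) - np.log(b) - np.log(c)


@dataclass
class DependencyModel:
    """Precomputed pairwise symptom-dependency weights for one kernel.

    ``log_corr[f, i, j]`` is the log pairwise correlation of symptoms (i, j)
    given disease f, already zeroed below the co-occurrence threshold.
    """

    variant: str
    cooc_threshold: float
    diseases: tuple[str, ...]
    symptoms: tuple[str, ...]
    log_or_sd: np.ndarray       # (k, V) log OR(S, D_f)
    log_or_ss: np.ndarray       # (V, V) log OR(S_i, S_j), symmetric, diag 0
    pair_cooc: np.ndarray       # (V, V) cohort-wide co-occurrence counts
    log_corr: np.ndarray        # (k, V, V) thresholded log correlations
    clamp: tuple[float, float] | None = None

    d_index: dict[str, int] = field(init=False, repr=False)
    s_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.d_index = {d: i for i, d in enumerate(self.diseases)}
        self.s_index = {s: i for i, s in enumerate(self.symptoms)}

    @property
    def k(self) -> int:
        return len(self.diseases)

    def or_symptom_disease(self, symptom: str, disease: str) -> float:
        return float(np.exp(self.log_or_sd[self.d_index[disease], self.s_index[symptom]]))

    def or_symptom_symptom(self, s_i: str, s_j: str) -> float:
        return float(np.exp(self.log_or_ss[self.s_index[s_i], self.s_index[s_j]]))

    def pair_correlation(self, s_i: str, s_j: str, disease: str) -> float:
        if s_i == s_j:
            raise ValueError(f"need two distinct symptoms, got {s_i!r} twice")
        return float(
            np.exp(self.log_corr[self.d_index[disease], self.s_index[s_i], self.s_index[s_j]])
        )

    def pairwise_map(self, disease: str) -> dict[frozenset, float]:
        """All pairwise correlations for one disease as a {frozenset: value} map."""
        f = self.d_index[disease]
        out: dict[frozenset, float] = {}
        V = len(self.symptoms)
        for i in range(V):
            for j in range(i + 1, V):
                out[frozenset((self.symptoms[i], self.symptoms[j]))] = float(
                    np.exp(self.log_corr[f, i, j])
                )
        return out

    def vector_dependency(self, symptoms: SymptomVector | Iterable[str], disease: str) -> float:
        """Dependency degree of a vector under this model's kernel."""
        idx = [self.s_index[s] for s in symptoms]
        n = len(idx)
        if n <= 1:
            return 1.0
        f = self.d_index[disease]
        sub = self.log_corr[np.ix_([f], idx, idx)][0]
        return float(np.exp(np.triu(sub, k=1).sum() / (n * (n - 1) / 2)))

    # -- serialization --------------------------------------------------------
    def to_json_dict(self) -> dict:
        V = len(self.symptoms)
        or_ss = []
        corr = []
        for i in range(V):
            for j in range(i + 1, V):
                or_ss.append(
                    [self.symptoms[i], self.symptoms[j],
                     float(self.log_or_ss[i, j]), float(self.pair_cooc[i, j])]
                )
                if self.pair_cooc[i, j] >= self.cooc_threshold:
                    for f, d in enumerate(self.diseases):
                        corr.append(
                            [self.symptoms[i], self.symptoms[j], d,
                             float(self.log_corr[f, i, j])]
                        )
        return {
            "variant": self.variant,
            "cooc_threshold": self.cooc_threshold,
            "symptoms": list(self.symptoms),
            "clamp": list(self.clamp) if self.clamp else None,
            "or_sd": {
                d: {s: float(self.log_or_sd[f, v]) for v, s in enumerate(self.symptoms)}
                for f, d in enumerate(self.diseases)
            },
            "or_ss": or_ss,
            "corr": corr,
        }

    @classmethod
    def from_json_dict(cls, obj: Mapping) -> "DependencyModel":
        diseases = tuple(obj["or_sd"].keys())
        symptoms = tuple(obj["symptoms"])
        k, V = len(diseases), len(symptoms)
        si = {s: i for i, s in enumerate(symptoms)}
        di = {d: i for i, d in enumerate(diseases)}
        log_or_sd = np.array(
            [[obj["or_sd"][d][s] for s in symptoms] for d in diseases]
        )
        log_or_ss = np.zeros((V, V))
        pair_cooc = np.zeros((V, V))
        for s1, s2, v, cnt in obj["or_ss"]:
            i, j = si[s1], si[s2]
            log_or_ss[i, j] = log_or_ss[j, i] = v
            pair_cooc[i, j] = pair_cooc[j, i] = cnt
        log_corr = np.zeros((k, V, V))
        for s1, s2, d, v in obj["corr"]:
            i, j, f = si[s1], si[s2], di[d]
            log_corr[f, i, j] = log_corr[f, j, i] = v
        clamp = tuple(obj["clamp"]) if obj.get("clamp") else None
        return cls(
            variant=obj["variant"],
            cooc_threshold=float(obj["cooc_threshold"]),
            diseases=diseases,
            symptoms=symptoms,
            log_or_sd=log_or_sd,
            log_or_ss=log_or_ss,
            pair_cooc=pair_cooc,
            log_corr=log_corr,
            clamp=clamp,
        )


def fit_dependency_model(
    counts: CountStatistics,
    variant: str = OR_BASED,
    cooc_threshold: float = 5,
    clamp: tuple[float, float] | None = None,
) -> DependencyModel:
    """Build the full pairwise-correlation tensor for one kernel.

    ``clamp=(lo, hi)`` optionally clips pairwise correlations into [lo, hi]
    (off by default; a robustness knob, not part of the base method).
    """
    if variant not in (OR_BASED, COOCCURRENCE_BASED):
        raise ValueError(f"unknown dependency variant {variant!r}")
    k, V = counts.k, len(counts.symptoms)
    m = counts.m

    # OR(S, D_f) for every symptom/disease
    a = counts.symptom_disease
    b = counts.symptom_counts[None, :] - a
    c = counts.disease_counts[:, None] - a
    d = m - counts.symptom_counts[None, :] - counts.disease_counts[:, None] + a
    log_or_sd = _log_or_tables(a, b, c, d)

    # OR(S_i, S_j) cohort-wide
    N = counts.pair_counts
    s = counts.symptom_counts
    a2 = N
    b2 = s[:, None] - N
    c2 = s[None, :] - N
    d2 = m - s[:, None] - s[None, :] + N
    log_or_ss = _log_or_tables(a2, b2, c2, d2)
    np.fill_diagonal(log_or_ss, 0.0)

    above = counts.pair_counts >= cooc_threshold
    np.fill_diagonal(above, False)

    if variant == OR_BASED:
        log_corr = (
            log_or_ss[None, :, :]
            - log_or_sd[:, :, None]
            - log_or_sd[:, None, :]
        )
    else:
        model = probability_model_from_counts(counts)
        log_pair = np.log(counts.pair_disease + 1.0) - np.log(
            counts.disease_counts + counts.k
        )[:, None, None]
        log_cond = np.log(model.cond_)
        log_corr = log_pair - log_cond[:, :, None] - log_cond[:, None, :]
    log_corr = np.where(above[None, :, :], log_corr, 0.0)
    if clamp is not None:
        lo, hi = clamp
        log_corr = np.clip(log_corr, math.log(lo), math.log(hi))
    # keep exact symmetry and a zero diagonal
    log_corr = (log_corr + log_corr.transpose(0, 2, 1)) / 2.0
    for f in range(k):
        np.fill_diagonal(log_corr[f], 0.0)

    return DependencyModel(
        variant=variant,
        cooc_threshold=float(cooc_threshold),
        diseases=counts.diseases,
        symptoms=counts.symptoms,
        log_or_sd=log_or_sd,
        log_or_ss=log_or_ss,
        pair_cooc=counts.pair_counts.copy(),
        log_corr=log_corr,
        clamp=clamp,
    )
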