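"""Count statistics and Laplace-corrected probability estimation.

Training starts from sufficient statistics over the cohort: how many records
carry each disease, each (symptom, disease) combination, and each
(symptom-pair, disease) combination, plus cohort-wide 2x2 cell counts for any
symptom/disease or symptom/symptom pair.  All counts are weight sums so the
same code serves both plain fitting (unit weights) and boosting (bootstrap
multiplicities / sample weights).

Probabilities use the Laplace correction with the number of diseases ``k`` as
the denominator constant:

    P(D_f)        = (#D_f + 1) / (m + k)
    P(S | D_f)    = (#(S, D_f) + 1) / (#D_f + k)
    P(S_i, S_j | D_f) = (#(S_i, S_j, D_f) + 1) / (#D_f + k)

which keeps every estimate strictly inside (0, 1) for finite counts.  Note the
``+k`` is used even though the symptom attribute is binary; that is the
smoothing convention this method is defined with, and it is isolated here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import Cohort

__all__ = [
    "CountStatistics",
    "ProbabilityModel",
    "count_statistics",
    "disease_prior",
    "symptom_conditional",
    "pair_conditional",
    "fit_probability_model",
    "probability_model_from_counts",
]


@dataclass
class CountStatistics:
    """Weighted sufficient statistics of a cohort.

    Arrays are indexed by the vocabulary orderings in ``diseases`` /
    ``symptoms``; name-based accessors are provided for all spec'd cells.
    """

    diseases: tuple[str, ...]
    symptoms: tuple[str, ...]
    m: float                       # total weight (== record count at unit weights)
    n_records: int
    disease_counts: np.ndarray     # (k,)   weight with disease D_f
    symptom_counts: np.ndarray     # (V,)   cohort-wide weight with S present
    symptom_disease: np.ndarray    # (k, V) weight with disease D_f and S present
    pair_counts: np.ndarray        # (V, V) cohort-wide weight with both present
    pair_disease: np.ndarray       # (k, V, V) same, restricted to disease D_f

    d_index: dict[str, int] = field(init=False, repr=False)
    s_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.d_index = {d: i for i, d in enumerate(self.diseases)}
        self.s_index = {s: i for i, s in enumerate(self.symptoms)}

    @property
    def k(self) -> int:
        return len(self.diseases)

    # -- name-based accessors -------------------------------------------------
    def _di(self, disease: str) -> int:
        try:
            return self.d_index[disease]
        except KeyError:
            raise KeyError(f"unknown disease {disease!r}") from None

    def _si(self, symptom: str) -> int:
        try:
            return self.s_index[symptom]
        except KeyError:
            raise KeyError(f"unknown symptom {symptom!r}") from None

    def count_disease(self, disease: str) -> float:
        return float(self.disease_counts[self._di(disease)])

    def count_symptom(self, symptom: str) -> float:
        return float(self.symptom_counts[self._si(symptom)])

    def count_symptom_given_disease(self, symptom: str, disease: str) -> float:
        return float(self.symptom_disease[self._di(disease), self._si(symptom)])

    def count_pair(self, s_i: str, s_j: str) -> float:
        """Cohort-wide weight of records containing both symptoms."""
        i, j = self._si(s_i), self._si(s_j)
        if i == j:
            raise ValueError(f"pair requires two distinct symptoms, got {s_i!r} twice")
        return float(self.pair_counts[i, j])

    def count_pair_given_disease(self, s_i: str, s_j: str, disease: str) -> float:
        i, j = self._si(s_i), self._si(s_j)
        if i == j:
            raise ValueError(f"pair requires two distinct symptoms, got {s_i!r} twice")
        return float(self.pair_disease[self._di(disease), i, j])

    def cell_symptom_disease(self, symptom: str, disease: str):
        """2x2 cells (a, b, c, d) for S present/absent x disease is/is-not D_f."""
        a = self.count_symptom_given_disease(symptom, disease)
        b = self.count_symptom(symptom) - a
        c = self.count_disease(disease) - a
        d = self.m - a - b - c
        return a, b, c, d

    def cell_symptom_pair(self, s_i: str, s_j: str):
        """2x2 cells (a, b, c, d) for S_i present/absent x S_j present/absent."""
        a = self.count_pair(s_i, s_j)
        b = self.count_symptom(s_i) - a
        c = self.count_symptom(s_j) - a
        d = self.m - a - b - c
        return a, b, c, d


def count_statistics(
    cohort: Cohort, weights: Sequence[float] | np.ndarray | None = None
) -> CountStatistics:
    """Tally all weighted counts in one pass over the cohort."""
    m = cohort.m
    if weights is None:
        w = np.ones(m)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,):
            raise ValueError(f"weights length {w.shape} does not match {m} records")
        if np.any(w < 0):
            raise ValueError("negative record weight")
        if m > 0 and w.sum() <= 0:
            raise ValueError("weights must sum to a positive total")

    diseases = cohort.disease_vocabulary
    symptoms = cohort.symptom_vocabulary
    k, V = len(diseases), len(symptoms)
    s_index = {s: i for i, s in enumerate(symptoms)}
    d_index = {d: i for i, d in enumerate(diseases)}

    X = np.zeros((m, V), dtype=float)
    y = np.zeros(m, dtype=int)
    for r, rec in enumerate(cohort):
        y[r] = d_index[rec.disease]
        for s in rec.symptoms:
            X[r, s_index[s]] = 1.0

    disease_counts = np.zeros(k)
    np.add.at(disease_counts, y, w)
    Xw = X * w[:, None]
    symptom_counts = Xw.sum(axis=0)
    symptom_disease = np.zeros((k, V))
    pair_disease = np.zeros((k, V, V))
    for f in range(k):
        idx = np.flatnonzero(y == f)
        if idx.size == 0:
            continue
        Xf, Xfw = X[idx], Xw[idx]
        symptom_disease[f] = Xfw.sum(axis=0)
        P = Xf.T @ Xfw
        np.fill_diagonal(P, 0.0)
        pair_disease[f] = P
    pair_counts = pair_disease.sum(axis=0)

    return CountStatistics(
        diseases=tuple(diseases),
        symptoms=tuple(symptoms),
        m=float(w.sum()),
        n_records=m,
        disease_counts=disease_counts,
        symptom_counts=symptom_counts,
        symptom_disease=symptom_disease,
        pair_counts=pair_counts,
        pair_disease=pair_disease,
    )


def disease_prior(counts: CountStatistics) -> dict[str, float]:
    """Laplace-smoothed priors P(D_f) = (#D_f + 1)/(m + k).

    With m = 0 this degrades gracefully to the uniform 1/k distribution.
    """
    if counts.k < 1:
        raise ValueError("need at least one disease")
    denom = counts.m + counts.k
    return {
        d: float((counts.disease_counts[i] + 1.0) / denom)
        for i, d in enumerate(counts.diseases)
    }


def symptom_conditional(counts: CountStatistics, symptom: str, disease: str) -> float:
    """P(S | D_f) = (#(S, D_f) + 1)/(#D_f + k)."""
    num = counts.count_symptom_given_disease(symptom, disease) + 1.0
    den = counts.count_disease(disease) + counts.k
    return num / den


def pair_conditional(counts: CountStatistics, s_i: str, s_j: str, disease: str) -> float:
    """P((S_i, S_j) | D_f) with the same +1/+k smoothing; symmetric in the pair."""
    num = counts.count_pair_given_disease(s_i, s_j, disease) + 1.0
    den = counts.count_disease(disease) + counts.k
    return num / den


@dataclass
class ProbabilityModel:
    """Laplace-smoothed priors and conditionals over fixed vocabularies.

    ``pair_disease`` (raw pair counts per disease) is retained so pair
    conditionals and co-occurrence correlations are available without a second
    pass over the data; a model re-read from an ontology is *partial*
    (``pair_disease is None``) and supports prior/conditional lookups only.
    """

    diseases: tuple[str, ...]
    symptoms: tuple[str, ...]
    k: int
    m: float
    disease_counts: np.ndarray          # (k,) raw training support per disease
    prior_: np.ndarray                  # (k,)
    cond_: np.ndarray                   # (k, V)
    pair_disease: np.ndarray | None = None  # (k, V, V) raw counts or None

    d_index: dict[str, int] = field(init=False, repr=False)
    s_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.d_index = {d: i for i, d in enumerate(self.diseases)}
        self.s_index = {s: i for i, s in enumerate(self.symptoms)}

    def _di(self, disease: str) -> int:
        try:
            return self.d_index[disease]
        except KeyError:
            raise KeyError(f"unknown disease {disease!r}") from None

    def _si(self, symptom: str) -> int:
        try:
            return self.s_index[symptom]
        except KeyError:
            raise KeyError(f"unknown symptom {symptom!r}") from None

    def prior(self, disease: str) -> float:
        return float(self.prior_[self._di(disease)])

    def conditional(self, symptom: str, disease: str) -> float:
        return float(self.cond_[self._di(disease), self._si(symptom)])

    def pair_conditional(self, s_i: str, s_j: str, disease: str) -> float:
        if self.pair_disease is None:
            raise ValueError("partial model: pair conditionals are unavailable")
        i, j = self._si(s_i), self._si(s_j)
        if i == j:
            raise ValueError(f"pair requires two distinct symptoms, got {s_i!r} twice")
        f = self._di(disease)
        num = self.pair_disease[f, i, j] + 1.0
        den = self.disease_counts[f] + self.k
        return float(num / den)

    def pair_cooccurrence_counts(self) -> np.ndarray:
        """Cohort-wide (V, V) co-occurrence counts (for thresholding)."""
        if self.pair_disease is None:
            raise ValueError("partial model: pair counts are unavailable")
        return self.pair_disease.sum(axis=0)

    # -- serialization --------------------------------------------------------
    def to_json_dict(self) -> dict:
        pairs = []
        pair_counts = []
        if self.pair_disease is not None:
            for f, d in enumerate(self.diseases):
                den = self.disease_counts[f] + self.k
                ii, jj = np.nonzero(np.triu(self.pair_disease[f], k=1))
                for i, j in zip(ii.tolist(), jj.tolist()):
                    pairs.append(
                        [self.symptoms[i], self.symptoms[j], d,
                         float((self.pair_disease[f, i, j] + 1.0) / den)]
                    )
                    pair_counts.append(
                        [self.symptoms[i], self.symptoms[j], d,
                         float(self.pair_disease[f, i, j])]
                    )
        return {
            "k": self.k,
            "m": self.m,
            "disease_counts": {d: float(c) for d, c in zip(self.diseases, self.disease_counts)},
            "symptoms": list(self.symptoms),
            "priors": {d: float(p) for d, p in zip(self.diseases, self.prior_)},
            "conditionals": {
                d: {s: float(self.cond_[f, v]) for v, s in enumerate(self.symptoms)}
                for f, d in enumerate(self.diseases)
            },
            "pair_conditionals": pairs,
            "pair_counts": pair_counts,
        }

    @classmethod
    def from_json_dict(cls, obj: Mapping) -> "ProbabilityModel":
        diseases = tuple(obj["priors"].keys())
        symptoms = tuple(obj["symptoms"])
        k, m = int(obj["k"]), float(obj["m"])
        dc = np.array([obj["disease_counts"][d] for d in diseases])
        prior = np.array([obj["priors"][d] for d in diseases])
        cond = np.array(
            [[obj["conditionals"][d][s] for s in symptoms] for d in diseases]
        )
        pair = None
        entries = obj.get("pair_counts")
        raw = entries is not None
        if entries is None and obj.get("pair_conditionals") is not None:
            entries = obj["pair_conditionals"]
        if entries is not None:
            pair = np.zeros((len(diseases), len(symptoms), len(symptoms)))
            di = {d: i for i, d in enumerate(diseases)}
            si = {s: i for i, s in enumerate(symptoms)}
            for s1, s2, d, v in entries:
                f = di[d]
                cnt = v if raw else v * (dc[f] + k) - 1.0
                pair[f, si[s1], si[s2]] = cnt
                pair[f, si[s2], si[s1]] = cnt
        return cls(
            diseases=diseases, symptoms=symptoms, k=k, m=m,
            disease_counts=dc, prior_=prior, cond_=cond, pair_disease=pair,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), ensure_ascii=False), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ProbabilityModel":
        return cls.from_json_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def probability_model_from_counts(counts: CountStatistics) -> ProbabilityModel:
    prior = (counts.disease_counts + 1.0) / (counts.m + counts.k)
    cond = (counts.symptom_disease + 1.0) / (counts.disease_counts[:, None] + counts.k)
    return ProbabilityModel(
        diseases=counts.diseases,
        symptoms=counts.symptoms,
        k=counts.k,
        m=counts.m,
        disease_counts=counts.disease_counts.copy(),
        prior_=prior,
        cond_=cond,
        pair_disease=counts.pair_disease.copy(),
    )


def fit_probability_model(
    cohort: Cohort, weights: Sequence[float] | np.ndarray | None = None
) -> ProbabilityModel:
    """Training steps 1-2: tally counts, then Laplace-smooth everything."""
    return probability_model_from_counts(count_statistics(cohort, weights))
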