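"""AdaBoost (multiclass SAMME) optimization of the dependency-aware classifier.

Each round draws a weight-proportional bootstrap resample of the training
cohort, fits the base learner (probability model + dependency model) on the
resample's multiplicity weights, measures the weighted top-1 error on the
*full* cohort, converts it to a round weight

    alpha_t = ln((1 - eps_t) / eps_t) + ln(k - 1)

and multiplies the weights of misclassified records by e^{alpha_t} before
renormalizing, so the next resample concentrates on the records the current
model gets wrong.  A round with eps_t >= 1 - 1/k (no better than chance) is
discarded and training stops; eps_t == 0 keeps the round and stops.  All
randomness flows from one seeded generator, so training is reproducible.

The ensemble predicts with an alpha-weighted average of round posteriors
(not hard voting), so it still emits a proper ``PosteriorTable`` and can be
scored with ROC machinery like any single model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .classifiers import PosteriorTable, _table_from_log_scores, batch_log_scores, _resolve_query
from .cohort import Cohort, SymptomVector
from .dependency import (
    COOCCURRENCE_BASED,
    OR_BASED,
    DependencyModel,
    fit_dependency_model,
)
from .estimation import ProbabilityModel, count_statistics, probability_model_from_counts
from scipy.special import logsumexp, softmax

__all__ = ["BoostedEnsemble", "adaboost_train", "ensemble_posterior"]

_EPS_FLOOR = 1e-12


@dataclass
class BoostedEnsemble:
    rounds: list[tuple[ProbabilityModel, DependencyModel | None, float]]
    T: int
    seed: int
    variant: str
    history: list[dict] = field(default_factory=list)  # per-round eps/alpha diagnostics

    def __len__(self) -> int:
        return len(self.rounds)

    def to_json_dict(self) -> dict:
        return {
            "T": self.T,
            "seed": self.seed,
            "variant": self.variant,
            "history": self.history,
            "rounds": [
                {
                    "alpha": alpha,
                    "probability": model.to_json_dict(),
                    "dependency": dep.to_json_dict() if dep is not None else None,
                }
                for model, dep, alpha in self.rounds
            ],
        }

    @classmethod
    def from_json_dict(cls, obj) -> "BoostedEnsemble":
        rounds = []
        for r in obj["rounds"]:
            model = ProbabilityModel.from_json_dict(r["probability"])
            dep = (
                DependencyModel.from_json_dict(r["dependency"])
                if r["dependency"] is not None
                else None
            )
            rounds.append((model, dep, float(r["alpha"])))
        return cls(
            rounds=rounds,
            T=int(obj["T"]),
            seed=int(obj["seed"]),
            variant=obj["variant"],
            history=list(obj.get("history", [])),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), ensure_ascii=False), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BoostedEnsemble":
        return cls.from_json_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _presence_matrix(cohort: Cohort, symptoms: tuple[str, ...]) -> np.ndarray:
    si = {s: i for i, s in enumerate(symptoms)}
    X = np.zeros((cohort.m, len(symptoms)))
    for r, rec in enumerate(cohort):
        for s in rec.symptoms:
            if s in si:
                X[r, si[s]] = 1.0
    return X


def _top1(model: ProbabilityModel, dep: DependencyModel | None, X: np.ndarray) -> np.ndarray:
    """Top-1 disease index per row with the lexicographic tie-break."""
    log_scores = batch_log_scores(model, dep, X)
    # break exact ties toward the lexicographically smallest disease name
    name_order = np.argsort(np.argsort(model.diseases))
    keyed = log_scores - 1e-15 * name_order[None, :]
    return np.argmax(keyed, axis=1)


def adaboost_train(
    cohort: Cohort,
    T: int = 10,
    seed: int = 0,
    variant: str = "sdnb",
    cooc_threshold: float = 5,
    clamp: tuple[float, float] | None = None,
) -> BoostedEnsemble:
    """Train a SAMME ensemble of base diagnostic classifiers.

    ``variant`` selects the base learner: ``"sdnb"`` (odds-ratio weighted,
    the default), ``"improved_nb"`` (co-occurrence weighted) or ``"nb"``.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if cohort.m == 0:
        raise ValueError("cannot boost an empty cohort")
    k = cohort.k
    if k < 2:
        raise ValueError(f"boosting needs at least 2 diseases, got {k}")
    if variant not in ("sdnb", "improved_nb", "nb"):
        raise ValueError(f"unknown base variant {variant!r}")
    dep_variant = {"sdnb": OR_BASED, "improved_nb": COOCCURRENCE_BASED, "nb": None}[variant]

    rng = np.random.default_rng(seed)
    m = cohort.m
    d_index = {d: i for i, d in enumerate(cohort.disease_vocabulary)}
    y = np.array([d_index[rec.disease] for rec in cohort])
    X = _presence_matrix(cohort, cohort.symptom_vocabulary)

    w = np.full(m, 1.0 / m)
    rounds: list[tuple[ProbabilityModel, DependencyModel | None, float]] = []
    history: list[dict] = []

    for t in range(T):
        idx = rng.choice(m, size=m, replace=True, p=w)
        mult = np.bincount(idx, minlength=m).astype(float)
        counts = count_statistics(cohort, mult)
        model = probability_model_from_counts(counts)
        dep = (
            fit_dependency_model(counts, dep_variant, cooc_threshold, clamp)
            if dep_variant is not None
            else None
        )
        pred = _top1(model, dep, X)
        mis = pred != y
        eps = float(w[mis].sum())
        if eps >= 1.0 - 1.0 / k:
            history.append({"round": t, "eps": eps, "alpha": None, "kept": False})
            break
        alpha = float(np.log((1.0 - eps) / max(eps, _EPS_FLOOR)) + np.log(k - 1))
        rounds.append((model, dep, alpha))
        history.append({"round": t, "eps": eps, "alpha": alpha, "kept": True})
        if eps == 0.0:
            break
        w = w.copy()
        w[mis] *= np.exp(alpha)
        w /= w.sum()

    return BoostedEnsemble(rounds=rounds, T=T, seed=seed, variant=variant, history=history)


def ensemble_posterior(
    ensemble: BoostedEnsemble, query: SymptomVector | Iterable[str]
) -> PosteriorTable:
    """Alpha-weighted average of round posteriors, renormalized."""
    if not ensemble.rounds:
        raise ValueError("empty ensemble")
    model0 = ensemble.rounds[0][0]
    known, unknown = _resolve_query(model0, query)
    X = np.zeros((1, len(model0.symptoms)))
    for s in known:
        X[0, model0.s_index[s]] = 1.0
    post = _ensemble_batch_posteriors(ensemble, X)[0]
    # feed through the shared table builder for consistent ranking/tie rules
    return _table_from_log_scores(model0.diseases, np.log(post), unknown)


def _ensemble_batch_posteriors(ensemble: BoostedEnsemble, X: np.ndarray) -> np.ndarray:
    """(n, k) ensemble posterior matrix for presence matrix X aligned to the
    first round's symptom vocabulary (all rounds share vocabularies)."""
    alphas = np.array([a for _, _, a in ensemble.rounds])
    if alphas.sum() <= 0:
        alphas = np.ones_like(alphas)
    alphas = alphas / alphas.sum()
    out = None
    for (model, dep, _), a in zip(ensemble.rounds, alphas):
        post = softmax(batch_log_scores(model, dep, X), axis=1)
        out = a * post if out is None else out + a * post
    return out / out.sum(axis=1, keepdims=True)


def ensemble_top1(ensemble: BoostedEnsemble, cohort: Cohort) -> np.ndarray:
    """Top-1 predicted disease index per record (ensemble vote)."""
    model0 = ensemble.rounds[0][0]
    X = _presence_matrix(cohort, model0.symptoms)
    post = _ensemble_batch_posteriors(ensemble, X)
    name_order = np.argsort(np.argsort(model0.diseases))
    return np.argmax(post - 1e-15 * name_order[None, :], axis=1)
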