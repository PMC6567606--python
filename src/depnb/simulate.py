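"""Seeded synthetic diagnostic-cohort generator.

The generator emulates exactly the statistical structure the classifier
assumes: a categorical disease prior, per-disease independent Bernoulli
symptoms theta[D][S] = P(S | D), and — to create the conditional-independence
violations the dependency-aware variants are built for — injectable pairwise
symptom couplings.  A coupling (S_a, S_b, rho) is applied post-hoc to every
record: with probability rho the value of S_b is overwritten by the value of
S_a (presence *and* absence are copied).  rho = 1 makes the two columns
identical; rho = 0 leaves the record untouched.  Couplings are applied in
listed order, so chained couplings are well defined, and the effective truth

    P_eff(S_b | D) = rho * P_eff(S_a | D) + (1 - rho) * theta[D][S_b]

is available in closed form for parameter-recovery tests.

Real EMR cohorts additionally carry reporting noise, demographic confounding
and label errors; none of that is modelled here (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import Cohort, DiagnosticRecord, SymptomVector

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "generate_cohort",
    "paper_scale_spec",
    "desk_spec",
    "desk_background_pairs",
]


@dataclass
class GeneratorSpec:
    k: int
    V: int
    m: int
    priors: np.ndarray                       # (k,) sums to 1
    theta: np.ndarray                        # (k, V) true P(S | D)
    couplings: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0
    disease_names: tuple[str, ...] = ()
    symptom_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.disease_names:
            self.disease_names = tuple(f"D{f:03d}" for f in range(self.k))
        if not self.symptom_names:
            self.symptom_names = tuple(f"S{v:02d}" for v in range(self.V))
        self.priors = np.asarray(self.priors, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.priors.shape != (self.k,):
            raise ValueError(f"priors must have shape ({self.k},)")
        if abs(self.priors.sum() - 1.0) > 1e-9 or np.any(self.priors < 0):
            raise ValueError("priors must be a probability vector summing to 1")
        if self.theta.shape != (self.k, self.V):
            raise ValueError(f"theta must have shape ({self.k}, {self.V})")
        if np.any((self.theta < 0) | (self.theta > 1)):
            raise ValueError("theta entries must lie in [0, 1]")
        names = set(self.symptom_names)
        for s_a, s_b, rho in self.couplings:
            if s_a == s_b:
                raise ValueError(f"coupling symptoms must be distinct, got {s_a!r} twice")
            if s_a not in names or s_b not in names:
                raise ValueError(f"coupling ({s_a!r}, {s_b!r}) not in symptom vocabulary")
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"coupling probability {rho} outside [0, 1]")

    def effective_theta(self) -> np.ndarray:
        """True per-disease symptom marginals after sequential couplings."""
        eff = self.theta.copy()
        si = {s: i for i, s in enumerate(self.symptom_names)}
        for s_a, s_b, rho in self.couplings:
            a, b = si[s_a], si[s_b]
            eff[:, b] = rho * eff[:, a] + (1.0 - rho) * eff[:, b]
        return eff

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "V": self.V,
            "m": self.m,
            "seed": self.seed,
            "priors": self.priors.tolist(),
            "theta": self.theta.tolist(),
            "couplings": [[a, b, r] for a, b, r in self.couplings],
            "disease_names": list(self.disease_names),
            "symptom_names": list(self.symptom_names),
        }

    @classmethod
    def from_json_dict(cls, obj) -> "GeneratorSpec":
        return cls(
            k=obj["k"],
            V=obj["V"],
            m=obj["m"],
            priors=np.array(obj["priors"]),
            theta=np.array(obj["theta"]),
            couplings=[tuple(c) for c in obj["couplings"]],
            seed=obj["seed"],
            disease_names=tuple(obj["disease_names"]),
            symptom_names=tuple(obj["symptom_names"]),
        )


@dataclass
class GroundTruth:
    """The spec that produced a cohort; written as a sidecar JSON so recovery
    tests need no shared in-process state."""

    spec: GeneratorSpec

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.spec.to_json_dict()), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(GeneratorSpec.from_json_dict(json.loads(Path(path).read_text(encoding="utf-8"))))


def generate_cohort(spec: GeneratorSpec) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort from the spec; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    y = rng.choice(spec.k, size=spec.m, p=spec.priors)
    X = rng.random((spec.m, spec.V)) < spec.theta[y]
    si = {s: i for i, s in enumerate(spec.symptom_names)}
    for s_a, s_b, rho in spec.couplings:
        a, b = si[s_a], si[s_b]
        copy_mask = rng.random(spec.m) < rho
        X[copy_mask, b] = X[copy_mask, a]
    records = []
    for r in range(spec.m):
        present = [spec.symptom_names[v] for v in np.flatnonzero(X[r])]
        records.append(
            DiagnosticRecord(
                record_id=f"r{r:06d}",
                disease=spec.disease_names[y[r]],
                symptoms=SymptomVector(tuple(present)),
            )
        )
    cohort = Cohort(records, spec.disease_names, spec.symptom_names)
    return cohort, GroundTruth(spec)


def _zipf_priors(k: int, exponent: float = 1.0) -> np.ndarray:
    p = 1.0 / np.arange(1, k + 1) ** exponent
    return p / p.sum()


def desk_spec(
    m: int = 5000,
    rho: float = 0.0,
    seed: int = 0,
    k: int = 20,
    V: int = 30,
) -> GeneratorSpec:
    """Desk-scale study conditions: k=20 diseases, V=30 symptoms.

    Symptoms 0..k-1 form the "characteristic" pool: disease f presents
    symptoms {f, f+1, f+2} (mod k) with conditionals (0.6, 0.2, 0.1) — one
    prominent symptom and two minor ones, the magnitude profile real
    disease/symptom conditional tables show — over a 0.05 base rate for the
    rest of the pool.  Symptoms k..V-1 are pure background with a flat 0.15
    rate for every disease, hence marginally independent of both disease and
    each other: the designated null pairs for calibration checks.  Priors
    are Zipf-distributed (heavy-tailed, like real clinic caseloads) so the
    leading diseases have prior >= 0.1.

    ``rho > 0`` injects two couplings, (S00 -> S01) and (S05 -> S06), both
    inside the characteristic pool, creating exactly the symptom-dependence
    the weighted classifiers are designed to exploit.
    """
    if V <= k:
        raise ValueError("desk spec expects background symptoms: V > k")
    theta = np.full((k, V), 0.05)
    theta[:, k:] = 0.15
    profile = (0.6, 0.2, 0.1)
    for f in range(k):
        for off, p in enumerate(profile):
            theta[f, (f + off) % k] = p
    couplings = []
    if rho > 0:
        couplings = [("S00", "S01", rho), ("S05", "S06", rho)]
    return GeneratorSpec(
        k=k, V=V, m=m, priors=_zipf_priors(k), theta=theta,
        couplings=couplings, seed=seed,
    )


def desk_background_pairs(spec: GeneratorSpec, n_pairs: int = 3) -> list[tuple[str, str]]:
    """Designated independent background symptom pairs of a desk spec."""
    bg = [s for i, s in enumerate(spec.symptom_names) if np.ptp(spec.theta[:, i]) == 0]
    pairs = []
    for i in range(0, 2 * n_pairs, 2):
        if i + 1 < len(bg):
            pairs.append((bg[i], bg[i + 1]))
    return pairs


def paper_scale_spec(m: int = 30000, seed: int = 0) -> GeneratorSpec:
    """Full-scale study conditions: 336 diseases x 81 symptoms.

    Heavy-tailed Zipf(1.5) priors mean the rare tail gets fewer than 10
    records at m = 30,000, exercising the low-support exclusion used when
    enriching the ontology.  Each disease presents 3 characteristic symptoms
    at 0.55 over a 0.03 base rate; the last 10 symptoms are flat background
    at 0.1.
    """
    k, V = 336, 81
    rng = np.random.default_rng(12345)  # fixed: the spec itself is a constant
    theta = np.full((k, V), 0.03)
    theta[:, V - 10:] = 0.10
    for f in range(k):
        chars = rng.choice(V - 10, size=3, replace=False)
        theta[f, chars] = 0.55
    return GeneratorSpec(
        k=k, V=V, m=m, priors=_zipf_priors(k, 1.5), theta=theta, couplings=[], seed=seed,
    )
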