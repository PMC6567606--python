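"""Probabilistic enrichment of a disease/symptom ontology (OWL 2, RDF/XML).

The learned probabilities are written into the ontology as *data properties*:
each sufficiently supported disease class carries a ``priorProbability``
literal, and each (disease, symptom) pair carries a ``conditionalProbability``
literal on a **reified link individual** — OWL 2 cannot attach a typed data
value directly to an object-property edge, so a small individual stands for
the edge and points at both ends via ``linksDisease`` / ``linksSymptom``.
Synonyms are attached with the ``hasExactSynonym`` annotation (oboInOwl
namespace), and free-text queries are resolved against labels and synonyms by
character n-gram Dice matching.

Diseases whose training support falls below ``min_support`` still appear as
classes but receive no probabilities: probability estimates from a handful of
records are not trustworthy enough to publish in a knowledge resource.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping
from urllib.parse import quote, unquote

import numpy as np
from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef, XSD

from .estimation import ProbabilityModel

__all__ = [
    "OntologySchema",
    "MatchResult",
    "build_ontology",
    "enrich_and_serialize",
    "load_ontology",
    "read_probabilities",
    "match_query",
    "dice_score",
]

DEFAULT_BASE = "http://example.org/depnb#"
OBOINOWL = Namespace("http://www.geneontology.org/formats/oboInOwl#")


@dataclass(frozen=True)
class MatchResult:
    entity: str          # canonical label of the matched class
    kind: str            # "disease" | "symptom"
    score: float
    surface: str         # the label or synonym that matched


class OntologySchema:
    """An in-memory disease/symptom ontology backed by an rdflib Graph."""

    def __init__(self, base: str = DEFAULT_BASE) -> None:
        self.base = base
        self.ns = Namespace(base)
        self.graph = Graph()
        self.graph.bind("", self.ns)
        self.graph.bind("owl", OWL)
        self.graph.bind("oboInOwl", OBOINOWL)
        self.diseases: dict[str, URIRef] = {}
        self.symptoms: dict[str, URIRef] = {}
        self.synonyms: dict[str, list[str]] = {}
        g = self.graph
        for cls in ("Disease", "Symptom", "DiseaseSymptomLink"):
            g.add((self.ns[cls], RDF.type, OWL.Class))
        for prop in ("priorProbability", "conditionalProbability"):
            g.add((self.ns[prop], RDF.type, OWL.DatatypeProperty))
        for prop in ("linksDisease", "linksSymptom"):
            g.add((self.ns[prop], RDF.type, OWL.ObjectProperty))
        g.add((OBOINOWL.hasExactSynonym, RDF.type, OWL.AnnotationProperty))

    # -- construction ---------------------------------------------------------
    def _entity(self, label: str, kind: str) -> URIRef:
        registry = self.diseases if kind == "disease" else self.symptoms
        if label in registry:
            return registry[label]
        iri = self.ns[f"{kind}_{quote(label, safe='')}"]
        parent = self.ns.Disease if kind == "disease" else self.ns.Symptom
        self.graph.add((iri, RDF.type, OWL.Class))
        self.graph.add((iri, RDFS.subClassOf, parent))
        self.graph.add((iri, RDFS.label, Literal(label)))
        registry[label] = iri
        return iri

    def add_disease(self, label: str) -> URIRef:
        return self._entity(label, "disease")

    def add_symptom(self, label: str) -> URIRef:
        return self._entity(label, "symptom")

    def add_synonym(self, label: str, synonym: str) -> None:
        iri = self.diseases.get(label) or self.symptoms.get(label)
        if iri is None:
            raise KeyError(f"unknown entity {label!r}")
        self.graph.add((iri, OBOINOWL.hasExactSynonym, Literal(synonym)))
        self.synonyms.setdefault(label, []).append(synonym)

    def set_prior(self, disease: str, p: float) -> None:
        if not 0.0 < p < 1.0:
            raise ValueError(f"prior for {disease!r} must be in (0, 1), got {p}")
        self.graph.add(
            (self.diseases[disease], self.ns.priorProbability, Literal(p, datatype=XSD.double))
        )

    def add_link(self, disease: str, symptom: str, p: float) -> URIRef:
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"conditional for ({symptom!r} | {disease!r}) must be in (0, 1), got {p}"
            )
        d_iri = self.diseases[disease]
        s_iri = self.symptoms[symptom]
        link = self.ns[f"link_{quote(disease, safe='')}__{quote(symptom, safe='')}"]
        g = self.graph
        g.add((link, RDF.type, self.ns.DiseaseSymptomLink))
        g.add((link, self.ns.linksDisease, d_iri))
        g.add((link, self.ns.linksSymptom, s_iri))
        g.add((link, self.ns.conditionalProbability, Literal(p, datatype=XSD.double)))
        return link

    # -- read-back ------------------------------------------------------------
    def priors(self) -> dict[str, float]:
        out = {}
        for d_iri, _, lit in self.graph.triples((None, self.ns.priorProbability, None)):
            label = self._label_of(d_iri)
            out[label] = float(lit)
        return out

    def conditionals(self) -> dict[str, dict[str, float]]:
        """{disease: {symptom: P(symptom | disease)}} from the reified links."""
        out: dict[str, dict[str, float]] = {}
        g = self.graph
        for link in g.subjects(RDF.type, self.ns.DiseaseSymptomLink):
            d_iri = g.value(link, self.ns.linksDisease)
            s_iri = g.value(link, self.ns.linksSymptom)
            p = g.value(link, self.ns.conditionalProbability)
            if d_iri is None or s_iri is None or p is None:
                raise ValueError(f"link {link} is missing disease, symptom or probability")
            if (d_iri, RDF.type, OWL.Class) not in g:
                raise ValueError(f"link {link} references missing disease class {d_iri}")
            if (s_iri, RDF.type, OWL.Class) not in g:
                raise ValueError(f"link {link} references missing symptom class {s_iri}")
            out.setdefault(self._label_of(d_iri), {})[self._label_of(s_iri)] = float(p)
        return out

    def _label_of(self, iri: URIRef) -> str:
        lab = self.graph.value(iri, RDFS.label)
        if lab is not None:
            return str(lab)
        return unquote(str(iri).rsplit("#", 1)[-1].split("_", 1)[-1])

    def entity_surfaces(self) -> list[tuple[str, str, str]]:
        """(canonical label, kind, surface form) for every label and synonym."""
        rows = []
        for kind, registry in (("disease", self.diseases), ("symptom", self.symptoms)):
            for label in registry:
                rows.append((label, kind, label))
                for syn in self.synonyms.get(label, []):
                    rows.append((label, kind, syn))
        return rows


def build_ontology(
    model: ProbabilityModel,
    min_support: int = 10,
    aliases: Mapping[str, Iterable[str]] | None = None,
    base: str = DEFAULT_BASE,
) -> OntologySchema:
    """Build a schema from a fitted model, attaching probabilities only to
    diseases with at least ``min_support`` training records."""
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    onto = OntologySchema(base=base)
    for s in model.symptoms:
        onto.add_symptom(s)
    for f, d in enumerate(model.diseases):
        onto.add_disease(d)
        if model.disease_counts[f] >= min_support:
            onto.set_prior(d, model.prior(d))
            for s in model.symptoms:
                onto.add_link(d, s, model.conditional(s, d))
    if aliases:
        for label, syns in aliases.items():
            for syn in syns:
                try:
                    onto.add_synonym(label, syn)
                except KeyError:
                    pass  # alias rows for entities outside the model are skipped
    return onto


def enrich_and_serialize(onto: OntologySchema, path: str | Path) -> Path:
    """Serialize to OWL 2 RDF/XML (the dialect mainstream editors default to)."""
    path = Path(path)
    onto.graph.serialize(destination=str(path), format="xml")
    return path


def load_ontology(path: str | Path, base: str = DEFAULT_BASE) -> OntologySchema:
    onto = OntologySchema(base=base)
    onto.graph = Graph()
    onto.graph.parse(str(path), format="xml")
    ns = onto.ns
    g = onto.graph
    for iri in g.subjects(RDFS.subClassOf, ns.Disease):
        onto.diseases[onto._label_of(iri)] = iri
    for iri in g.subjects(RDFS.subClassOf, ns.Symptom):
        onto.symptoms[onto._label_of(iri)] = iri
    for kind, registry in (("disease", onto.diseases), ("symptom", onto.symptoms)):
        for label, iri in registry.items():
            syns = [str(s) for s in g.objects(iri, OBOINOWL.hasExactSynonym)]
            if syns:
                onto.synonyms[label] = sorted(syns)
    return onto


def read_probabilities(path_or_onto: str | Path | OntologySchema) -> ProbabilityModel:
    """Recover a partial probability model (priors + conditionals only).

    Classification with this model is exact with respect to the in-memory
    model on the enriched diseases: the stored double literals round-trip
    bit-for-bit through RDF/XML.
    """
    onto = (
        path_or_onto
        if isinstance(path_or_onto, OntologySchema)
        else load_ontology(path_or_onto)
    )
    priors = onto.priors()
    conds = onto.conditionals()
    if not priors:
        raise ValueError("ontology contains no priorProbability assertions")
    diseases = tuple(sorted(priors))
    symptoms: list[str] = []
    for d in diseases:
        for s in conds.get(d, {}):
            if s not in symptoms:
                symptoms.append(s)
    symptoms_t = tuple(sorted(symptoms))
    cond = np.full((len(diseases), len(symptoms_t)), np.nan)
    for f, d in enumerate(diseases):
        for v, s in enumerate(symptoms_t):
            if s in conds.get(d, {}):
                cond[f, v] = conds[d][s]
    if np.isnan(cond).any():
        missing = [
            (diseases[f], symptoms_t[v]) for f, v in zip(*np.nonzero(np.isnan(cond)))
        ]
        raise ValueError(f"missing conditional probabilities for {missing[:5]!r} ...")
    return ProbabilityModel(
        diseases=diseases,
        symptoms=symptoms_t,
        k=len(diseases),
        m=float("nan"),
        disease_counts=np.zeros(len(diseases)),
        prior_=np.array([priors[d] for d in diseases]),
        cond_=cond,
        pair_disease=None,
    )


# -- n-gram matching ----------------------------------------------------------

def _normalize_text(text: str) -> str:
    t = unicodedata.normalize("NFC", text).casefold().strip()
    return re.sub(r"\s+", " ", t)


def _ngrams(text: str, n: int) -> Counter:
    if len(text) < n:
        return Counter([text] if text else [])
    return Counter(text[i : i + n] for i in range(len(text) - n + 1))


def dice_score(a: str, b: str, n: int = 2) -> float:
    """Dice coefficient over character n-gram multisets of normalized strings."""
    na, nb = _normalize_text(a), _normalize_text(b)
    if na == nb:
        return 1.0
    ga, gb = _ngrams(na, n), _ngrams(nb, n)
    total = sum(ga.values()) + sum(gb.values())
    if total == 0:
        return 0.0
    inter = sum((ga & gb).values())
    return 2.0 * inter / total


def match_query(
    onto: OntologySchema, text: str, n: int = 2, threshold: float = 0.4
) -> list[MatchResult]:
    """Resolve free text against every label/synonym by n-gram Dice score."""
    if not text or not text.strip():
        raise ValueError("query text must be nonempty")
    results: dict[tuple[str, str], MatchResult] = {}
    for label, kind, surface in onto.entity_surfaces():
        score = dice_score(text, surface, n)
        if score >= threshold:
            key = (label, kind)
            if key not in results or score > results[key].score:
                results[key] = MatchResult(entity=label, kind=kind, score=score, surface=surface)
    return sorted(results.values(), key=lambda r: (-r.score, r.entity))
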