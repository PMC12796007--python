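"""Phenotype-ontology substrate: DAG traversal, information content, MICA.

The ontology is a rooted DAG of clinical-feature terms connected by ``is_a``
edges (the Human Phenotype Ontology is the intended real input; synthetic
ontologies use the ``TT:`` prefix).  On top of it this module provides the
three primitives every downstream comparison relies on:

* annotation-frequency counting over a disease corpus, with optional
  propagation of each annotation to all ancestors (distinct-disease
  counting, the standard Resnik convention);
* information content ``IC(t) = -ln(TF(t)/N)`` in nats, with a pseudo-count
  of one for terms never annotated so that IC stays finite;
* the most-informative-common-ancestor (MICA) query used by the semantic
  similarity metrics.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "TERM_ID_RE",
    "OntologyError",
    "OntologyStructureError",
    "UnknownTermError",
    "TermRecord",
    "OntologyGraph",
    "AnnotationCorpus",
    "load_ontology",
    "build_corpus",
    "information_content",
    "mica",
]

TERM_ID_RE = re.compile(r"^[A-Za-z]+:[0-9]+$")


class OntologyError(ValueError):
    """Base class for ontology-level failures."""


class OntologyStructureError(OntologyError):
    """The loaded graph violates a structural invariant (cycle, dangling edge)."""


class UnknownTermError(KeyError):
    """A term identifier is absent from the ontology."""


def validate_term_id(term_id: str) -> str:
    if not TERM_ID_RE.match(term_id):
        raise OntologyError(f"malformed term CURIE: {term_id!r}")
    prefix, local = term_id.split(":", 1)
    return f"{prefix.upper()}:{local}"


@dataclass(frozen=True)
class TermRecord:
    """One ontology term: label, synonyms, obsolescence."""

    label: str
    synonyms: tuple[str, ...] = ()
    obsolete: bool = False
    replaced_by: str | None = None


class OntologyGraph:
    """Rooted is_a DAG over phenotype terms.

    Edges run child -> parent in the underlying :class:`networkx.DiGraph`,
    so the ancestor closure of ``t`` is ``nx.descendants(graph, t)``.
    Obsolete terms are kept in :attr:`terms` (for identifier resolution and
    ``replaced_by`` redirection) but carry no edges and are excluded from
    traversal, IC and MICA.
    """

    def __init__(
        self,
        terms: Mapping[str, TermRecord],
        edges: Iterable[tuple[str, str]],
    ) -> None:
        self.terms: dict[str, TermRecord] = dict(terms)
        g = nx.DiGraph()
        g.add_nodes_from(t for t, rec in self.terms.items() if not rec.obsolete)
        for child, parent in edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise OntologyStructureError(
                        f"is_a edge {child} -> {parent} references unknown term {endpoint}"
                    )
                if self.terms[endpoint].obsolete:
                    raise OntologyStructureError(
                        f"is_a edge {child} -> {parent} touches obsolete term {endpoint}"
                    )
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyStructureError(
                f"cycle detected through term {cycle[0][0]}"
            )
        self._graph = g
        self.roots: frozenset[str] = frozenset(
            t for t in g.nodes if g.out_degree(t) == 0
        )
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- basic accessors -------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    def active_terms(self) -> list[str]:
        """Non-obsolete term identifiers, sorted."""
        return sorted(t for t, rec in self.terms.items() if not rec.obsolete)

    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def resolve(self, term_id: str) -> str:
        """Follow a single ``replaced_by`` hop for obsolete identifiers."""
        rec = self.terms.get(term_id)
        if rec is None:
            raise UnknownTermError(term_id)
        if rec.obsolete and rec.replaced_by and rec.replaced_by in self.terms:
            return rec.replaced_by
        return term_id

    def _check_active(self, term_id: str) -> None:
        rec = self.terms.get(term_id)
        if rec is None:
            raise UnknownTermError(term_id)
        if rec.obsolete:
            raise OntologyError(f"term {term_id} is obsolete; traversal undefined")

    def parents(self, term_id: str) -> frozenset[str]:
        self._check_active(term_id)
        return frozenset(self._graph.successors(term_id))

    def children(self, term_id: str) -> frozenset[str]:
        self._check_active(term_id)
        return frozenset(self._graph.predecessors(term_id))

    def ancestors(self, term_id: str, include_self: bool = False) -> frozenset[str]:
        """Transitive is_a closure of ``term_id``."""
        self._check_active(term_id)
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term_id))
            self._ancestor_cache[term_id] = cached
        return cached | {term_id} if include_self else cached

    def ancestors_within(self, term_id: str, hops: int) -> frozenset[str]:
        """Ancestors reachable in at most ``hops`` is_a steps (any path), excluding self."""
        self._check_active(term_id)
        frontier = {term_id}
        seen: set[str] = set()
        for _ in range(hops):
            frontier = {p for t in frontier for p in self._graph.successors(t)}
            frontier -= seen
            seen |= frontier
        return frozenset(seen)


def load_ontology(source: IO[str] | str) -> OntologyGraph:
    """Parse an OBO flat file into an :class:`OntologyGraph`.

    Only ``is_a`` relations define the hierarchy; every other relationship
    tag is ignored.  Synonyms are collected from all scopes.  Obsolete terms
    are loaded (their ``replaced_by`` target, if any, is recorded) but get
    no edges.
    """
    multigraph = obonet.read_obo(source, ignore_obsolete=False)
    terms: dict[str, TermRecord] = {}
    edges: list[tuple[str, str]] = []
    defined: set[str] = set()
    for node, data in multigraph.nodes(data=True):
        node = validate_term_id(node)
        if not data:
            # networkx auto-creates attribute-less nodes for is_a targets
            # that never appear as [Term] stanzas
            continue
        defined.add(node)
        synonyms = tuple(
            _parse_synonym(s) for s in data.get("synonym", ()) if _parse_synonym(s)
        )
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        replaced = data.get("replaced_by") or None
        terms[node] = TermRecord(
            label=data.get("name", ""),
            synonyms=synonyms,
            obsolete=obsolete,
            replaced_by=replaced[0] if replaced else None,
        )
    for child, parent, rel in multigraph.edges(keys=True):
        if rel != "is_a":
            continue
        child, parent = validate_term_id(child), validate_term_id(parent)
        if parent not in defined:
            raise OntologyStructureError(
                f"is_a edge {child} -> {parent} has a dangling target"
            )
        if terms.get(child, TermRecord("")).obsolete:
            continue
        edges.append((child, parent))
    return OntologyGraph(terms, edges)


_SYNONYM_RE = re.compile(r'^"(.*)"')


def _parse_synonym(raw: str) -> str:
    m = _SYNONYM_RE.match(raw.strip())
    return m.group(1) if m else raw.strip()


@dataclass(frozen=True)
class AnnotationCorpus:
    """Term-frequency table over a disease-annotation corpus.

    ``term_frequency[t]`` is the number of *distinct* diseases annotated to
    ``t`` (after ancestor propagation when built with ``propagate=True``);
    ``disease_count`` is N, the number of diseases in the corpus.
    """

    disease_count: int
    term_frequency: Mapping[str, int] = field(default_factory=dict)

    def tf(self, term_id: str) -> int:
        return self.term_frequency.get(term_id, 0)


def build_corpus(kb, graph: OntologyGraph, propagate: bool = True) -> AnnotationCorpus:
    """Count per-term disease annotations for information content.

    ``kb`` is any object with an ``annotations`` mapping
    DiseaseID -> iterable of (TermID, frequency-class) pairs (or bare term
    IDs).  With ``propagate`` on, a disease annotated to ``t`` counts once
    toward every ancestor of ``t`` — set-union semantics, so a disease
    annotated to two siblings contributes one, not two, to their shared
    ancestors.
    """
    annotations = getattr(kb, "annotations", kb)
    if not annotations:
        raise ValueError("annotation KB is empty; disease count must be positive")
    counts: Counter[str] = Counter()
    for disease, records in annotations.items():
        term_ids = {rec[0] if isinstance(rec, tuple) else getattr(rec, "term", rec) for rec in records}
        for t in term_ids:
            if t not in graph:
                raise UnknownTermError(f"annotated term {t} absent from ontology ({disease})")
        if propagate:
            closure: set[str] = set()
            for t in term_ids:
                closure |= graph.ancestors(t, include_self=True)
            counts.update(closure)
        else:
            counts.update(term_ids)
    tf = {t: counts.get(t, 0) for t in graph.active_terms()}
    return AnnotationCorpus(disease_count=len(annotations), term_frequency=tf)


def information_content(corpus: AnnotationCorpus) -> dict[str, float]:
    """Resnik information content in nats: ``IC(t) = -ln(TF'(t)/N)``.

    Terms with zero observed frequency get a pseudo-count of one so that
    IC stays finite when candidate profiles mention terms never annotated
    in the reference corpus.
    """
    n = corpus.disease_count
    if n < 1:
        raise ValueError("disease count must be >= 1")
    return {
        t: max(0.0, -math.log(max(tf, 1) / n))
        for t, tf in corpus.term_frequency.items()
    }


def mica(
    graph: OntologyGraph,
    ic: Mapping[str, float],
    t1: str,
    t2: str,
) -> tuple[str | None, float]:
    """Most informative common ancestor of two terms.

    Ancestor sets include the terms themselves.  Ties on IC are broken by
    lexicographically smallest term ID for determinism.  Terms with no
    common ancestor (possible in multi-root graphs) yield ``(None, 0.0)``.
    """
    common = graph.ancestors(t1, include_self=True) & graph.ancestors(
        t2, include_self=True
    )
    if not common:
        return None, 0.0
    best = min(common, key=lambda t: (-ic.get(t, 0.0), t))
    return best, ic.get(best, 0.0)
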