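"""Shared fixtures: tiny hand-built ontologies and seeded random DAGs."""

from __future__ import annotations

import numpy as np
import pytest

from phenoaudit.ontology import (
    OntologyGraph,
    TermRecord,
    build_corpus,
    information_content,
)


def make_graph(edges: list[tuple[str, str]], labels: dict[str, str] | None = None,
               synonyms: dict[str, tuple[str, ...]] | None = None) -> OntologyGraph:
    labels = labels or {}
    synonyms = synonyms or {}
    terms = {}
    for child, parent in edges:
        for t in (child, parent):
            terms.setdefault(
                t, TermRecord(label=labels.get(t, f"label {t}"), synonyms=synonyms.get(t, ()))
            )
    return OntologyGraph(terms, edges)


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """C is_a B is_a A."""
    return make_graph([("TT:0000003", "TT:0000002"), ("TT:0000002", "TT:0000001")])


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """D is_a B, D is_a C, B is_a A, C is_a A."""
    return make_graph(
        [
            ("TT:0000004", "TT:0000002"),
            ("TT:0000004", "TT:0000003"),
            ("TT:0000002", "TT:0000001"),
            ("TT:0000003", "TT:0000001"),
        ]
    )


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyGraph:
    """Single-rooted random DAG with 1-2 parents per non-root term."""
    edges = []
    for i in range(2, n_terms + 1):
        parents = {int(rng.integers(1, i))}
        if rng.random() < 0.4:
            parents.add(int(rng.integers(1, i)))
        for p in parents:
            edges.append((f"TT:{i:07d}", f"TT:{p:07d}"))
    return make_graph(edges)


@pytest.fixture
def random_dag_with_ic():
    """40-term random DAG plus an IC map from a random annotation corpus."""
    rng = np.random.default_rng(2024)
    graph = random_dag(rng, 40)
    terms = graph.active_terms()
    annotations = {
        f"DZ:{d:07d}": {
            (str(t), "unknown")
            for t in rng.choice(terms, size=int(rng.integers(2, 7)), replace=False)
        }
        for d in range(1, 13)
    }
    corpus = build_corpus(annotations, graph)
    return graph, information_content(corpus)
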