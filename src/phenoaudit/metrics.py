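"""Agreement metrics between candidate and reference knowledge.

Two complementary views of phenotype-set agreement:

* the Jaccard index on exact term identity — a strict set-based overlap,
  with a one-sided hypergeometric test against the number of phenotype
  concepts in the ontology;
* a Resnik-style semantic similarity — best-match averaging of
  ``IC(MICA(t1, t2))`` over term pairs, symmetrized as an equal-weight
  mean of the two directed scores and normalized by the self-similarities
  of the two sets.

Gene agreement uses plain precision/recall after alias normalization, the
one-to-one nature of causative gene links making set overlap statistics
unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .kb import DEFAULT_COMPARISON_CLASSES, AnnotationKB, filter_by_frequency
from .ontology import OntologyGraph, mica

__all__ = [
    "jaccard",
    "jaccard_significance",
    "directed_similarity",
    "symmetric_similarity",
    "normalized_similarity",
    "SimilarityResult",
    "GenePR",
    "gene_precision_recall",
    "compare_kbs",
    "compare_term_sets",
]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float | None:
    """|a ∩ b| / |a ∪ b| on exact term identity; ``None`` when both empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return None
    return len(a & b) / len(union)


def jaccard_significance(
    overlap: int, size_a: int, size_b: int, population: int
) -> float:
    """One-sided upper-tail hypergeometric p-value P(X >= overlap).

    ``population`` is the number of phenotype concepts in the loaded
    ontology; the test asks whether the observed overlap between two
    annotation sets is greater than expected for random sets of the same
    sizes.
    """
    if not (0 <= overlap <= min(size_a, size_b)):
        raise ValueError("overlap exceeds the smaller set")
    if max(size_a, size_b) > population:
        raise ValueError("set size exceeds population")
    # sf(k) = P(X > k), so P(X >= overlap) = sf(overlap - 1)
    return float(hypergeom.sf(overlap - 1, population, size_a, size_b))


def directed_similarity(
    s1: Iterable[str],
    s2: Iterable[str],
    graph: OntologyGraph,
    ic: Mapping[str, float],
) -> float:
    """Best-match average sim(S1 -> S2) = (1/m) Σ_{t1∈S1} max_{t2∈S2} IC(MICA(t1,t2)).

    An empty opposite set contributes 0 per term, keeping the statistic
    defined for degenerate candidates.
    """
    s1, s2 = sorted(set(s1)), sorted(set(s2))
    if not s1:
        raise ValueError("S1 must be non-empty for a directed similarity")
    if not s2:
        return 0.0
    total = 0.0
    for t1 in s1:
        total += max(mica(graph, ic, t1, t2)[1] for t2 in s2)
    return total / len(s1)


def symmetric_similarity(s1, s2, graph, ic) -> float:
    """0.5·sim(S1→S2) + 0.5·sim(S2→S1)."""
    return 0.5 * directed_similarity(s1, s2, graph, ic) + 0.5 * directed_similarity(
        s2, s1, graph, ic
    )


def normalized_similarity(s1, s2, graph, ic, factor2: bool = True) -> float | None:
    """Symmetric similarity scaled by the sets' self-similarities.

    With ``factor2`` (default) the score is
    ``2·sim(S1,S2) / (sim(S1,S1) + sim(S2,S2))``, so identical sets score
    exactly 1.  ``factor2=False`` gives the plain ratio without the
    constant (capped at 0.5 for identical sets).  Returns ``None`` when
    both self-similarities are 0 (all-root sets under propagated IC).
    """
    denom = symmetric_similarity(s1, s1, graph, ic) + symmetric_similarity(
        s2, s2, graph, ic
    )
    if denom <= 0.0:
        return None
    num = symmetric_similarity(s1, s2, graph, ic)
    return (2.0 if factor2 else 1.0) * num / denom


@dataclass(frozen=True)
class SimilarityResult:
    jaccard: float | None
    jaccard_p: float | None
    directed_12: float
    directed_21: float
    symmetric: float
    normalized: float | None


def compare_term_sets(
    s1: Iterable[str],
    s2: Iterable[str],
    graph: OntologyGraph,
    ic: Mapping[str, float],
    population: int | None = None,
) -> SimilarityResult:
    """All pairwise metrics for one pair of non-empty term sets."""
    s1, s2 = set(s1), set(s2)
    pop = population if population is not None else len(graph.active_terms())
    j = jaccard(s1, s2)
    jp = (
        jaccard_significance(len(s1 & s2), len(s1), len(s2), pop)
        if s1 and s2
        else None
    )
    d12 = directed_similarity(s1, s2, graph, ic)
    d21 = directed_similarity(s2, s1, graph, ic)
    return SimilarityResult(
        jaccard=j,
        jaccard_p=jp,
        directed_12=d12,
        directed_21=d21,
        symmetric=0.5 * d12 + 0.5 * d21,
        normalized=normalized_similarity(s1, s2, graph, ic),
    )


@dataclass(frozen=True)
class GenePR:
    tp: int
    fp: int
    fn: int
    unmapped: int = 0

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None


def gene_precision_recall(
    candidate: Iterable[str],
    reference: Iterable[str],
    mapping: Mapping[str, str] | None = None,
) -> GenePR:
    """Precision/recall of a candidate gene set after alias normalization.

    ``mapping`` maps alias spellings to approved symbols; candidate
    strings that normalize to nothing recognizable are still counted as
    false positives but also reported under ``unmapped``.
    """
    mapping = {k.upper(): v.upper() for k, v in (mapping or {}).items()}

    def norm(symbol: str) -> str:
        s = symbol.strip().upper()
        return mapping.get(s, s)

    cand_raw = [c for c in (s.strip() for s in candidate) if c]
    cand = {norm(c) for c in cand_raw}
    ref = {norm(r) for r in reference if r.strip()}
    unmapped = sum(1 for c in cand_raw if c.upper() not in mapping and c.upper() not in ref)
    tp = len(cand & ref)
    return GenePR(tp=tp, fp=len(cand - ref), fn=len(ref - cand), unmapped=unmapped)


def compare_kbs(
    candidate: AnnotationKB,
    reference: AnnotationKB,
    graph: OntologyGraph,
    ic: Mapping[str, float],
    drop_excluded: bool = True,
    population: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-disease similarity table between two annotation KBs.

    Metrics are computed only on diseases present in both KBs; annotations
    of class ``excluded`` (assertions of absence) are removed first by
    default.  Returns the per-disease table and a summary with
    median/quartiles plus the diseases exclusive to either side.
    """
    if drop_excluded:
        candidate = filter_by_frequency(candidate, DEFAULT_COMPARISON_CLASSES)
        reference = filter_by_frequency(reference, DEFAULT_COMPARISON_CLASSES)
    shared = sorted(candidate.diseases() & reference.diseases())
    rows = []
    for disease in shared:
        s1, s2 = candidate.terms(disease), reference.terms(disease)
        if not s1 or not s2:
            continue
        r = compare_term_sets(s1, s2, graph, ic, population=population)
        rows.append(
            {
                "disease_id": disease,
                "n_candidate": len(s1),
                "n_reference": len(s2),
                "jaccard": r.jaccard,
                "jaccard_p": r.jaccard_p,
                "sym_sim": r.symmetric,
                "norm_sim": r.normalized,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "disease_id",
            "n_candidate",
            "n_reference",
            "jaccard",
            "jaccard_p",
            "sym_sim",
            "norm_sim",
        ],
    )
    summary: dict = {
        "n_shared": len(shared),
        "candidate_only": sorted(candidate.diseases() - reference.diseases()),
        "reference_only": sorted(reference.diseases() - candidate.diseases()),
    }
    if table.empty:
        summary["notice"] = "no shared diseases with non-empty profiles"
    else:
        for col in ("jaccard", "sym_sim", "norm_sim"):
            q = table[col].quantile([0.25, 0.5, 0.75])
            summary[col] = {
                "q1": float(q.loc[0.25]),
                "median": float(q.loc[0.5]),
                "q3": float(q.loc[0.75]),
            }
    return table, summary
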