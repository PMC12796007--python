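"""Novel-annotation detection, evidence triage, and convergence analysis.

A candidate term is *potentially novel* for a disease when neither the
term nor any of its parent or grandparent terms (ancestors within two
is_a hops, along any parent path) appears in the reference profile.
Potential novelties are triaged against an abstract corpus by a vote
panel: the first abstract on which the panel is unanimous validates the
association; a best tally of two-of-three routes it to a manual-review
export; no abstracts at all is its own status.  Finally, novelties
proposed independently by several sources are intersected — convergence
across models is the signal separating plausible new biology from
idiosyncratic hallucination.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .assessors import PromptTask, VotePanel
from .kb import AnnotationKB
from .metrics import jaccard
from .ontology import OntologyGraph

__all__ = [
    "EvidenceStatus",
    "AbstractDoc",
    "NoveltyRecord",
    "detect_novel_terms",
    "assess_evidence",
    "convergent_novelties",
    "top_level_breakdown",
    "write_review_sheet",
]


class EvidenceStatus(str, enum.Enum):
    VALIDATED = "validated"
    REVIEWABLE = "reviewable"  # 2-of-3 best tally, manual-review route
    UNVALIDATED = "unvalidated"
    NO_ABSTRACTS = "no_abstracts"


@dataclass(frozen=True)
class AbstractDoc:
    id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("abstract text must be non-empty")


@dataclass
class NoveltyRecord:
    disease: str
    item: str  # term ID or gene symbol
    sources: set[str] = field(default_factory=set)
    evidence_status: EvidenceStatus = EvidenceStatus.NO_ABSTRACTS
    abstracts_checked: int = 0
    best_tally: str = ""
    supporting_abstract: str | None = None


def detect_novel_terms(
    candidate: Iterable[str],
    reference: Iterable[str],
    graph: OntologyGraph,
    hops: int = 2,
) -> set[str]:
    """Candidate terms absent from the reference up to ``hops`` ancestor levels.

    ``t`` is novel iff ``t`` itself and every ancestor reachable in at
    most ``hops`` is_a steps (any parent path) are all absent from the
    reference set.  The default of two hops excludes parents and
    grandparents.
    """
    reference = set(reference)
    novel: set[str] = set()
    for t in set(candidate):
        if t in reference:
            continue
        if graph.ancestors_within(t, hops) & reference:
            continue
        novel.add(t)
    return novel


def assess_evidence(
    panel: VotePanel,
    abstracts: Sequence[AbstractDoc],
    disease: str,
    disease_label: str,
    term: str,
    term_label: str,
    sources: Iterable[str] = (),
    short_circuit: bool = True,
    template_id: str = "default",
) -> NoveltyRecord:
    """Triage one (disease, term) novelty against an abstract corpus.

    Each abstract is put to the panel ("is the phenotype described as a
    manifestation of the disease in this abstract?").  The first
    unanimous positive validates the association (short-circuit; a
    full-scan mode is available for audit exports).  A best tally one
    vote short of unanimity marks the record reviewable.
    """
    record = NoveltyRecord(disease=disease, item=term, sources=set(sources))
    if not abstracts:
        return record
    best_positives = -1
    status = EvidenceStatus.UNVALIDATED
    for doc in abstracts:
        task = PromptTask(
            kind="assess_evidence",
            payload={
                "disease": disease,
                "disease_label": disease_label,
                "term_id": term,
                "term_label": term_label,
                "abstract": doc.text,
            },
            template_id=template_id,
        )
        try:
            result = panel.vote(task)
        except Exception:
            continue  # assessor failure skips the abstract, run continues
        record.abstracts_checked += 1
        if result.positives > best_positives:
            best_positives = result.positives
            record.best_tally = result.tally
        if result.accepted:
            status = EvidenceStatus.VALIDATED
            record.supporting_abstract = doc.id
            if short_circuit:
                break
        elif (
            status is not EvidenceStatus.VALIDATED
            and result.positives == result.total - 1
            and result.total >= 2
        ):
            status = EvidenceStatus.REVIEWABLE
    if record.abstracts_checked == 0:
        status = EvidenceStatus.NO_ABSTRACTS
    record.evidence_status = status
    return record


def convergent_novelties(
    per_source: Mapping[str, Iterable[tuple[str, str]]],
    min_sources: int = 2,
    exclude: Iterable[tuple[str, str]] = (),
) -> tuple[set[tuple[str, str]], dict[tuple[str, str], float | None]]:
    """Items proposed by at least ``min_sources`` sources, plus pairwise overlap.

    ``per_source`` maps a source name to its set of (disease, item)
    novelties.  ``exclude`` removes items that turned out to be present
    in a curated KB or validated by literature evidence, leaving the
    convergent-but-unattested stratum.  The second return value is the
    Jaccard index between every pair of per-source novelty sets.
    """
    if len(per_source) < 2:
        raise ValueError("convergence needs at least two sources")
    sets = {name: set(items) for name, items in per_source.items()}
    exclude = set(exclude)
    counts: dict[tuple[str, str], int] = {}
    for items in sets.values():
        for item in items:
            counts[item] = counts.get(item, 0) + 1
    convergent = {
        item
        for item, c in counts.items()
        if c >= min_sources and item not in exclude
    }
    names = sorted(sets)
    pairwise = {
        (a, b): jaccard(sets[a], sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return convergent, pairwise


def top_level_breakdown(
    novelties: Iterable[tuple[str, str]],
    reference: AnnotationKB,
    graph: OntologyGraph,
) -> list[dict]:
    """Bucket novel terms by top-level abnormality and flag uncovered categories.

    Top-level categories are the children of the ontology root.  For each
    (disease, novel term) the reference profile is checked for *any*
    annotation under the same category; a novelty in a category the
    reference profile never touches is the candidate-hallucination
    stratum (or a genuinely uncovered organ system).
    """
    if len(graph.roots) != 1:
        raise ValueError("top-level breakdown requires a single-rooted ontology")
    root = next(iter(graph.roots))
    top_levels = graph.children(root)

    def categories(term: str) -> frozenset[str]:
        cats = graph.ancestors(term, include_self=True) & top_levels
        return cats if cats else frozenset({root})

    ref_categories: dict[str, set[str]] = {}
    rows: list[dict] = []
    for disease, term in sorted(set(novelties)):
        if disease not in ref_categories:
            cats: set[str] = set()
            for ref_term in reference.terms(disease):
                cats |= categories(ref_term)
            ref_categories[disease] = cats
        for cat in sorted(categories(term)):
            rows.append(
                {
                    "disease": disease,
                    "term": term,
                    "category": cat,
                    "category_label": graph.terms[cat].label if cat in graph.terms else "",
                    "uncovered_category": cat not in ref_categories[disease],
                }
            )
    return rows


def write_review_sheet(
    records: Sequence[NoveltyRecord],
    sink: IO[str],
    sample_size: int | None = None,
    seed: int = 0,
    statuses: Iterable[EvidenceStatus] = (EvidenceStatus.REVIEWABLE,),
) -> int:
    """Emit a TSV review sheet for manual validation.

    Defaults to the two-of-three reviewable stratum; with ``sample_size``
    a fixed-seed random sample of the selected records is drawn instead,
    mirroring spot-check style manual validation.
    """
    statuses = set(statuses)
    selected = [r for r in records if r.evidence_status in statuses]
    selected.sort(key=lambda r: (r.disease, r.item))
    if sample_size is not None and sample_size < len(selected):
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(selected), size=sample_size, replace=False))
        selected = [selected[i] for i in idx]
    writer = csv.writer(sink, delimiter="\t", lineterminator="\n")
    writer.writerow(
        ["disease", "item", "sources", "status", "best_tally", "abstracts_checked"]
    )
    for r in selected:
        writer.writerow(
            [
                r.disease,
                r.item,
                ",".join(sorted(r.sources)),
                r.evidence_status.value,
                r.best_tally,
                r.abstracts_checked,
            ]
        )
    return len(selected)
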