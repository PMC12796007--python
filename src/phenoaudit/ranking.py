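"""Phenotype-driven disease-ranking evaluation over patient cases.

Patient cases arrive as GA4GH Phenopacket v2 JSON documents; a knowledge
base is evaluated by ranking every disease against each patient's
observed term set and scoring recall@k.  Ranking can come from the
built-in semantic ranker (symmetric Resnik set similarity between the
observed profile and each disease profile) or from an external
likelihood-ratio tool consumed at the file level (TSV in, TSV out).
Matching supports declared OMIM<->ORPHA equivalences and an optional
broader-category map (a ranked group entry counts as a hit when the true
disease is one of its subtypes).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .kb import AnnotationKB, augment_kb
from .metrics import symmetric_similarity
from .ontology import OntologyGraph

log = logging.getLogger(__name__)

__all__ = [
    "PatientCase",
    "RankedList",
    "read_phenopackets",
    "rank_by_similarity",
    "ingest_external_ranking",
    "recall_at_k",
    "subset_evaluation",
    "augmentation_experiment",
]

DEFAULT_CAP = 10


@dataclass(frozen=True)
class PatientCase:
    case_id: str
    observed: frozenset[str]
    truth: str
    equivalents: frozenset[str] = frozenset()

    def truth_ids(self, extra: Mapping[str, Iterable[str]] | None = None) -> frozenset[str]:
        ids = {self.truth} | set(self.equivalents)
        if extra:
            ids |= set(extra.get(self.truth, ()))
        return frozenset(ids)


@dataclass
class RankedList:
    case_id: str
    entries: list[tuple[str, float]]
    source: str = ""

    def top(self, k: int) -> list[str]:
        return [d for d, _ in self.entries[:k]]


def _phenopacket_truth(doc: dict) -> str | None:
    for disease in doc.get("diseases", ()):  # direct diseases block
        term = disease.get("term", {})
        if term.get("id"):
            return term["id"]
    for interp in doc.get("interpretations", ()):  # interpretation fallback
        dx = interp.get("diagnosis", {}).get("disease", {})
        if dx.get("id"):
            return dx["id"]
    return None


def read_phenopackets(directory: str | Path) -> tuple[list[PatientCase], int]:
    """Load every ``*.json`` Phenopacket under ``directory``.

    ``observed`` collects phenotypic-feature term IDs with
    ``excluded: false`` (or absent); files lacking a truth disease or
    valid JSON are skipped and counted.  Returns (cases, skipped).
    """
    cases: list[PatientCase] = []
    skipped = 0
    for path in sorted(Path(directory).glob("*.json")):
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError:
            log.warning("malformed phenopacket %s skipped", path.name)
            skipped += 1
            continue
        observed = {
            f["type"]["id"]
            for f in doc.get("phenotypicFeatures", ())
            if f.get("type", {}).get("id") and not f.get("excluded", False)
        }
        truth = _phenopacket_truth(doc)
        if truth is None or not observed:
            skipped += 1
            continue
        cases.append(
            PatientCase(
                case_id=doc.get("id", path.stem),
                observed=frozenset(observed),
                truth=truth,
            )
        )
    return cases, skipped


def rank_by_similarity(
    kb: AnnotationKB,
    graph: OntologyGraph,
    ic: Mapping[str, float],
    case: PatientCase,
    cap: int = DEFAULT_CAP,
) -> RankedList:
    """Rank KB diseases by symmetric semantic similarity to the observed terms.

    Descending score, ties broken by lexicographic disease ID, truncated
    at ``cap`` (top-10 retention by default).
    """
    if not kb.annotations:
        raise ValueError("cannot rank against an empty knowledge base")
    scored: list[tuple[str, float]] = []
    for disease in kb.annotations:
        profile = kb.terms(disease)
        score = symmetric_similarity(case.observed, profile, graph, ic) if profile else 0.0
        scored.append((disease, score))
    scored.sort(key=lambda e: (-e[1], e[0]))
    return RankedList(case_id=case.case_id, entries=scored[:cap], source=f"builtin:{kb.name}")


DEFAULT_COLUMN_PROFILE = {"case_id": "case_id", "disease_id": "disease_id", "score": "score"}


def ingest_external_ranking(
    source: IO[str] | str,
    column_profile: Mapping[str, str] | None = None,
    cap: int = DEFAULT_CAP,
    source_tag: str = "external",
) -> list[RankedList]:
    """Normalize an external ranker's TSV output into :class:`RankedList`s.

    The column profile maps the logical fields (case_id, disease_id,
    score) onto the tool's column names.  Rows keep their file order per
    case; the retention cap trims each list.  Unknown CURIE prefixes pass
    through verbatim.
    """
    prof = dict(DEFAULT_COLUMN_PROFILE, **(column_profile or {}))
    if isinstance(source, str):
        import io

        source = io.StringIO(source)
    reader = csv.DictReader(source, delimiter="\t")
    if reader.fieldnames is None:
        log.warning("empty external ranking file")
        return []
    for logical, column in prof.items():
        if column not in reader.fieldnames:
            raise ValueError(f"external ranking missing configured column {column!r} ({logical})")
    per_case: dict[str, RankedList] = {}
    for row in reader:
        case_id = row[prof["case_id"]].strip()
        rl = per_case.setdefault(case_id, RankedList(case_id=case_id, entries=[], source=source_tag))
        if len(rl.entries) < cap:
            rl.entries.append((row[prof["disease_id"]].strip(), float(row[prof["score"]])))
    return list(per_case.values())


def _is_hit(
    ranked: RankedList,
    case: PatientCase,
    k: int,
    mode: str,
    broader: Mapping[str, Iterable[str]] | None,
    equivalents: Mapping[str, Iterable[str]] | None,
) -> bool:
    truth_ids = case.truth_ids(equivalents)
    for entry in ranked.top(k):
        if entry in truth_ids:
            return True
        if mode == "broader" and broader and truth_ids & set(broader.get(entry, ())):
            return True
    return False


def recall_at_k(
    results: Sequence[RankedList],
    cases: Sequence[PatientCase],
    k: int,
    mode: str = "exact",
    broader: Mapping[str, Iterable[str]] | None = None,
    equivalents: Mapping[str, Iterable[str]] | None = None,
) -> float:
    """Fraction of cases whose true disease appears in the top k.

    ``exact`` matches the truth ID or a declared equivalent; ``broader``
    additionally accepts a ranked group whose member set contains the
    truth.  A case without a ranked list counts as a miss.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("exact", "broader"):
        raise ValueError(f"unknown matching mode {mode!r}")
    if not cases:
        return 0.0
    by_case = {r.case_id: r for r in results}
    hits = 0
    for case in cases:
        ranked = by_case.get(case.case_id)
        if ranked is None:
            log.warning("case %s has no ranked list; counted as miss", case.case_id)
            continue
        if _is_hit(ranked, case, k, mode, broader, equivalents):
            hits += 1
    return hits / len(cases)


def _covered(kb: AnnotationKB, case: PatientCase, equivalents) -> bool:
    return bool(case.truth_ids(equivalents) & kb.diseases())


def subset_evaluation(
    kbs: Mapping[str, AnnotationKB],
    cases: Sequence[PatientCase],
    graph: OntologyGraph,
    ic: Mapping[str, float],
    ks: Sequence[int] = (1, 5, 10),
    cap: int = DEFAULT_CAP,
    mode: str = "exact",
    broader: Mapping[str, Iterable[str]] | None = None,
    equivalents: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, dict]:
    """Evaluate each KB on its model-specific subset and on the common subset.

    The model-specific subset keeps only cases whose truth the KB covers
    (no case demands a diagnosis the knowledge source cannot express);
    the common subset keeps cases covered by *every* KB, giving a level
    playing field for cross-source comparison.
    """
    if not kbs:
        raise ValueError("at least one knowledge base required")
    common_cases = [
        c for c in cases if all(_covered(kb, c, equivalents) for kb in kbs.values())
    ]
    reports: dict[str, dict] = {}
    for name, kb in kbs.items():
        specific = [c for c in cases if _covered(kb, c, equivalents)]
        report: dict = {
            "coverage": {
                "n_diseases": len(kb.diseases()),
                "model_specific_cases": len(specific),
                "common_cases": len(common_cases),
            }
        }
        if not common_cases:
            report["notice"] = "common subset is empty"
        for subset_name, subset in (("model_specific", specific), ("common", common_cases)):
            if not subset:
                report[subset_name] = {f"recall@{k}": 0.0 for k in ks}
                continue
            results = [rank_by_similarity(kb, graph, ic, c, cap=cap) for c in subset]
            report[subset_name] = {
                f"recall@{k}": recall_at_k(
                    results, subset, k, mode=mode, broader=broader, equivalents=equivalents
                )
                for k in ks
            }
        reports[name] = report
    return reports


def augmentation_experiment(
    base: AnnotationKB,
    additions: Mapping[str, Iterable[str]],
    cases: Sequence[PatientCase],
    graph: OntologyGraph,
    ic: Mapping[str, float],
    ks: Sequence[int] = (1, 5, 10),
    cap: int = DEFAULT_CAP,
    equivalents: Mapping[str, Iterable[str]] | None = None,
) -> dict:
    """Paired before/after evaluation of augmenting a KB with extra terms.

    Typically fed the convergent-novelty set: does folding in annotations
    that several independent sources agree on improve ranking recall?
    Identical cases and settings on both arms; reports per-k deltas.
    """
    augmented = augment_kb(base, additions)
    before = subset_evaluation(
        {"base": base}, cases, graph, ic, ks=ks, cap=cap, equivalents=equivalents
    )["base"]
    after = subset_evaluation(
        {"augmented": augmented}, cases, graph, ic, ks=ks, cap=cap, equivalents=equivalents
    )["augmented"]
    deltas = {
        subset: {
            key: after[subset][key] - before[subset][key] for key in before[subset]
        }
        for subset in ("model_specific", "common")
    }
    return {"before": before, "after": after, "delta": deltas}
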