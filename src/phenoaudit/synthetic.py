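"""Synthetic study inputs with known ground truth.

Everything the audit pipeline consumes can be generated here at desk
scale: a rooted ontology DAG with synonyms, a reference annotation KB
with frequency-qualified profiles and causative genes, corrupted
free-text candidate profiles (term dropout, ancestor substitution,
injected hallucinations — the three error mechanisms observed in
model-externalized knowledge), noisy patient Phenopackets, and mock
abstract corpora with a planted verdict key.  Ground-truth parameters
(dropout keep-rate, gene precision/recall, noise rates) are part of the
spec, so every downstream estimate can be checked for parameter
recovery.  Same spec + same seed gives byte-identical artifacts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kb import Annotation, AnnotationKB, FrequencyClass, GeneKB
from .ontology import OntologyGraph, TermRecord

__all__ = [
    "SyntheticSpec",
    "CorruptionSpec",
    "GeneTruthSpec",
    "PatientNoiseSpec",
    "CorruptedProfile",
    "generate_ontology",
    "ontology_to_obo",
    "generate_reference_kb",
    "corrupt_profile",
    "generate_candidate_genes",
    "generate_patients",
    "mock_abstracts",
]

_FREQUENCY_CHOICES = (
    (FrequencyClass.OBLIGATE, 0.05),
    (FrequencyClass.VERY_FREQUENT, 0.20),
    (FrequencyClass.FREQUENT, 0.35),
    (FrequencyClass.OCCASIONAL, 0.25),
    (FrequencyClass.VERY_RARE, 0.10),
    (FrequencyClass.UNKNOWN, 0.05),
)


def _check_rate(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class CorruptionSpec:
    """How a candidate source distorts a reference profile.

    ``dropout_keep`` is the per-term retention probability; each kept
    term is replaced by a random proper ancestor with probability
    ``ancestor_sub_rate`` (taxonomic substitution); hallucinations are
    appended at ``ceil(hallucination_rate * |profile|)`` terms drawn
    outside the profile's 2-hop ancestor neighbourhood so they are
    guaranteed novelty-positive.
    """

    dropout_keep: float = 0.6
    ancestor_sub_rate: float = 0.2
    hallucination_rate: float = 0.2
    #: substitution generality: ancestors within this many is_a hops are
    #: eligible replacements (1 = parent, 2 = parent or grandparent);
    #: taxonomic substitution is mild generalization, not a jump to the root
    sub_hops: int = 2

    def __post_init__(self) -> None:
        for name in ("dropout_keep", "ancestor_sub_rate", "hallucination_rate"):
            _check_rate(name, getattr(self, name))
        if self.sub_hops < 1:
            raise ValueError("sub_hops must be >= 1")


@dataclass(frozen=True)
class GeneTruthSpec:
    """Planted gene-set quality: target recall r* and precision p*."""

    recall: float = 0.6
    precision: float = 0.7

    def __post_init__(self) -> None:
        _check_rate("recall", self.recall)
        _check_rate("precision", self.precision)


@dataclass(frozen=True)
class PatientNoiseSpec:
    """Patient-profile imprecision: per-term generalization to a parent
    with probability ``imprecision_rate`` plus ``noise_terms`` unrelated
    terms per case."""

    imprecision_rate: float = 0.2
    noise_terms: int = 2
    n_per_disease: int = 5

    def __post_init__(self) -> None:
        _check_rate("imprecision_rate", self.imprecision_rate)
        if self.noise_terms < 0 or self.n_per_disease < 1:
            raise ValueError("noise_terms must be >= 0 and n_per_disease >= 1")


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_terms: int = 200
    max_children: int = 8
    n_diseases: int = 50
    profile_mean: float = 8.0
    profile_min: int = 3
    profile_max: int = 20
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    gene_truth: GeneTruthSpec = field(default_factory=GeneTruthSpec)
    patient_noise: PatientNoiseSpec = field(default_factory=PatientNoiseSpec)

    def __post_init__(self) -> None:
        if self.n_terms < 3:
            raise ValueError("n_terms must be >= 3")
        if not 1 <= self.profile_min <= self.profile_max:
            raise ValueError("need 1 <= profile_min <= profile_max")
        if self.n_diseases < 1 or self.max_children < 2:
            raise ValueError("n_diseases >= 1 and max_children >= 2 required")


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible sub-streams per generator operation
    return np.random.default_rng([spec_seed, stream])


def _term_id(i: int) -> str:
    return f"TT:{i:07d}"


# ---------------------------------------------------------------------------
# Ontology


def generate_ontology(spec: SyntheticSpec) -> OntologyGraph:
    """Grow a single-rooted random DAG by parent attachment.

    The first five terms form a chain (guaranteeing depth >= 4); each
    later term attaches to one recent-half parent and, with probability
    0.3, a second parent anywhere earlier.  A node already carrying
    ``max_children`` children stops being eligible.  Labels are
    ``Term NNNN`` with 0-2 synonyms.
    """
    rng = _rng(spec.seed, 1)
    n = spec.n_terms
    terms: dict[str, TermRecord] = {}
    edges: list[tuple[str, str]] = []
    child_count = np.zeros(n + 1, dtype=int)

    def eligible(indices: Iterable[int]) -> list[int]:
        return [j for j in indices if child_count[j] < spec.max_children]

    for i in range(1, n + 1):
        tid = _term_id(i)
        n_syn = int(rng.integers(0, 3))
        synonyms = tuple(f"Synonym {chr(65 + s)} of term {i:04d}" for s in range(n_syn))
        label = "Synthetic phenotypic abnormality" if i == 1 else f"Term {i:04d}"
        terms[tid] = TermRecord(label=label, synonyms=synonyms)
        if i == 1:
            continue
        if i <= 5:
            parents = [i - 1]
        else:
            lo = max(1, i // 2)
            pool = eligible(range(lo, i)) or eligible(range(1, i)) or [1]
            parents = [int(rng.choice(pool))]
            if rng.random() < 0.3:
                pool2 = [j for j in eligible(range(1, i)) if j != parents[0]]
                if pool2:
                    parents.append(int(rng.choice(pool2)))
        for p in parents:
            edges.append((tid, _term_id(p)))
            child_count[p] += 1
    return OntologyGraph(terms, edges)


def ontology_to_obo(graph: OntologyGraph) -> str:
    """Serialize as a minimal OBO flat file, re-loadable by ``load_ontology``."""
    lines = ["format-version: 1.2", "ontology: synthetic-phenotype-ontology", ""]
    for tid in sorted(graph.terms):
        rec = graph.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {rec.label}")
        for syn in rec.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        if rec.obsolete:
            lines.append("is_obsolete: true")
            if rec.replaced_by:
                lines.append(f"replaced_by: {rec.replaced_by}")
        else:
            for parent in sorted(graph.parents(tid)):
                lines.append(f"is_a: {parent} ! {graph.terms[parent].label}")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Reference knowledge bases


def _disease_id(i: int) -> str:
    return f"DZ:{i:07d}"


def _profile_size(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    if spec.profile_min == spec.profile_max:
        return spec.profile_min
    sigma = 0.5
    mu = math.log(spec.profile_mean) - sigma**2 / 2  # lognormal mean = profile_mean
    size = int(round(float(rng.lognormal(mu, sigma))))
    return max(spec.profile_min, min(spec.profile_max, size))


def generate_reference_kb(
    spec: SyntheticSpec, graph: OntologyGraph
) -> tuple[AnnotationKB, GeneKB]:
    """Reference annotations plus causative genes for ``n_diseases`` diseases.

    Profile sizes follow a clipped log-normal around ``profile_mean``;
    terms are drawn leaf-biased (leaves weighted 3:1 over internal
    terms, the root excluded) so profiles look like curated annotations
    rather than uniform samples.  Profiles are kept pairwise distinct.
    Each disease gets 1-3 causative genes from a synthetic symbol pool.
    """
    rng = _rng(spec.seed, 2)
    active = [t for t in graph.active_terms() if t not in graph.roots]
    weights = np.array([3.0 if not graph.children(t) else 1.0 for t in active])
    weights /= weights.sum()
    kb = AnnotationKB(name="synthetic-reference")
    freq_classes = [c for c, _ in _FREQUENCY_CHOICES]
    freq_p = np.array([p for _, p in _FREQUENCY_CHOICES])
    seen_profiles: set[frozenset[str]] = set()
    for i in range(1, spec.n_diseases + 1):
        disease = _disease_id(i)
        for _ in range(100):
            size = min(_profile_size(spec, rng), len(active))
            profile = frozenset(
                rng.choice(active, size=size, replace=False, p=weights)
            )
            if profile not in seen_profiles:
                break
        seen_profiles.add(profile)
        for term in sorted(profile):
            freq = freq_classes[int(rng.choice(len(freq_classes), p=freq_p))]
            kb.add(disease, Annotation(term=term, frequency=freq), label=f"Disease {i:04d}")

    gene_rng = _rng(spec.seed, 3)
    pool = [f"GENE{j:04d}" for j in range(1, max(60, 4 * spec.n_diseases) + 1)]
    genes = GeneKB(name="synthetic-genes")
    for i in range(1, spec.n_diseases + 1):
        disease = _disease_id(i)
        k = int(gene_rng.integers(1, 4))
        for sym in gene_rng.choice(pool, size=k, replace=False):
            genes.genes.setdefault(disease, set()).add(str(sym))
            genes.association_class[(disease, str(sym))] = (
                "Disease-causing germline mutation(s) in"
            )
    return kb, genes


# ---------------------------------------------------------------------------
# Candidate-profile corruption


@dataclass(frozen=True)
class CorruptedProfile:
    """Free-text rendering of a corrupted profile plus its ground truth."""

    lines: tuple[str, ...]
    kept: frozenset[str]  # retained terms still at their original identity
    substituted: tuple[tuple[str, str], ...]  # (original, ancestor) pairs
    hallucinated: frozenset[str]

    @property
    def output_terms(self) -> frozenset[str]:
        return (
            self.kept
            | {anc for _, anc in self.substituted}
            | self.hallucinated
        )


def _surface_form(graph: OntologyGraph, term: str, rng: np.random.Generator) -> str:
    rec = graph.terms[term]
    forms = (rec.label, *rec.synonyms)
    return forms[int(rng.integers(0, len(forms)))]


def corrupt_profile(
    profile: Iterable[str],
    graph: OntologyGraph,
    corruption: CorruptionSpec,
    seed: int,
) -> CorruptedProfile:
    """Render a reference profile as corrupted free-text phenotype lines.

    Surface forms (label or a random synonym) are chosen per line so the
    alignment stage is genuinely exercised rather than bypassed.
    """
    rng = np.random.default_rng(seed)
    profile = sorted(set(profile))
    kept: list[str] = []
    substituted: list[tuple[str, str]] = []
    for term in profile:
        if rng.random() >= corruption.dropout_keep:
            continue
        ancestors = sorted(graph.ancestors_within(term, corruption.sub_hops))
        if ancestors and rng.random() < corruption.ancestor_sub_rate:
            substituted.append((term, ancestors[int(rng.integers(0, len(ancestors)))]))
        else:
            kept.append(term)

    n_hall = math.ceil(corruption.hallucination_rate * len(profile))
    forbidden: set[str] = set(profile)
    hallucinated: list[str] = []
    if n_hall:
        candidates = [
            t
            for t in graph.active_terms()
            if t not in graph.roots
            and t not in forbidden
            and not (graph.ancestors_within(t, 2) & forbidden)
        ]
        n_hall = min(n_hall, len(candidates))
        hallucinated = [
            str(t) for t in rng.choice(candidates, size=n_hall, replace=False)
        ]

    out_terms = kept + [anc for _, anc in substituted] + hallucinated
    lines = tuple(_surface_form(graph, t, rng) for t in out_terms)
    return CorruptedProfile(
        lines=lines,
        kept=frozenset(kept),
        substituted=tuple(substituted),
        hallucinated=frozenset(hallucinated),
    )


# ---------------------------------------------------------------------------
# Candidate genes


def generate_candidate_genes(
    truth: Iterable[str],
    gene_truth: GeneTruthSpec,
    pool: Sequence[str],
    seed: int,
) -> set[str]:
    """Corrupt a true gene set to hit target recall r* and precision p*.

    Each true gene is kept with probability r*; false genes are added at
    ``tp * (1 - p*) / p*`` in expectation (stochastic rounding of the
    fractional part — plain rounding is biased upward for small true-gene
    counts) so the aggregate precision converges to p*.
    """
    if gene_truth.precision == 0:
        raise ValueError("target precision must be positive")
    rng = np.random.default_rng(seed)
    truth = sorted(set(truth))
    if not set(pool) >= set(truth):
        raise ValueError("gene pool must contain the true genes")
    kept = [g for g in truth if rng.random() < gene_truth.recall]
    target = len(kept) * (1 - gene_truth.precision) / gene_truth.precision
    n_false = int(target) + (1 if rng.random() < target - int(target) else 0)
    decoys = sorted(set(pool) - set(truth))
    n_false = min(n_false, len(decoys))
    false = [str(g) for g in rng.choice(decoys, size=n_false, replace=False)] if n_false else []
    return set(kept) | set(false)


# ---------------------------------------------------------------------------
# Patients


def generate_patients(
    kb: AnnotationKB,
    graph: OntologyGraph,
    noise: PatientNoiseSpec,
    seed: int,
    out_dir: str | Path,
) -> list[Path]:
    """Write Phenopacket v2 JSON cases sampled from KB disease profiles.

    Per disease, ``n_per_disease`` cases: each profile term is generalized
    to a random parent with probability ``imprecision_rate`` (clinical
    imprecision), then ``noise_terms`` random unrelated terms are added.
    The truth disease is recorded in the packet's ``diseases`` block.
    """
    if not kb.annotations:
        raise ValueError("annotation KB is empty")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    non_root = [t for t in graph.active_terms() if t not in graph.roots]
    paths: list[Path] = []
    for disease in sorted(kb.annotations):
        profile = sorted(kb.terms(disease))
        for j in range(1, noise.n_per_disease + 1):
            observed: set[str] = set()
            for term in profile:
                if rng.random() < noise.imprecision_rate:
                    parents = sorted(graph.parents(term))
                    observed.add(
                        parents[int(rng.integers(0, len(parents)))] if parents else term
                    )
                else:
                    observed.add(term)
            for _ in range(noise.noise_terms):
                observed.add(str(rng.choice(non_root)))
            case_id = f"{disease.replace(':', '_')}-case{j:03d}"
            packet = {
                "id": case_id,
                "subject": {"id": f"patient-{case_id}"},
                "phenotypicFeatures": [
                    {"type": {"id": t, "label": graph.terms[t].label}}
                    for t in sorted(observed)
                ],
                "diseases": [
                    {
                        "term": {
                            "id": disease,
                            "label": kb.disease_labels.get(disease, ""),
                        }
                    }
                ],
                "metaData": {
                    "created": "2026-01-01T00:00:00Z",
                    "createdBy": "phenoaudit-synthetic",
                    "phenopacketSchemaVersion": "2.0.0",
                },
            }
            path = out_dir / f"{case_id}.json"
            path.write_text(json.dumps(packet, indent=2, sort_keys=True) + "\n")
            paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Abstract corpora


def mock_abstracts(
    kb: AnnotationKB,
    plan: Sequence[Mapping[str, str]],
    graph: OntologyGraph,
    seed: int,
) -> tuple[dict[tuple[str, str], list[dict]], dict[str, str]]:
    """Template abstract corpora with a planted verdict key.

    ``plan`` entries are mappings with ``disease``, ``term`` and
    ``expect`` in {``validated``, ``unvalidated``, ``no_abstracts``}.
    Positive abstracts mention the term label verbatim (so the
    keyword-policy mock panel votes yes unanimously); distractor
    abstracts avoid it.  Returns (corpora keyed by (disease, term),
    expected-status key keyed by "disease|term").
    """
    rng = np.random.default_rng(seed)
    corpora: dict[tuple[str, str], list[dict]] = {}
    key: dict[str, str] = {}
    for entry in plan:
        disease, term, expect = entry["disease"], entry["term"], entry["expect"]
        label = graph.terms[term].label
        disease_label = kb.disease_labels.get(disease, disease)
        docs: list[dict] = []
        if expect == "validated":
            docs.append(
                {
                    "id": f"FIX:{int(rng.integers(10**6, 10**7))}",
                    "text": f"Patients with {disease_label} frequently present {label} "
                    "among their clinical manifestations.",
                }
            )
        elif expect == "unvalidated":
            docs.append(
                {
                    "id": f"FIX:{int(rng.integers(10**6, 10**7))}",
                    "text": f"A cohort study of {disease_label} describing unrelated "
                    "laboratory findings only.",
                }
            )
        elif expect != "no_abstracts":
            raise ValueError(f"unknown expectation {expect!r}")
        corpora[(disease, term)] = docs
        key[f"{disease}|{term}"] = expect
    return corpora, key


def write_abstract_corpora(
    corpora: Mapping[tuple[str, str], Sequence[Mapping]],
    key: Mapping[str, str],
    out_dir: str | Path,
) -> None:
    """Persist corpora as one JSONL per (disease, term) plus the key JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (disease, term), docs in sorted(corpora.items()):
        name = f"{disease.replace(':', '_')}__{term.replace(':', '_')}.jsonl"
        with (out_dir / name).open("w") as fh:
            for doc in docs:
                fh.write(json.dumps(dict(doc), sort_keys=True) + "\n")
    (out_dir / "expected_key.json").write_text(
        json.dumps(dict(key), indent=2, sort_keys=True) + "\n"
    )
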