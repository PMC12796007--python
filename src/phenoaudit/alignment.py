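"""Free-text phenotype lists -> ontology terms.

A transparent dictionary matcher (built from term labels and synonyms)
proposes candidate terms for each phrase; a vote panel validates each
(phrase, term) pair; phrases with no accepted candidate get a second
chance through panel-generated synonyms; whatever is still unmatched is
retained verbatim as a residual — no phrase is silently lost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .assessors import PromptTask, VotePanel
from .ontology import OntologyGraph

__all__ = [
    "normalize_phrase",
    "Lexicon",
    "Match",
    "PhraseAlignment",
    "CandidateProfile",
    "build_lexicon",
    "recognize",
    "align_profile",
    "alignment_report",
]

_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―−"), "-")


def normalize_phrase(text: str) -> str:
    """ASCII-lowercase, dash folding, punctuation-to-space, collapsed whitespace."""
    text = text.translate(_DASHES).lower()
    text = re.sub(r"[^a-z0-9]+", " ", text)
    return re.sub(r"\s+", " ", text).strip()


@dataclass(frozen=True)
class Lexicon:
    """Normalized phrase -> set of term IDs, from labels and all synonyms.

    Collisions (one surface form naming several terms) are kept as
    multi-term entries; the vote/IC machinery downstream resolves them.
    """

    entries: Mapping[str, frozenset[str]]
    max_tokens: int

    def lookup(self, normalized: str) -> frozenset[str]:
        return self.entries.get(normalized, frozenset())


def build_lexicon(graph: OntologyGraph) -> Lexicon:
    entries: dict[str, set[str]] = {}
    for term_id in graph.active_terms():
        rec = graph.terms[term_id]
        for surface in (rec.label, *rec.synonyms):
            key = normalize_phrase(surface)
            if key:
                entries.setdefault(key, set()).add(term_id)
    max_tokens = max((len(k.split()) for k in entries), default=1)
    return Lexicon(
        entries={k: frozenset(v) for k, v in entries.items()}, max_tokens=max_tokens
    )


@dataclass(frozen=True)
class Match:
    term: str
    text: str  # matched normalized span
    start: int  # token offsets within the normalized phrase
    end: int


def recognize(lexicon: Lexicon, phrase: str) -> list[Match]:
    """Longest-match-first scan of a phrase against the lexicon.

    A full-phrase exact match wins outright; otherwise the normalized
    token sequence is scanned left to right, preferring the longest
    n-gram at each position, with matched tokens consumed so spans are
    disjoint.
    """
    norm = normalize_phrase(phrase)
    if not norm:
        return []
    whole = lexicon.lookup(norm)
    tokens = norm.split()
    if whole:
        return [Match(t, norm, 0, len(tokens)) for t in sorted(whole)]
    matches: list[Match] = []
    i = 0
    while i < len(tokens):
        hit = None
        for n in range(min(lexicon.max_tokens, len(tokens) - i), 0, -1):
            span = " ".join(tokens[i : i + n])
            terms = lexicon.lookup(span)
            if terms:
                hit = (terms, span, n)
                break
        if hit:
            terms, span, n = hit
            matches.extend(Match(t, span, i, i + n) for t in sorted(terms))
            i += n
        else:
            i += 1
    return matches


@dataclass
class PhraseAlignment:
    """Fate of one raw phrase: accepted terms, stage, vote tallies."""

    phrase: str
    accepted: list[str] = field(default_factory=list)
    stage: int = 0  # 1 = direct, 2 = synonym retry, 0 = unmatched
    tallies: dict[str, str] = field(default_factory=dict)
    error: bool = False


@dataclass
class CandidateProfile:
    """One knowledge source's aligned view of one disease."""

    disease: str
    source: str
    raw_phenotypes: list[str]
    aligned_terms: set[str] = field(default_factory=set)
    residuals: list[str] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)
    raw_genes: list[str] = field(default_factory=list)
    phrase_log: list[PhraseAlignment] = field(default_factory=list)

    @property
    def mapped_count(self) -> int:
        return len(self.raw_phenotypes) - len(self.residuals) - len(self.rejected)


def _vote_pair(
    panel: VotePanel, graph: OntologyGraph, phrase: str, term: str, template_id: str
):
    rec = graph.terms[term]
    task = PromptTask(
        kind="validate_alignment",
        payload={
            "phrase": phrase,
            "term_id": term,
            "label": rec.label,
            "synonyms": "|".join(rec.synonyms),
        },
        template_id=template_id,
    )
    return panel.vote(task)


def _resolve_span_conflicts(
    accepted: dict[str, tuple[int, int, int]], ic: Mapping[str, float] | None
) -> list[str]:
    """One term per matched span: best tally, then highest IC, then smallest ID."""
    by_span: dict[tuple[int, int], list[str]] = {}
    for term, (start, end, _) in accepted.items():
        by_span.setdefault((start, end), []).append(term)
    winners: list[str] = []
    for span_terms in by_span.values():
        span_terms.sort(
            key=lambda t: (
                -accepted[t][2],
                -(ic or {}).get(t, 0.0),
                t,
            )
        )
        winners.append(span_terms[0])
    return sorted(winners)


def align_profile(
    lexicon: Lexicon,
    panel: VotePanel,
    raw: Sequence[str],
    graph: OntologyGraph,
    ic: Mapping[str, float] | None = None,
    disease: str = "",
    source: str = "",
    raw_genes: Sequence[str] = (),
    template_id: str = "default",
) -> CandidateProfile:
    """Three-stage alignment of raw phenotype phrases.

    Stage 1: dictionary candidates for each phrase, each (phrase, term)
    pair put to a unanimity vote.  Stage 2: for phrases with no accepted
    candidate, panel members suggest synonyms, which are re-recognized and
    re-voted.  Stage 3: still-unmatched phrases kept verbatim as
    residuals.  A panel failure on a pair rejects the phrase but the run
    continues.
    """
    profile = CandidateProfile(
        disease=disease, source=source, raw_phenotypes=list(raw), raw_genes=list(raw_genes)
    )
    for phrase in raw:
        record = PhraseAlignment(phrase=phrase)
        accepted: dict[str, tuple[int, int, int]] = {}
        voted: set[str] = set()
        errored = False

        def consider(matches: list[Match]) -> None:
            nonlocal errored
            for m in matches:
                if m.term in voted:
                    continue
                voted.add(m.term)
                try:
                    result = _vote_pair(panel, graph, phrase, m.term, template_id)
                except Exception:
                    errored = True
                    continue
                record.tallies[m.term] = result.tally
                if result.accepted:
                    accepted[m.term] = (m.start, m.end, result.positives)
                elif result.parse_failures > 0:
                    # assessor failures, not negative votes, sank this pair
                    errored = True

        consider(recognize(lexicon, phrase))
        if accepted:
            record.stage = 1
        else:
            # synonym-enrichment retry for the residual phrase
            for synonym in panel.synonyms(phrase, template_id=template_id):
                consider(recognize(lexicon, synonym))
            if accepted:
                record.stage = 2

        if accepted:
            record.accepted = _resolve_span_conflicts(accepted, ic)
            profile.aligned_terms.update(record.accepted)
        elif errored:
            record.error = True
            profile.rejected.append(phrase)
        else:
            profile.residuals.append(phrase)
        profile.phrase_log.append(record)
    return profile


def alignment_report(profiles: Sequence[CandidateProfile]) -> dict:
    """Per-profile and aggregate mapping statistics.

    ``expansion_ratio`` is aligned terms per raw phrase; dictionary
    matching of multi-concept phrases can push it past 1, mirroring term
    totals exceeding the original line counts.
    """
    per_profile = []
    for p in profiles:
        n = len(p.raw_phenotypes)
        per_profile.append(
            {
                "disease": p.disease,
                "source": p.source,
                "n_phrases": n,
                "mapped": p.mapped_count,
                "residuals": len(p.residuals),
                "rejected": len(p.rejected),
                "mapped_fraction": p.mapped_count / n if n else None,
                "expansion_ratio": len(p.aligned_terms) / n if n else None,
            }
        )
    fractions = [r["mapped_fraction"] for r in per_profile if r["mapped_fraction"] is not None]
    ratios = [r["expansion_ratio"] for r in per_profile if r["expansion_ratio"] is not None]
    return {
        "profiles": per_profile,
        "n_profiles": len(per_profile),
        "mean_mapped_fraction": sum(fractions) / len(fractions) if fractions else None,
        "mean_expansion_ratio": sum(ratios) / len(ratios) if ratios else None,
        "total_residuals": sum(r["residuals"] for r in per_profile),
    }
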