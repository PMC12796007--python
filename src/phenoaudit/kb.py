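"""Disease-annotation and disease-gene knowledge bases.

Readers for the two curated annotation sources used in rare-disease work —
the community ``phenotype.hpoa`` 12-column TSV and Orphanet phenotype/gene
XML exports — plus filtering, restriction, augmentation, and a
deterministic ``phenotype.hpoa`` exporter so a modified knowledge base can
be dropped into any downstream ranker that consumes that dialect.
"""

from __future__ import annotations

import csv
import enum
import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd
from lxml import etree

from .ontology import OntologyGraph, TERM_ID_RE

log = logging.getLogger(__name__)

__all__ = [
    "FrequencyClass",
    "Annotation",
    "AnnotationKB",
    "GeneKB",
    "KBFormatError",
    "read_hpoa",
    "read_orphanet_phenotypes",
    "read_gene_kb",
    "filter_by_frequency",
    "restrict_to_diseases",
    "augment_kb",
    "export_hpoa",
    "HPOA_COLUMNS",
    "DEFAULT_COMPARISON_CLASSES",
    "FREQUENT_CLASSES",
]


class KBFormatError(ValueError):
    """A knowledge-base source violates its declared format."""


class FrequencyClass(str, enum.Enum):
    """Closed vocabulary of annotation-frequency qualifiers."""

    OBLIGATE = "obligate"
    VERY_FREQUENT = "very_frequent"
    FREQUENT = "frequent"
    OCCASIONAL = "occasional"
    VERY_RARE = "very_rare"
    EXCLUDED = "excluded"
    UNKNOWN = "unknown"


#: HPO frequency-subontology identifiers -> class
_HP_FREQUENCY_TERMS = {
    "HP:0040280": FrequencyClass.OBLIGATE,
    "HP:0040281": FrequencyClass.VERY_FREQUENT,
    "HP:0040282": FrequencyClass.FREQUENT,
    "HP:0040283": FrequencyClass.OCCASIONAL,
    "HP:0040284": FrequencyClass.VERY_RARE,
    "HP:0040285": FrequencyClass.EXCLUDED,
}
_CLASS_TO_HP = {v: k for k, v in _HP_FREQUENCY_TERMS.items()}

#: Orphanet frequency wording (leading phrase) -> class
_ORPHANET_FREQUENCY = {
    "obligate": FrequencyClass.OBLIGATE,
    "very frequent": FrequencyClass.VERY_FREQUENT,
    "frequent": FrequencyClass.FREQUENT,
    "occasional": FrequencyClass.OCCASIONAL,
    "very rare": FrequencyClass.VERY_RARE,
    "excluded": FrequencyClass.EXCLUDED,
}

#: classes kept by default in comparisons ("excluded" asserts absence)
DEFAULT_COMPARISON_CLASSES = frozenset(FrequencyClass) - {FrequencyClass.EXCLUDED}
#: the frequent-or-better subset used for the stricter reference variant
FREQUENT_CLASSES = frozenset(
    {FrequencyClass.OBLIGATE, FrequencyClass.VERY_FREQUENT, FrequencyClass.FREQUENT}
)

DISEASE_ID_RE = re.compile(r"^[A-Za-z]+:[0-9]+$")

HPOA_COLUMNS = [
    "database_id",
    "disease_name",
    "qualifier",
    "hpo_id",
    "reference",
    "evidence",
    "onset",
    "frequency",
    "sex",
    "modifier",
    "aspect",
    "biocuration",
]


def percent_to_class(value: float) -> FrequencyClass:
    """Map a percentage to a frequency class using the Orphanet band edges."""
    if value >= 100:
        return FrequencyClass.OBLIGATE
    if value >= 80:
        return FrequencyClass.VERY_FREQUENT
    if value >= 30:
        return FrequencyClass.FREQUENT
    if value >= 5:
        return FrequencyClass.OCCASIONAL
    if value > 0:
        return FrequencyClass.VERY_RARE
    return FrequencyClass.EXCLUDED


def parse_hpoa_frequency(cell: str) -> FrequencyClass:
    """Parse an HPOA frequency cell: HP frequency term, ratio, percent, or empty."""
    cell = (cell or "").strip()
    if not cell:
        return FrequencyClass.UNKNOWN
    if cell in _HP_FREQUENCY_TERMS:
        return _HP_FREQUENCY_TERMS[cell]
    m = re.match(r"^(\d+)\s*/\s*(\d+)$", cell)
    if m:
        num, den = int(m.group(1)), int(m.group(2))
        if den == 0:
            return FrequencyClass.UNKNOWN
        return percent_to_class(100.0 * num / den)
    m = re.match(r"^(\d+(?:\.\d+)?)\s*%$", cell)
    if m:
        return percent_to_class(float(m.group(1)))
    return FrequencyClass.UNKNOWN


@dataclass(frozen=True)
class Annotation:
    """One disease-phenotype annotation with provenance."""

    term: str
    frequency: FrequencyClass = FrequencyClass.UNKNOWN
    provenance: str = "base"

    def key(self) -> tuple[str, str]:
        return (self.term, self.frequency.value)


@dataclass
class AnnotationKB:
    """Disease -> set of frequency-qualified phenotype annotations."""

    name: str
    annotations: dict[str, set[Annotation]] = field(default_factory=dict)
    disease_labels: dict[str, str] = field(default_factory=dict)
    skipped_rows: int = 0

    def diseases(self) -> set[str]:
        return set(self.annotations)

    def terms(self, disease: str) -> set[str]:
        """Bare term-ID profile of one disease."""
        return {a.term for a in self.annotations.get(disease, set())}

    def n_annotations(self) -> int:
        return sum(len(v) for v in self.annotations.values())

    def triples(self) -> set[tuple[str, str, str]]:
        """(disease, term, frequency-class) triples, for round-trip checks."""
        return {
            (d, a.term, a.frequency.value)
            for d, anns in self.annotations.items()
            for a in anns
        }

    def add(self, disease: str, annotation: Annotation, label: str = "") -> None:
        self.annotations.setdefault(disease, set()).add(annotation)
        self.disease_labels.setdefault(disease, label)


def _resolve_term(term: str, graph: OntologyGraph | None) -> str | None:
    """Canonicalize a term against the ontology; follow replaced_by once."""
    if graph is None:
        return term
    if term not in graph:
        return None
    resolved = graph.resolve(term)
    return None if graph.terms[resolved].obsolete else resolved


def read_hpoa(
    source: IO[str] | str,
    name: str = "hpoa",
    graph: OntologyGraph | None = None,
) -> AnnotationKB:
    """Read a ``phenotype.hpoa`` 12-column TSV into an :class:`AnnotationKB`.

    Rows with qualifier ``NOT`` are dropped, only aspect ``P`` (phenotypic
    abnormality) rows are kept, and the frequency column is mapped onto the
    closed :class:`FrequencyClass` vocabulary.  Malformed CURIEs skip the
    row (counted in ``skipped_rows``); a missing column aborts.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    if not lines:
        raise KBFormatError("empty phenotype.hpoa source")
    df = pd.read_csv(
        io.StringIO("\n".join(lines)), sep="\t", dtype=str, keep_default_na=False
    )
    for col in HPOA_COLUMNS:
        if col not in df.columns:
            raise KBFormatError(f"phenotype.hpoa source missing column {col!r}")
    kb = AnnotationKB(name=name)
    for row in df.itertuples(index=False):
        if row.qualifier.strip().upper() == "NOT":
            continue
        if row.aspect.strip() != "P":
            continue
        disease, term = row.database_id.strip(), row.hpo_id.strip()
        if not DISEASE_ID_RE.match(disease) or not TERM_ID_RE.match(term):
            kb.skipped_rows += 1
            continue
        resolved = _resolve_term(term, graph)
        if resolved is None:
            kb.skipped_rows += 1
            continue
        kb.add(
            disease,
            Annotation(term=resolved, frequency=parse_hpoa_frequency(row.frequency)),
            label=row.disease_name.strip(),
        )
    return kb


#: default element names for the Orphanet phenotype export ("en_product4" shape)
ORPHANET_PHENOTYPE_PROFILE = {
    "disorder": "Disorder",
    "orpha_code": "OrphaCode",
    "name": "Name",
    "association": "HPODisorderAssociation",
    "hpo_id": "HPOId",
    "hpo_term": "HPOTerm",
    "frequency": "HPOFrequency",
}


def read_orphanet_phenotypes(
    source: IO[bytes] | IO[str] | str | bytes,
    name: str = "orphanet",
    graph: OntologyGraph | None = None,
    profile: Mapping[str, str] | None = None,
) -> AnnotationKB:
    """Read an Orphanet phenotype XML export into an :class:`AnnotationKB`."""
    prof = dict(ORPHANET_PHENOTYPE_PROFILE, **(profile or {}))
    root = _parse_xml(source)
    kb = AnnotationKB(name=name)
    for disorder in root.iter(prof["disorder"]):
        code = disorder.findtext(prof["orpha_code"])
        if code is None or not code.strip().isdigit():
            kb.skipped_rows += 1
            log.warning("Orphanet disorder without OrphaCode skipped")
            continue
        disease = f"ORPHA:{code.strip()}"
        label = (disorder.findtext(prof["name"]) or "").strip()
        for assoc in disorder.iter(prof["association"]):
            term = (assoc.findtext(f".//{prof['hpo_id']}") or "").strip()
            if not TERM_ID_RE.match(term):
                kb.skipped_rows += 1
                continue
            resolved = _resolve_term(term, graph)
            if resolved is None:
                kb.skipped_rows += 1
                continue
            freq_text = " ".join(
                t.strip() for t in assoc.find(prof["frequency"]).itertext()
            ).strip() if assoc.find(prof["frequency"]) is not None else ""
            kb.add(
                disease,
                Annotation(term=resolved, frequency=_orphanet_class(freq_text)),
                label=label,
            )
        kb.disease_labels.setdefault(disease, label)
    return kb


def _orphanet_class(text: str) -> FrequencyClass:
    low = text.lower()
    # longest wording first so "very frequent" does not match "frequent"
    for phrase in sorted(_ORPHANET_FREQUENCY, key=len, reverse=True):
        if low.startswith(phrase):
            return _ORPHANET_FREQUENCY[phrase]
    return FrequencyClass.UNKNOWN


def _parse_xml(source) -> etree._Element:
    if isinstance(source, str):
        source = source.encode()
    if isinstance(source, bytes):
        return etree.fromstring(source)
    data = source.read()
    if isinstance(data, str):
        data = data.encode()
    return etree.fromstring(data)


# ---------------------------------------------------------------------------
# Gene knowledge bases


#: Orphanet association-type wordings denoting a causative / pathogenic link
CAUSATIVE_PATTERNS = (
    "disease-causing germline mutation",
    "disease-causing somatic mutation",
    "documented pathogenic variant",
    "causative",
)


@dataclass
class GeneKB:
    """Disease -> causative gene symbols, with verbatim association classes.

    Only associations whose class denotes a causative (disease-causing
    germline/somatic) or documented-pathogenic-variant relationship enter
    :attr:`genes`; every association seen, causative or not, is recorded in
    :attr:`association_class` for audit.
    """

    name: str
    genes: dict[str, set[str]] = field(default_factory=dict)
    association_class: dict[tuple[str, str], str] = field(default_factory=dict)
    dropped: int = 0

    def symbols(self, disease: str) -> set[str]:
        return set(self.genes.get(disease, set()))


def is_causative(association: str) -> bool:
    low = association.lower()
    return any(p in low for p in CAUSATIVE_PATTERNS)


ORPHANET_GENE_PROFILE = {
    "disorder": "Disorder",
    "orpha_code": "OrphaCode",
    "association": "DisorderGeneAssociation",
    "gene_symbol": "Symbol",
    "association_type": "DisorderGeneAssociationType",
}


def read_gene_kb(
    source,
    mode: str = "orphanet",
    name: str = "genes",
    profile: Mapping[str, str] | None = None,
) -> GeneKB:
    """Read gene-disease associations from Orphanet gene XML or a 3-column TSV.

    TSV mode expects columns ``disease_id``, ``gene_symbol``,
    ``association_class`` (header required).
    """
    kb = GeneKB(name=name)
    if mode == "orphanet":
        prof = dict(ORPHANET_GENE_PROFILE, **(profile or {}))
        root = _parse_xml(source)
        for disorder in root.iter(prof["disorder"]):
            code = disorder.findtext(prof["orpha_code"])
            if code is None or not code.strip().isdigit():
                kb.dropped += 1
                continue
            disease = f"ORPHA:{code.strip()}"
            for assoc in disorder.iter(prof["association"]):
                symbol = (assoc.findtext(f".//{prof['gene_symbol']}") or "").strip().upper()
                if not symbol:
                    kb.dropped += 1
                    continue
                atype_el = assoc.find(prof["association_type"])
                atype = (
                    " ".join(t.strip() for t in atype_el.itertext()).strip()
                    if atype_el is not None
                    else ""
                )
                _record_gene(kb, disease, symbol, atype)
    elif mode in ("hpoa-genes", "tsv"):
        if isinstance(source, (bytes,)):
            source = source.decode()
        if isinstance(source, str):
            source = io.StringIO(source)
        reader = csv.DictReader(source, delimiter="\t")
        if reader.fieldnames is None:
            return kb
        for needed in ("disease_id", "gene_symbol", "association_class"):
            if needed not in reader.fieldnames:
                raise KBFormatError(f"gene TSV missing column {needed!r}")
        for row in reader:
            symbol = (row["gene_symbol"] or "").strip().upper()
            disease = (row["disease_id"] or "").strip()
            if not symbol or not DISEASE_ID_RE.match(disease):
                kb.dropped += 1
                continue
            _record_gene(kb, disease, symbol, (row["association_class"] or "").strip())
    else:
        raise ValueError(f"unknown gene-KB mode {mode!r}")
    return kb


def _record_gene(kb: GeneKB, disease: str, symbol: str, association: str) -> None:
    kb.association_class[(disease, symbol)] = association
    if is_causative(association):
        kb.genes.setdefault(disease, set()).add(symbol)
    else:
        kb.dropped += 1
        log.debug("non-causative association dropped: %s %s (%s)", disease, symbol, association)


# ---------------------------------------------------------------------------
# KB transforms


def filter_by_frequency(kb: AnnotationKB, keep: Iterable[FrequencyClass]) -> AnnotationKB:
    """Keep only annotations whose frequency class is in ``keep``.

    Diseases left without annotations are dropped from the result's
    annotation map (their labels remain addressable).
    """
    keep = frozenset(FrequencyClass(k) for k in keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    out = AnnotationKB(name=kb.name, disease_labels=dict(kb.disease_labels))
    for disease, anns in kb.annotations.items():
        kept = {a for a in anns if a.frequency in keep}
        if kept:
            out.annotations[disease] = kept
    return out


def restrict_to_diseases(kb: AnnotationKB, ids: Iterable[str]) -> AnnotationKB:
    """Intersect the KB's disease keys with ``ids``; labels carried over."""
    ids = set(ids)
    out = AnnotationKB(name=kb.name, disease_labels=dict(kb.disease_labels))
    for disease, anns in kb.annotations.items():
        if disease in ids:
            out.annotations[disease] = set(anns)
    return out


def augment_kb(base: AnnotationKB, additions: Mapping[str, Iterable[str]]) -> AnnotationKB:
    """Union extra bare terms into a KB.

    Added annotations carry class ``unknown`` and provenance ``"augmented"``;
    where a term already exists in the base the base annotation wins.
    """
    out = AnnotationKB(
        name=base.name,
        annotations={d: set(a) for d, a in base.annotations.items()},
        disease_labels=dict(base.disease_labels),
    )
    for disease, terms in additions.items():
        existing = out.terms(disease)
        for term in terms:
            if term in existing:
                continue
            out.annotations.setdefault(disease, set()).add(
                Annotation(term=term, frequency=FrequencyClass.UNKNOWN, provenance="augmented")
            )
        out.disease_labels.setdefault(disease, "")
    return out


def export_hpoa(kb: AnnotationKB, sink: IO[str], strict: bool = False) -> int:
    """Write the KB in the 12-column ``phenotype.hpoa`` dialect.

    Rows are sorted by (disease, term) so repeated exports of the same KB
    are byte-identical.  All generated rows carry evidence code ``IEA``
    (machine-inferred).  Returns the data-row count.
    """
    rows: list[tuple[str, str, str]] = []
    for disease, anns in kb.annotations.items():
        if strict and not disease.split(":")[0] in ("ORPHA", "OMIM"):
            raise KBFormatError(
                f"strict export requires ORPHA/OMIM identifiers, got {disease}"
            )
        for a in anns:
            freq = _CLASS_TO_HP.get(a.frequency, "")
            rows.append((disease, a.term, freq))
    rows.sort()
    sink.write("\t".join(HPOA_COLUMNS) + "\n")
    for disease, term, freq in rows:
        label = kb.disease_labels.get(disease, "")
        sink.write(
            "\t".join(
                [disease, label, "", term, "", "IEA", "", freq, "", "", "P", "phenoaudit"]
            )
            + "\n"
        )
    return len(rows)
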