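"""Record/replay abstraction over externally queried judgment services.

Five task kinds are exchanged with language-model assessors in the real
study: knowledge externalization, alignment validation, synonym
generation, evidence relevance, and direct diagnosis.  Each is a
:class:`PromptTask` with named payload slots.  Executors come in three
flavours:

* :class:`MockAssessor` — a pure, seeded function of the task content;
  policies ``accept`` / ``reject`` give the two degenerate panels, and
  ``keyword`` gives content-sensitive votes (a term label occurring in an
  abstract counts as supporting evidence) so synthetic fixtures can plant
  known verdicts.
* :class:`RecordingExecutor` — wraps any executor and appends one JSON
  record per call to a JSONL cache, keyed by a content hash of
  (template_id, payload).
* :class:`ReplayExecutor` — serves responses from such a cache and, in
  strict mode, raises on any unseen task, guaranteeing offline runs never
  touch a network.

A :class:`VotePanel` aggregates several executors under a unanimity rule
(all members must vote yes, matching the three-of-three bar used for
alignment acceptance); the tally is reported so two-of-three cases can be
routed to manual-review exports.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

__all__ = [
    "TASK_KINDS",
    "PromptTask",
    "AssessorResponse",
    "ResponseParseError",
    "CacheMissError",
    "MockAssessor",
    "RecordingExecutor",
    "ReplayExecutor",
    "VotePanel",
    "VoteResult",
    "task_hash",
    "parse_response",
]

TASK_KINDS = (
    "externalize",
    "validate_alignment",
    "generate_synonyms",
    "assess_evidence",
    "direct_diagnosis",
)

_BOOLEAN_KINDS = {"validate_alignment", "assess_evidence"}


class ResponseParseError(ValueError):
    """Raw assessor output does not follow the task's output grammar."""


class CacheMissError(KeyError):
    """Strict replay was asked for a task absent from the cache."""


@dataclass(frozen=True)
class PromptTask:
    kind: str
    payload: Mapping[str, str]
    template_id: str = "default"

    def __post_init__(self) -> None:
        if self.kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.kind!r}")


def task_hash(task: PromptTask) -> str:
    """Stable content hash of (template_id, payload); kind is part of the template."""
    blob = json.dumps(
        {"template_id": task.template_id, "kind": task.kind, "payload": dict(sorted(task.payload.items()))},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass(frozen=True)
class AssessorResponse:
    raw_text: str
    parsed: object
    parse_error: str | None = None

    @property
    def ok(self) -> bool:
        return self.parse_error is None


_YESNO_RE = re.compile(r"\b(yes|no)\b", re.IGNORECASE)
_BULLET_RE = re.compile(r"^\s*(?:[-*•]|\d+[.)])\s*")


def parse_response(kind: str, raw_text: str) -> object:
    """Parse raw assessor text per the task kind's documented rule.

    Boolean tasks: first standalone yes/no token, case-insensitive,
    surrounding prose tolerated.  List tasks: one item per line, bullets
    and numbering stripped.  Externalization: lines under a ``phenotypes``
    heading and a ``genes`` heading.
    """
    if kind in _BOOLEAN_KINDS:
        m = _YESNO_RE.search(raw_text)
        if not m:
            raise ResponseParseError(f"no yes/no token in {raw_text!r}")
        return m.group(1).lower() == "yes"
    if kind in ("generate_synonyms", "direct_diagnosis"):
        items = [_BULLET_RE.sub("", ln).strip() for ln in raw_text.splitlines()]
        return [it for it in items if it]
    if kind == "externalize":
        sections: dict[str, list[str]] = {"phenotypes": [], "genes": []}
        current: str | None = None
        for ln in raw_text.splitlines():
            stripped = ln.strip().lower().rstrip(":")
            if stripped in sections:
                current = stripped
                continue
            item = _BULLET_RE.sub("", ln).strip()
            if item and current:
                sections[current].append(item)
        if current is None:
            raise ResponseParseError("externalization output lacks phenotypes/genes headings")
        return sections
    raise ResponseParseError(f"unknown task kind {kind!r}")


class Executor(Protocol):
    def execute(self, task: PromptTask) -> AssessorResponse: ...


def _safe_response(kind: str, raw_text: str) -> AssessorResponse:
    try:
        return AssessorResponse(raw_text=raw_text, parsed=parse_response(kind, raw_text))
    except ResponseParseError as exc:
        return AssessorResponse(raw_text=raw_text, parsed=None, parse_error=str(exc))


def _normalize_key(s: str) -> str:
    return re.sub(r"\s+", " ", re.sub(r"[^a-z0-9]+", " ", s.lower())).strip()


@dataclass
class MockAssessor:
    """Deterministic offline assessor: a pure function of (task hash, seed).

    ``policy`` selects the behaviour of boolean votes:

    - ``accept`` / ``reject``: constant yes / no;
    - ``keyword``: yes when the task's own content supports it — for
      alignment validation, the phrase and the term label/synonyms share a
      substring after normalization; for evidence assessment, the term
      label occurs in the abstract text.

    ``synonym_table`` (normalized phrase -> list of synonyms) and
    ``knowledge`` (disease label -> externalization dict / ranked list)
    back the generative task kinds.
    """

    policy: str = "accept"
    seed: int = 0
    name: str = "mock"
    synonym_table: Mapping[str, Sequence[str]] = field(default_factory=dict)
    knowledge: Mapping[str, object] = field(default_factory=dict)

    def execute(self, task: PromptTask) -> AssessorResponse:
        kind = task.kind
        if kind in _BOOLEAN_KINDS:
            return _safe_response(kind, "yes" if self._vote(task) else "no")
        if kind == "generate_synonyms":
            phrase = _normalize_key(task.payload.get("phrase", ""))
            syns = list(self.synonym_table.get(phrase, ()))
            return _safe_response(kind, "\n".join(syns))
        if kind == "externalize":
            entry = self.knowledge.get(task.payload.get("disease", ""), {})
            phen = entry.get("phenotypes", []) if isinstance(entry, dict) else []
            genes = entry.get("genes", []) if isinstance(entry, dict) else []
            raw = "phenotypes:\n" + "\n".join(f"- {p}" for p in phen)
            raw += "\ngenes:\n" + "\n".join(f"- {g}" for g in genes)
            return _safe_response(kind, raw)
        if kind == "direct_diagnosis":
            ranked = self.knowledge.get("__diagnosis__", [])
            return _safe_response(kind, "\n".join(f"{i+1}. {d}" for i, d in enumerate(ranked)))
        raise ValueError(f"unknown task kind {kind!r}")

    def _vote(self, task: PromptTask) -> bool:
        if self.policy == "accept":
            return True
        if self.policy == "reject":
            return False
        if self.policy == "hash":
            # pseudo-random but fully determined by (content, seed)
            digest = hashlib.sha256(f"{task_hash(task)}:{self.seed}".encode()).digest()
            return digest[0] % 2 == 0
        if self.policy == "keyword":
            if task.kind == "validate_alignment":
                phrase = _normalize_key(task.payload.get("phrase", ""))
                names = [task.payload.get("label", "")] + list(
                    task.payload.get("synonyms", "").split("|")
                )
                for nm in names:
                    nm = _normalize_key(nm)
                    if nm and (nm in phrase or phrase in nm):
                        return True
                return False
            if task.kind == "assess_evidence":
                label = _normalize_key(task.payload.get("term_label", ""))
                text = _normalize_key(task.payload.get("abstract", ""))
                return bool(label) and label in text
        raise ValueError(f"unknown mock policy {self.policy!r}")


class RecordingExecutor:
    """Wrap an executor; append every call to an append-only JSONL cache."""

    def __init__(self, inner: Executor, cache_path: str | Path) -> None:
        self.inner = inner
        self.cache_path = Path(cache_path)

    def execute(self, task: PromptTask) -> AssessorResponse:
        response = self.inner.execute(task)
        record = {
            "hash": task_hash(task),
            "template_id": task.template_id,
            "kind": task.kind,
            "payload": dict(task.payload),
            "raw_text": response.raw_text,
            "timestamp": time.time(),
        }
        with self.cache_path.open("a") as fh:
            fh.write(json.dumps(record, sort_keys=True) + "\n")
        return response


class ReplayExecutor:
    """Serve responses from a JSONL cache; never touches a network.

    In strict mode an unseen task raises :class:`CacheMissError` naming
    the content hash, so incomplete caches fail loudly.
    """

    def __init__(self, cache_path: str | Path, strict: bool = True) -> None:
        self.strict = strict
        self._cache: dict[str, str] = {}
        path = Path(cache_path)
        if path.exists():
            for line in path.read_text().splitlines():
                if not line.strip():
                    continue
                rec = json.loads(line)
                self._cache[rec["hash"]] = rec["raw_text"]

    def execute(self, task: PromptTask) -> AssessorResponse:
        h = task_hash(task)
        if h not in self._cache:
            if self.strict:
                raise CacheMissError(f"no cached response for task hash {h}")
            return _safe_response(task.kind, "")
        return _safe_response(task.kind, self._cache[h])


@dataclass(frozen=True)
class VoteResult:
    accepted: bool
    positives: int
    total: int
    parse_failures: int = 0

    @property
    def tally(self) -> str:
        return f"{self.positives}/{self.total}"


@dataclass
class VotePanel:
    """Ordered panel of assessors with a unanimity (or threshold) rule.

    ``require=None`` means all members must vote positively — the
    three-of-three bar.  The outcome is independent of member order; a
    member whose output cannot be parsed counts as a negative vote and is
    flagged in the result.
    """

    assessors: Sequence[Executor]
    require: int | None = None

    def __post_init__(self) -> None:
        if not self.assessors:
            raise ValueError("vote panel must have at least one assessor")

    @property
    def threshold(self) -> int:
        return len(self.assessors) if self.require is None else self.require

    def vote(self, task: PromptTask) -> VoteResult:
        if task.kind not in _BOOLEAN_KINDS:
            raise ValueError(f"cannot vote on non-boolean task kind {task.kind!r}")
        positives = failures = 0
        for assessor in self.assessors:
            try:
                response = assessor.execute(task)
            except CacheMissError:
                raise
            except Exception:
                failures += 1
                continue
            if not response.ok:
                failures += 1
            elif response.parsed:
                positives += 1
        return VoteResult(
            accepted=positives >= self.threshold,
            positives=positives,
            total=len(self.assessors),
            parse_failures=failures,
        )

    def synonyms(self, phrase: str, template_id: str = "default") -> list[str]:
        """Union of synonym suggestions from every panel member, order-stable."""
        task = PromptTask(
            kind="generate_synonyms", payload={"phrase": phrase}, template_id=template_id
        )
        seen: dict[str, None] = {}
        for assessor in self.assessors:
            try:
                response = assessor.execute(task)
            except CacheMissError:
                raise
            except Exception:
                continue
            if response.ok:
                for syn in response.parsed:
                    seen.setdefault(syn, None)
        return sorted(seen)
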