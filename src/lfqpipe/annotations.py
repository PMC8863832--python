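"""Annotation term sets (GMT format) for over-representation analysis.

GMT is one term per line, tab-separated: term id, description, then member
identifiers.  Terms are restricted to the study's quantification universe
before testing; matching is case-insensitive on gene symbol with protein
accessions as a fallback key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    name: str
    members: frozenset[str]


@dataclass
class AnnotationCollection:
    """Named term -> member-ID sets over a stated universe."""

    terms: list[AnnotationTerm]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate term ids in collection")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def get(self, term_id: str) -> AnnotationTerm:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)

    def restrict_to(self, universe: Iterable[str]) -> "AnnotationCollection":
        """Intersect every term with ``universe``; drop terms left empty."""
        uni = frozenset(_norm(x) for x in universe)
        kept = []
        for t in self.terms:
            members = frozenset(m for m in t.members if _norm(m) in uni)
            if members:
                kept.append(AnnotationTerm(t.term_id, t.name, members))
        return AnnotationCollection(terms=kept, universe=uni)


def _norm(identifier: str) -> str:
    return identifier.strip().lower()


def read_gmt(path: str | Path) -> AnnotationCollection:
    terms = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        term_id, name, *members = parts
        terms.append(AnnotationTerm(term_id, name, frozenset(m for m in members if m)))
    return AnnotationCollection(terms=terms)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    lines = [
        "\t".join([t.term_id, t.name, *sorted(t.members)]) for t in collection.terms
    ]
    Path(path).write_text("\n".join(lines) + "\n")
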