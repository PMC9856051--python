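"""Gene-set collections: GMT input/output and size filtering.

A gene set (GS) is an a-priori-defined group of genes annotated to a shared
biological trait (a pathway, a process, a localization).  Collections are
stored in the GMT dialect used by GSEA and EnrichmentMap gene-set
archives: one set per line, ``name<TAB>description<TAB>member<TAB>member...``.

Gene identifiers are treated as opaque, case-sensitive strings; no alias or
symbol resolution is attempted — the expression data and the collection are
assumed to share a namespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator


class GmtFormatError(ValueError):
    """Raised for malformed GMT input (reports the offending line number)."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with deduplicated members.

    ``members`` preserves first-occurrence order of the source line so that
    round-trips are byte-stable.
    """

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def _dedup_members(tokens: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for t in tokens:
        if t:
            seen.setdefault(t)
    return tuple(seen)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Each line must carry at least three tab-separated fields (name,
    description, one or more members).  Duplicate member tokens within a
    line are deduplicated with a warning; duplicate set names are an error.
    """
    sets: list[GeneSet] = []
    seen_names: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if not name:
                raise GmtFormatError(f"{path}: line {lineno}: empty set name")
            if name in seen_names:
                raise GmtFormatError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                )
            members = _dedup_members(fields[2:])
            if not members:
                raise GmtFormatError(
                    f"{path}: line {lineno}: set {name!r} has no members"
                )
            if len(members) < len([t for t in fields[2:] if t]):
                warnings.warn(
                    f"{path}: line {lineno}: duplicate members in set "
                    f"{name!r} were deduplicated",
                    stacklevel=2,
                )
            seen_names.add(name)
            sets.append(GeneSet(name, description, members))
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection back to GMT (inverse of :func:`read_gmt`)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join((s.name, s.description, *s.members)) + "\n")


def filter_by_size(
    collection: GeneSetCollection,
    min_exclusive: int = 10,
    max_exclusive: int = 500,
) -> GeneSetCollection:
    """Keep sets whose raw membership count is strictly inside the bounds.

    The defaults retain sets with more than 10 and fewer than 500 member
    genes, the conventional guard against enrichment statistics on very
    small or very large sets.  Sizes are counted on the raw GMT membership,
    before any intersection with an expression universe.  Order is
    preserved; the operation is idempotent.
    """
    kept = [s for s in collection if min_exclusive < s.size < max_exclusive]
    return GeneSetCollection(kept, source=collection.source)


def size_filter_report(
    collection: GeneSetCollection,
    filtered: GeneSetCollection,
) -> dict[str, int]:
    """Before/after counts for logging alongside :func:`filter_by_size`."""
    return {"n_input": len(collection), "n_retained": len(filtered)}
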