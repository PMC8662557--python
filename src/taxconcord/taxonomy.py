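"""Rank ladder, lineage normalization, and rank-comparison primitives.

Every comparison in the pipeline runs over a five-level scoring ladder:
species (5), genus (4), family (3), order (2) and a single "high" bucket (1)
into which class, phylum, kingdom, domain and any other supra-ordinal rank
collapse.  A comparison matching at no rank scores 0.  The ladder mirrors
the weighting commonly used to grade metabarcoding identifications: a
species-level agreement is worth five times a class-level one.

Lineages are stored as ordered ``(rank_name, canonical_rank, name)`` entries
from highest to lowest rank.  Placeholder names ("unclassified",
"Incertae sedis", bare prefixes like ``g__``) are dropped during
normalization and never stored as taxa.  Species names are kept as full
binomials whenever the genus is recoverable, so congeners sharing an
epithet never collide.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Rank",
    "LADDER",
    "LineageEntry",
    "Lineage",
    "normalize_name",
    "canonical_rank",
    "build_lineage",
    "parse_qiime_lineage",
    "parse_plain_lineage",
    "deepest_shared_rank",
    "is_consistent_truncation",
]


class Rank(IntEnum):
    """Canonical comparison ranks; the integer value is the identification score."""

    NONE = 0
    HIGH = 1
    ORDER = 2
    FAMILY = 3
    GENUS = 4
    SPECIES = 5

    @property
    def score(self) -> int:
        return int(self)

    @property
    def label(self) -> str:
        return self.name.lower()


#: scoring ranks, deepest first (the high bucket is handled by name-set overlap)
LADDER: tuple[Rank, ...] = (Rank.SPECIES, Rank.GENUS, Rank.FAMILY, Rank.ORDER)

_PREFIX_RE = re.compile(r"^[a-zA-Z]__")

#: names that denote "no taxon here", case-insensitive after normalization
PLACEHOLDERS = frozenset(
    {"unclassified", "unidentified", "uncultured", "incertae sedis", "na", "n/a", "unassigned"}
)

_RANK_MAP = {
    "species": Rank.SPECIES,
    "genus": Rank.GENUS,
    "family": Rank.FAMILY,
    "order": Rank.ORDER,
    "class": Rank.HIGH,
    "subclass": Rank.HIGH,
    "phylum": Rank.HIGH,
    "subphylum": Rank.HIGH,
    "kingdom": Rank.HIGH,
    "subkingdom": Rank.HIGH,
    "domain": Rank.HIGH,
    "superkingdom": Rank.HIGH,
    "rootrank": Rank.HIGH,
    "root": Rank.HIGH,
    "clade": Rank.HIGH,
}


def normalize_name(raw: str, convention: str = "plain") -> str:
    """Normalize a single taxon field; returns '' for placeholders.

    Strips rank-prefix codes (``g__``), quotes and whitespace, converts
    underscores to spaces and collapses runs of whitespace.  Total: never
    raises.
    """
    s = raw
    while True:  # to a fixpoint: stripping may expose further quotes/prefixes
        prev = s
        s = s.strip().strip("'\"")
        s = _PREFIX_RE.sub("", s)
        s = " ".join(s.replace("_", " ").split())
        if s == prev:
            break
    if not s or s.casefold() in PLACEHOLDERS:
        return ""
    return s


def canonical_rank(rank_name: str) -> Rank:
    """Map a source rank label onto the five-level scoring ladder.

    Unknown labels degrade to HIGH with a warning so partially annotated
    references still load.
    """
    r = _RANK_MAP.get(rank_name.strip().casefold())
    if r is None:
        logger.warning("unknown rank label %r treated as high-level", rank_name)
        return Rank.HIGH
    return r


@dataclass(frozen=True)
class LineageEntry:
    rank_name: str
    rank: Rank
    name: str


@dataclass(frozen=True)
class Lineage:
    """An ordered lineage from highest to lowest rank.

    Each scoring rank (species..order) appears at most once; several source
    ranks (domain, phylum, class, ...) may collapse into the HIGH bucket and
    all their names are retained for high-level matching.
    """

    entries: tuple[LineageEntry, ...] = ()
    convention: str = field(default="plain", compare=False)

    # -- accessors ---------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return not self.entries

    def name_at(self, rank: Rank) -> Optional[str]:
        """Name at a scoring rank, or None if unnamed there."""
        for e in self.entries:
            if e.rank is rank:
                return e.name
        return None

    def high_names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries if e.rank is Rank.HIGH)

    def deepest_rank(self) -> Rank:
        return max((e.rank for e in self.entries), default=Rank.NONE)

    def deepest_name(self) -> Optional[str]:
        return self.entries[-1].name if self.entries else None

    @property
    def genus(self) -> Optional[str]:
        return self.name_at(Rank.GENUS)

    @property
    def species(self) -> Optional[str]:
        return self.name_at(Rank.SPECIES)

    # -- derived lineages --------------------------------------------------
    def truncated(self, max_rank: Rank) -> "Lineage":
        """Drop every entry deeper than ``max_rank``."""
        return Lineage(
            tuple(e for e in self.entries if e.rank <= max_rank), self.convention
        )

    def drop_deepest(self) -> "Lineage":
        return Lineage(self.entries[:-1], self.convention)

    # -- serialization -----------------------------------------------------
    def to_plain_string(self) -> str:
        return ";".join(e.name for e in self.entries)

    def to_qiime_string(self) -> str:
        if self.is_empty:
            return "Unassigned"
        prefixes = {
            "domain": "d",
            "kingdom": "k",
            "phylum": "p",
            "class": "c",
            "subclass": "c",
            "order": "o",
            "family": "f",
            "genus": "g",
            "species": "s",
        }
        parts = []
        for e in self.entries:
            p = prefixes.get(e.rank_name.casefold())
            name = e.name.replace(" ", "_")
            parts.append(f"{p}__{name}" if p else name)
        return ";".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_plain_string() or "<empty>"


def build_lineage(
    pairs: Iterable[tuple[str, str]], convention: str = "plain"
) -> Lineage:
    """Assemble a Lineage from (rank_name, raw_name) pairs.

    Normalizes names, drops placeholders, completes a bare species epithet
    into the full binomial when the genus is known, and keeps only the first
    occurrence of each scoring rank.
    """
    staged: list[tuple[str, Rank, str]] = []
    for rank_name, raw in pairs:
        name = normalize_name(raw, convention)
        if not name:
            continue
        staged.append((rank_name, canonical_rank(rank_name), name))

    genus = next((n for _, r, n in staged if r is Rank.GENUS), None)
    entries: list[LineageEntry] = []
    seen: set[Rank] = set()
    for rank_name, rank, name in staged:
        if rank is Rank.SPECIES and " " not in name and genus:
            name = f"{genus} {name}"
        if rank is not Rank.HIGH:
            if rank in seen:
                logger.warning("duplicate %s entry %r dropped", rank.label, name)
                continue
            seen.add(rank)
        entries.append(LineageEntry(rank_name, rank, name))
    entries.sort(key=lambda e: e.rank)  # stable: HIGH entries keep source order
    return Lineage(tuple(entries), convention)


_QIIME_PREFIXES = {
    "d": "domain",
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}


def parse_qiime_lineage(text: str) -> Lineage:
    """Parse a semicolon-delimited, rank-prefixed lineage string (``d__Fungi;...``)."""
    if normalize_name(text) == "":
        return Lineage((), "qiime_prefixed")
    pairs = []
    for token in text.split(";"):
        t = token.strip()
        rank_name = "clade"
        if len(t) > 2 and t[1:3] == "__":
            rank_name = _QIIME_PREFIXES.get(t[0].lower(), "clade")
        pairs.append((rank_name, t))
    return build_lineage(pairs, "qiime_prefixed")


_PLAIN_LADDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


def parse_plain_lineage(text: str) -> Lineage:
    """Parse a semicolon-delimited lineage with no rank labels.

    Ranks are positional: top-anchored on the kingdom..species ladder for up
    to seven tokens; when the last token is a two-word binomial (or the
    lineage is deeper than seven tokens) the assignment is anchored at the
    bottom instead (species/genus/family/order upward, the rest high-level).
    """
    tokens = [normalize_name(t) for t in text.split(";")]
    while tokens and not tokens[-1]:
        tokens.pop()
    if not tokens:
        return Lineage((), "plain")
    n = len(tokens)
    last = tokens[-1]
    if " " in last or n > 7:
        tail = ("species", "genus", "family", "order") if " " in last else (
            "genus",
            "family",
            "order",
        )
        ranks = ["clade"] * n
        for i, rname in enumerate(tail):
            idx = n - 1 - i
            if idx < 0:
                break
            ranks[idx] = rname
    else:
        ranks = list(_PLAIN_LADDER[:n])
    return build_lineage(zip(ranks, tokens), "plain")


def _high_set(lin: Lineage) -> set[str]:
    return {n.casefold() for n in lin.high_names()}


def deepest_shared_rank(a: Lineage, b: Lineage) -> Rank:
    """Lowest canonical rank at which both lineages carry equal names.

    Species comparison uses the full binomial; the high bucket matches when
    any supra-ordinal name is shared.  Returns NONE when no rank matches.
    """
    for rank in LADDER:
        na, nb = a.name_at(rank), b.name_at(rank)
        if na is not None and nb is not None and na.casefold() == nb.casefold():
            return rank
    if _high_set(a) & _high_set(b):
        return Rank.HIGH
    return Rank.NONE


def is_consistent_truncation(coarse: Lineage, fine: Lineage) -> bool:
    """True iff ``coarse`` is an ancestor-consistent prefix of ``fine``.

    Every named scoring rank in ``coarse`` must be named identically in
    ``fine``, and the coarse high-level names must be a subset of the fine
    ones.  Distinguishes "coarser but correct" from a genuine conflict.
    """
    for e in coarse.entries:
        if e.rank is Rank.HIGH:
            continue
        other = fine.name_at(e.rank)
        if other is None or other.casefold() != e.name.casefold():
            return False
    return _high_set(coarse) <= _high_set(fine)
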