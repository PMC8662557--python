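"""Diagnose the cause of each misidentification.

Two mechanisms drive simple-matching misidentifications against a curated
gold standard:

* **Underrepresentation** — the query's true genus is absent from the
  reference dataset, so the classifier can only return a close relative.
  Detected by an exact normalized-name membership check of the gold genus
  (and species) over the reference lineages.

* **Mislabeled reference** — the reference sequence the classifier matched
  carries a wrong deposited name.  Detected by a leave-one-out neighbor
  vote: each reference sequence is ranked against all others by canonical
  k-mer containment similarity, and a record is flagged when none of its
  qualifying nearest neighbors shares its labeled genus.  This is the
  in-dataset analogue of querying a suspect reference against a large
  database and finding no same-name sequences among the top hits.

A misidentified OTU whose gold genus is missing *and* whose matched
reference is flagged is attributed to both mechanisms; one with neither is
reported as unexplained rather than forced into a category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .concordance import ConcordanceRow
from .io import Assignment, ReferenceRecord
from .taxonomy import Lineage, Rank

logger = logging.getLogger(__name__)

__all__ = [
    "RepresentationCheck",
    "MislabelVerdict",
    "DiagnosisRow",
    "check_representation",
    "kmer_similarity",
    "neighbor_vote_screen",
    "classify_cause",
    "cause_breakdown",
    "diagnose",
]

CAUSES = ("mislabeled_reference", "underrepresentation", "both", "unexplained", "not_misidentified")


@dataclass(frozen=True)
class RepresentationCheck:
    otu_id: str
    target_genus: Optional[str]
    target_species: Optional[str]
    genus_present: bool
    species_present: bool


@dataclass(frozen=True)
class MislabelVerdict:
    accession: str
    labeled_genus: Optional[str]
    neighbor_ids: tuple[str, ...]
    conspecific_hits: int
    congeneric_hits: int
    flagged: bool


@dataclass(frozen=True)
class DiagnosisRow:
    otu_id: str
    cause: str
    gold_genus: Optional[str] = None
    genus_present: bool = False
    species_present: bool = False
    matched_accessions: tuple[str, ...] = ()
    flagged_accessions: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# representation


def check_representation(
    gold: Assignment, reference: Sequence[ReferenceRecord]
) -> RepresentationCheck:
    """Is the gold genus (and species) represented in the reference dataset?"""
    if not reference:
        raise ValueError("empty reference set")
    genus = gold.lineage.genus
    species = gold.lineage.species
    if genus is None:
        logger.warning("%s: gold lineage names no genus; representation undefined", gold.otu_id)
        return RepresentationCheck(gold.otu_id, None, species, False, False)
    genus_cf = genus.casefold()
    species_cf = species.casefold() if species else None
    genus_present = False
    species_present = False
    for rec in reference:
        g = rec.lineage.genus
        if g is not None and g.casefold() == genus_cf:
            genus_present = True
        if species_cf is not None:
            s = rec.lineage.species
            if s is not None and s.casefold() == species_cf:
                species_present = True
    return RepresentationCheck(gold.otu_id, genus, species, genus_present, species_present)


# ---------------------------------------------------------------------------
# k-mer similarity screen

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def kmer_set(seq: str, k: int) -> frozenset[str]:
    """Canonical k-mer set of a sequence; k-mers containing N are excluded."""
    seq = seq.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if not _VALID.issuperset(kmer):
            continue
        out.add(min(kmer, _revcomp(kmer)))
    return frozenset(out)


def kmer_similarity(seq_a: str, seq_b: str, k: int = 8, name: str = "") -> float:
    """Containment similarity |K(a) n K(b)| / min(|K(a)|, |K(b)|).

    Canonical k-mers (a k-mer and its reverse complement identified) make
    the measure strand-insensitive.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if len(seq_a) < k or len(seq_b) < k:
        raise ValueError(f"sequence shorter than k={k}" + (f" ({name})" if name else ""))
    ka, kb = kmer_set(seq_a, k), kmer_set(seq_b, k)
    m = min(len(ka), len(kb))
    if m == 0:
        return 0.0
    return len(ka & kb) / m


def _set_similarity(ka: frozenset[str], kb: frozenset[str]) -> float:
    m = min(len(ka), len(kb))
    return len(ka & kb) / m if m else 0.0


def neighbor_vote_screen(
    reference: Sequence[ReferenceRecord],
    k: int = 8,
    top_n: int = 50,
    min_similarity: float = 0.1,
    flag_on: str = "genus",
) -> list[MislabelVerdict]:
    """Leave-one-out label vote over the reference set.

    For each sequenced record, all other records with containment
    similarity >= ``min_similarity`` are ranked (ties broken by accession)
    and the ``top_n`` nearest are inspected.  With ``flag_on='genus'`` a
    record is flagged when it has at least one qualifying neighbor and none
    shares its labeled genus; ``flag_on='species'`` additionally demands a
    conspecific hit.  Deterministic and seed-free.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if flag_on not in {"genus", "species"}:
        raise ValueError(f"flag_on must be 'genus' or 'species', got {flag_on!r}")
    sequenced = []
    for rec in reference:
        if rec.sequence is None:
            logger.warning("reference %s has no sequence; skipped by screen", rec.accession)
            continue
        sequenced.append(rec)
    if len(sequenced) < 2:
        raise ValueError("mislabel screen needs at least 2 sequenced reference records")
    sets = {}
    for rec in sequenced:
        if len(rec.sequence) < k:
            raise ValueError(f"sequence shorter than k={k} ({rec.accession})")
        sets[rec.accession] = kmer_set(rec.sequence, k)

    verdicts: list[MislabelVerdict] = []
    for rec in sequenced:
        sims = []
        for other in sequenced:
            if other.accession == rec.accession:
                continue
            s = _set_similarity(sets[rec.accession], sets[other.accession])
            if s >= min_similarity:
                sims.append((-s, other.accession, other))
        sims.sort(key=lambda t: (t[0], t[1]))
        neighbors = [t[2] for t in sims[:top_n]]
        genus = rec.lineage.genus
        species = rec.lineage.species
        congeneric = sum(
            1
            for nb in neighbors
            if genus is not None
            and nb.lineage.genus is not None
            and nb.lineage.genus.casefold() == genus.casefold()
        )
        conspecific = sum(
            1
            for nb in neighbors
            if species is not None
            and nb.lineage.species is not None
            and nb.lineage.species.casefold() == species.casefold()
        )
        if not neighbors:
            flagged = False  # no comparable neighbors: no evidence either way
        elif flag_on == "genus":
            flagged = congeneric == 0
        else:
            flagged = conspecific == 0
        verdicts.append(
            MislabelVerdict(
                rec.accession,
                genus,
                tuple(nb.accession for nb in neighbors),
                conspecific,
                congeneric,
                flagged,
            )
        )
    return verdicts


# ---------------------------------------------------------------------------
# cause classification


def records_matching_assignment(
    assignment: Assignment, reference: Sequence[ReferenceRecord]
) -> list[ReferenceRecord]:
    """Reference records whose lineage matches the assignment at its deepest rank.

    Classifier outputs carry no accession, so the matched reference is
    recovered by name: every record naming the assignment's deepest taxon
    at the same rank is a candidate.
    """
    lin = assignment.lineage
    deepest = lin.deepest_rank()
    if deepest is Rank.NONE:
        return []
    if deepest is Rank.HIGH:
        names = {n.casefold() for n in lin.high_names()}
        return [
            rec
            for rec in reference
            if names & {n.casefold() for n in rec.lineage.high_names()}
        ]
    target = lin.name_at(deepest)
    out = []
    for rec in reference:
        n = rec.lineage.name_at(deepest)
        if n is not None and n.casefold() == target.casefold():
            out.append(rec)
    return out


def classify_cause(
    concordance_row: ConcordanceRow,
    method_assignment: Assignment,
    gold: Assignment,
    rep_check: RepresentationCheck,
    verdicts: dict[str, MislabelVerdict],
    reference: Sequence[ReferenceRecord],
) -> DiagnosisRow:
    """Attribute one misidentification to its mechanism(s).

    Underrepresentation: the gold genus is absent from the reference.
    Mislabel: some reference record matching the method's (wrong) assignment
    is flagged by the neighbor-vote screen (when several records share the
    name, any flagged one suffices).
    """
    if not concordance_row.misidentified:
        return DiagnosisRow(
            concordance_row.otu_id,
            "not_misidentified",
            rep_check.target_genus,
            rep_check.genus_present,
            rep_check.species_present,
        )
    underrep = not rep_check.genus_present
    matched = records_matching_assignment(method_assignment, reference)
    flagged = tuple(
        rec.accession
        for rec in matched
        if rec.accession in verdicts and verdicts[rec.accession].flagged
    )
    mislabel = bool(flagged)
    if underrep and mislabel:
        cause = "both"
    elif underrep:
        cause = "underrepresentation"
    elif mislabel:
        cause = "mislabeled_reference"
    else:
        cause = "unexplained"
    return DiagnosisRow(
        concordance_row.otu_id,
        cause,
        rep_check.target_genus,
        rep_check.genus_present,
        rep_check.species_present,
        tuple(rec.accession for rec in matched),
        flagged,
    )


def cause_breakdown(rows: Sequence[DiagnosisRow]) -> dict:
    """Fractions of misidentified OTUs per cause.

    'both' is its own bucket and is also merged into each constituent's
    *_involved fraction (for "more than half involved underrepresentation"
    style statements).  Fractions over misidentified OTUs sum to 1 across
    the four exclusive buckets.
    """
    mis = [r for r in rows if r.cause != "not_misidentified"]
    n = len(mis)
    counts = {c: sum(1 for r in mis if r.cause == c) for c in CAUSES if c != "not_misidentified"}
    frac = {c: (counts[c] / n if n else 0.0) for c in counts}
    return {
        "n_misidentified": n,
        "counts": counts,
        "fractions": frac,
        "underrepresentation_involved": frac["underrepresentation"] + frac["both"],
        "mislabel_involved": frac["mislabeled_reference"] + frac["both"],
    }


def diagnose(
    method_assignments: Sequence[Assignment],
    gold_assignments: Sequence[Assignment],
    reference: Sequence[ReferenceRecord],
    concordance_rows: Sequence[ConcordanceRow],
    k: int = 8,
    top_n: int = 50,
    min_similarity: float = 0.1,
    flag_on: str = "genus",
    verdicts: Optional[Sequence[MislabelVerdict]] = None,
) -> tuple[list[DiagnosisRow], list[MislabelVerdict]]:
    """Run the full diagnosis for one method against the gold standard."""
    if verdicts is None:
        verdicts = neighbor_vote_screen(reference, k=k, top_n=top_n, min_similarity=min_similarity, flag_on=flag_on)
    vmap = {v.accession: v for v in verdicts}
    gold_by_otu = {g.otu_id: g for g in gold_assignments}
    method_by_otu = {m.otu_id: m for m in method_assignments}
    out = []
    for row in concordance_rows:
        gold = gold_by_otu[row.otu_id]
        rep = check_representation(gold, reference)
        out.append(
            classify_cause(row, method_by_otu[row.otu_id], gold, rep, vmap, reference)
        )
    return out, list(verdicts)
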