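"""Readers and writers for the assignment tables and sequence files.

Supported dialects:

* QIIME 2 taxonomy TSV — header ``Feature ID / Taxon / Confidence``
  (case-insensitive), lineage in the ``d__Fungi;p__...`` prefixed form.
* RDP Classifier fixrank TSV — headerless; OTU id, an optional orientation
  field, then repeated ``name / rank / bootstrap`` triples from rootrank
  downward.
* Gold-standard TSV — header ``otu_id / lineage / support``; plain
  semicolon lineage; bootstrap support on the 0-100 scale.
* Reference taxonomy — two-column TSV ``accession <tab> lineage`` or a
  FASTA whose headers carry ``accession lineage`` (SILVA dialect), with an
  optional companion FASTA supplying sequences keyed by accession.

Low-confidence QIIME rows are blanked rather than dropped so the OTU count
stays constant across methods; RDP lineages are truncated at the first rank
whose bootstrap falls below the threshold.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import Lineage, Rank, build_lineage, parse_plain_lineage, parse_qiime_lineage

logger = logging.getLogger(__name__)

__all__ = [
    "Assignment",
    "ReferenceRecord",
    "FormatError",
    "read_qiime2_taxonomy",
    "read_rdp_fixrank",
    "read_gold_standard",
    "read_reference_taxonomy",
    "read_fasta",
    "write_qiime2_taxonomy",
    "write_rdp_fixrank",
    "write_gold_standard",
    "write_reference_taxonomy",
    "write_fasta",
    "write_report",
    "format_pct",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class Assignment:
    """One method's identification of one OTU."""

    otu_id: str
    lineage: Lineage
    confidence: Optional[float] = None
    method: str = "other"

    def __post_init__(self) -> None:
        if not self.otu_id:
            raise ValueError("otu_id must be non-empty")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference-dataset entry: accession, lineage, optional sequence."""

    accession: str
    lineage: Lineage
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: empty sequence")


# ---------------------------------------------------------------------------
# readers


def _find_column(header: Sequence[str], candidates: Sequence[str], path: str) -> int:
    lowered = [h.strip().casefold().replace("-", " ").replace("_", " ") for h in header]
    for cand in candidates:
        if cand in lowered:
            return lowered.index(cand)
    raise FormatError(f"{path}: missing required column (one of {candidates}); got {header}")


def read_qiime2_taxonomy(
    path: str | Path, confidence_threshold: Optional[float] = None
) -> list[Assignment]:
    """Read a QIIME 2 taxonomy TSV.

    Rows whose confidence falls below ``confidence_threshold`` (when given)
    keep their OTU id but have the lineage blanked — they count as
    unassigned, not missing.
    """
    path = Path(path)
    out: list[Assignment] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        i_id = _find_column(header, ["feature id", "featureid", "otu id", "otu"], str(path))
        i_tax = _find_column(header, ["taxon", "taxonomy", "lineage"], str(path))
        i_conf = _find_column(header, ["confidence", "consensus"], str(path))
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                otu, tax = row[i_id], row[i_tax]
            except IndexError:
                raise FormatError(f"{path}:{lineno}: expected at least 3 columns")
            conf_raw = row[i_conf].strip() if i_conf < len(row) else ""
            conf: Optional[float] = None
            if conf_raw:
                try:
                    conf = float(conf_raw)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: unparseable confidence {conf_raw!r}")
            lineage = parse_qiime_lineage(tax)
            if (
                confidence_threshold is not None
                and conf is not None
                and conf < confidence_threshold
            ):
                lineage = Lineage((), "qiime_prefixed")
            out.append(Assignment(otu, lineage, conf, "qiime_silva"))
    return out


def read_rdp_fixrank(path: str | Path, bootstrap_threshold: float = 0.0) -> list[Assignment]:
    """Read RDP Classifier fixrank output.

    The lineage keeps the deepest consecutive run of ranks (from rootrank
    downward) whose bootstrap is at least ``bootstrap_threshold``; the
    assignment confidence is the bootstrap of the deepest retained rank.
    Species-level triples are dropped: fixrank references resolve to genus.
    """
    path = Path(path)
    out: list[Assignment] = []
    with path.open(newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            otu = fields[0]
            rest = fields[1:]
            if rest and rest[0].strip() in {"", "-", "+"}:
                rest = rest[1:]
            if len(rest) % 3 != 0:
                raise FormatError(
                    f"{path}:{lineno}: fixrank triples misaligned "
                    f"({len(rest)} fields after id/orientation)"
                )
            pairs: list[tuple[str, str]] = []
            conf: Optional[float] = None
            for i in range(0, len(rest), 3):
                name, rank_name, boot_raw = rest[i], rest[i + 1], rest[i + 2]
                try:
                    boot = float(boot_raw)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: unparseable bootstrap {boot_raw!r}")
                if boot < bootstrap_threshold:
                    break
                if rank_name.strip().casefold() == "species":
                    logger.debug("%s:%d: species triple dropped (fixrank)", path, lineno)
                    continue
                pairs.append((rank_name, name))
                conf = boot
            out.append(Assignment(otu, build_lineage(pairs, "rdp_fixrank"), conf, "rdp"))
    return out


def read_gold_standard(path: str | Path) -> list[Assignment]:
    """Read the phylogenetic-binning gold standard TSV (support on 0-100)."""
    path = Path(path)
    out: list[Assignment] = []
    seen: dict[str, int] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        i_id = _find_column(header, ["otu id", "otu", "feature id"], str(path))
        i_tax = _find_column(header, ["lineage", "taxon", "taxonomy"], str(path))
        lowered = [h.strip().casefold() for h in header]
        i_sup = next(
            (lowered.index(c) for c in ("support", "bootstrap", "confidence") if c in lowered),
            None,
        )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            otu = row[i_id]
            seen[otu] = seen.get(otu, 0) + 1
            conf: Optional[float] = None
            if i_sup is not None and i_sup < len(row) and row[i_sup].strip():
                try:
                    conf = float(row[i_sup]) / 100.0
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: unparseable support {row[i_sup]!r}")
            out.append(Assignment(otu, parse_plain_lineage(row[i_tax]), conf, "binning"))
    dups = sorted(o for o, k in seen.items() if k > 1)
    if dups:
        raise FormatError(f"{path}: duplicate OTU ids: {', '.join(dups)}")
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_reference_taxonomy(
    taxonomy_path: str | Path, fasta_path: Optional[str | Path] = None
) -> list[ReferenceRecord]:
    """Read a reference taxonomy (TSV or SILVA-dialect FASTA), with sequences.

    When ``taxonomy_path`` is a FASTA, its headers must carry
    ``accession lineage`` and its sequences are used directly; a separate
    ``fasta_path`` attaches sequences to a TSV taxonomy by accession.
    """
    taxonomy_path = Path(taxonomy_path)
    entries: list[tuple[str, Lineage, Optional[str]]] = []
    with taxonomy_path.open() as fh:
        first = fh.read(1)
    if first == ">":
        for rec in SeqIO.parse(str(taxonomy_path), "fasta"):
            # description is "accession lineage..."
            lineage_text = rec.description[len(rec.id) :].strip()
            entries.append((rec.id, parse_plain_lineage(lineage_text), str(rec.seq).upper()))
    else:
        with taxonomy_path.open(newline="") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(
                        f"{taxonomy_path}:{lineno}: expected 'accession<TAB>lineage'"
                    )
                if lineno == 1 and parts[0].strip().casefold() in {"accession", "id"}:
                    continue
                entries.append((parts[0].strip(), parse_plain_lineage(parts[1]), None))
    if not entries:
        raise FormatError(f"{taxonomy_path}: no parseable reference rows")

    accs = [a for a, _, _ in entries]
    dup = sorted({a for a in accs if accs.count(a) > 1})
    if dup:
        raise FormatError(f"{taxonomy_path}: duplicated accessions: {', '.join(dup)}")

    seqs: dict[str, str] = {}
    if fasta_path is not None:
        seqs = read_fasta(fasta_path)
    records = []
    known = set(accs)
    for acc, lineage, seq in entries:
        seq = seqs.get(acc, seq)
        if seq is None:
            logger.warning("reference %s has no sequence", acc)
        records.append(ReferenceRecord(acc, lineage, seq))
    for acc in seqs:
        if acc not in known:
            logger.warning("sequence %s has no taxonomy entry; skipped", acc)
    return records


# ---------------------------------------------------------------------------
# writers


def write_qiime2_taxonomy(assignments: Iterable[Assignment], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write("Feature ID\tTaxon\tConfidence\n")
        for a in assignments:
            conf = "" if a.confidence is None else f"{a.confidence:.10g}"
            fh.write(f"{a.otu_id}\t{a.lineage.to_qiime_string()}\t{conf}\n")


def write_rdp_fixrank(assignments: Iterable[Assignment], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        for a in assignments:
            boot = 1.0 if a.confidence is None else a.confidence
            fields = [a.otu_id, "-"]
            for e in a.lineage.entries:
                fields += [e.name, e.rank_name, f"{boot:.10g}"]
            fh.write("\t".join(fields) + "\n")


def write_gold_standard(assignments: Iterable[Assignment], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write("otu_id\tlineage\tsupport\n")
        for a in assignments:
            sup = "" if a.confidence is None else f"{a.confidence * 100:.10g}"
            fh.write(f"{a.otu_id}\t{a.lineage.to_plain_string()}\t{sup}\n")


def write_reference_taxonomy(
    records: Iterable[ReferenceRecord],
    taxonomy_path: str | Path,
    fasta_path: Optional[str | Path] = None,
) -> None:
    records = list(records)
    with Path(taxonomy_path).open("w", newline="") as fh:
        for r in records:
            fh.write(f"{r.accession}\t{r.lineage.to_plain_string()}\n")
    if fasta_path is not None:
        write_fasta(
            {r.accession: r.sequence for r in records if r.sequence is not None}, fasta_path
        )


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# reports


def format_pct(fraction: float) -> str:
    """Render a fraction as a one-decimal percentage string ('0.375' -> '37.5%')."""
    return f"{fraction * 100:.1f}%"


def _cell(value: object) -> str:
    if isinstance(value, Lineage):
        return value.to_plain_string()
    if isinstance(value, Rank):
        return value.label
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return f"{value:.10g}"
    if isinstance(value, (tuple, list)):
        return ",".join(str(v) for v in value)
    return str(value)


def _jsonable(value: object) -> object:
    if isinstance(value, Lineage):
        return value.to_plain_string()
    if isinstance(value, Rank):
        return value.label
    if isinstance(value, (tuple, list)):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {f.name: _jsonable(getattr(value, f.name)) for f in dataclasses.fields(value)}
    return value


def write_report(rows: Sequence[object], summary: dict, path: str | Path, format: str = "tsv") -> None:
    """Write result rows plus a summary block.

    ``tsv`` writes the rows as a TSV at ``path`` and the summary as JSON at
    ``<path stem>.summary.json`` next to it; ``json`` writes a single JSON
    document ``{"summary": ..., "rows": [...]}``.  Column order follows the
    row dataclass field order, so output is deterministic.
    """
    path = Path(path)
    summary_json = _jsonable(summary)
    if format == "json":
        with path.open("w") as fh:
            json.dump({"summary": summary_json, "rows": _jsonable(list(rows))}, fh, indent=2)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    if rows:
        fields = [f.name for f in dataclasses.fields(rows[0])]
    else:
        fields = ["otu_id"]
    with path.open("w", newline="") as fh:
        fh.write("\t".join(fields) + "\n")
        for row in rows:
            fh.write("\t".join(_cell(getattr(row, f)) for f in fields) + "\n")
    sidecar = path.with_suffix(".summary.json")
    with sidecar.open("w") as fh:
        json.dump(summary_json, fh, indent=2)
        fh.write("\n")
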