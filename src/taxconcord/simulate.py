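"""Ground-truthed synthetic fixtures for the whole pipeline.

The generator emulates a small fungal LSU metabarcoding study: a synthetic
taxonomy (genera nested under families, orders and higher clades), one
marker-length sequence per species (genus ancestors diverge from a common
root, species diverge from their genus ancestor by point substitutions),
a reference dataset with two kinds of planted flaws —

* *underrepresentation*: a fraction of genera is dropped from the
  reference entirely;
* *mislabels*: labels of randomly chosen cross-genus record pairs are
  swapped;

— and three assignment tables over a shared OTU set: a gold-standard table
carrying the true lineages, and two simple-matching tables produced by a
deterministic nearest-reference classifier (canonical k-mer containment,
ties broken by accession), one reporting full lineages (QIIME-style) and
one truncated at genus (RDP-style).  Planted flaws therefore propagate
into misidentifications exactly: an OTU from a dropped genus is forced
onto a relative, an OTU whose nearest record was relabeled inherits the
wrong name.

Every stochastic choice is drawn from a single seeded generator in a fixed
order (taxonomy names, sequences, genus dropout, label swaps, OTU draws,
gold supports, per-method noise), so a config reproduces its fixture files
byte for byte.  The truth manifest records every planted flaw and each
OTU's intended per-method verdict and cause, sufficient to recompute the
expected misidentification rate and cause breakdown exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .diagnosis import kmer_set, records_matching_assignment, _set_similarity
from .io import (
    Assignment,
    ReferenceRecord,
    write_fasta,
    write_gold_standard,
    write_qiime2_taxonomy,
    write_rdp_fixrank,
)
from .taxonomy import Lineage, Rank, is_consistent_truncation, parse_plain_lineage

__all__ = [
    "SimulationConfig",
    "SyntheticTaxonomy",
    "TruthManifest",
    "SimulationResult",
    "generate_taxonomy",
    "generate_sequences",
    "build_reference",
    "simulate_assignments",
    "generate",
    "write_fixtures",
    "parse_config_file",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_KMER_K = 8  # word size of the simulated nearest-reference classifier


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    Defaults emulate a 71-OTU survey classified against a reference with a
    modest genus shortfall and a couple of swapped labels; divergences are
    on the scale of congeneric vs confamilial LSU D1-D3 fragments.
    """

    n_genera: int = 30
    species_per_genus: int = 3
    n_otus: int = 71
    genus_dropout_fraction: float = 0.15
    mislabel_fraction: float = 0.04
    seq_length: int = 600
    inter_genus_divergence: float = 0.20
    intra_genus_divergence: float = 0.03
    classifier_noise: float = 0.25
    seed: int = 20

    def __post_init__(self) -> None:
        for name in ("genus_dropout_fraction", "mislabel_fraction", "classifier_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.intra_genus_divergence < self.inter_genus_divergence:
            raise ValueError("intra_genus_divergence must be < inter_genus_divergence")
        if self.n_genera < 1 or self.species_per_genus < 1 or self.n_otus < 0:
            raise ValueError("counts must be positive")
        if self.seq_length < 100:
            raise ValueError("seq_length must be >= 100")


def parse_config_file(path: str | Path) -> SimulationConfig:
    """Parse a plain ``key = value`` config file into a SimulationConfig."""
    fields = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}
    kwargs = {}
    for lineno, line in enumerate(Path(path).open(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise KeyError(f"{path}:{lineno}: unknown config key {key!r}")
        caster = float if "float" in str(fields[key]) else int
        kwargs[key] = caster(value)
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# taxonomy


@dataclass(frozen=True)
class SyntheticTaxonomy:
    species_lineages: tuple[Lineage, ...]  # one per species, full 7-rank ladder
    genera: tuple[str, ...]

    @property
    def n_species(self) -> int:
        return len(self.species_lineages)

    def genus_of(self, i: int) -> str:
        return self.species_lineages[i].genus


_SYLLABLES = (
    "ba", "ce", "do", "fu", "gi", "lo", "mi", "na", "po", "ru",
    "sa", "ti", "ve", "xa", "zo", "qua", "ler", "mon", "pis", "tur",
)


def _fresh_name(rng: np.random.Generator, used: set[str], n_syll: int = 3, suffix: str = "") -> str:
    while True:
        idx = rng.integers(0, len(_SYLLABLES), size=n_syll)
        name = "".join(_SYLLABLES[i] for i in idx) + suffix
        if name not in used:
            used.add(name)
            return name


def generate_taxonomy(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> SyntheticTaxonomy:
    """Collision-free synthetic taxonomy: genera grouped 3-per-family, etc."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    used: set[str] = set()
    genera = [_fresh_name(rng, used).capitalize() for _ in range(config.n_genera)]
    n_fam = (config.n_genera + 2) // 3
    families = [_fresh_name(rng, used).capitalize() + "aceae" for _ in range(n_fam)]
    n_ord = (n_fam + 2) // 3
    orders = [_fresh_name(rng, used).capitalize() + "ales" for _ in range(n_ord)]
    n_cls = (n_ord + 2) // 3
    classes = [_fresh_name(rng, used).capitalize() + "mycetes" for _ in range(n_cls)]
    phylum = _fresh_name(rng, used).capitalize() + "mycota"
    lineages = []
    for gi, genus in enumerate(genera):
        fam = families[gi // 3]
        order = orders[gi // 9]
        cls = classes[gi // 27]
        for _ in range(config.species_per_genus):
            epithet = _fresh_name(rng, used, n_syll=2) + "um"
            text = f"Fungi;{phylum};{cls};{order};{fam};{genus};{genus} {epithet}"
            lineages.append(parse_plain_lineage(text))
    return SyntheticTaxonomy(tuple(lineages), tuple(genera))


# ---------------------------------------------------------------------------
# sequences


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point substitutions: each site changes to a different base with prob ``rate``."""
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits):
        # shift by 1..3 in base space guarantees a different base
        shift = rng.integers(1, 4, size=len(hits))
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + shift) % 4]
    return out


def generate_sequences(
    taxonomy: SyntheticTaxonomy,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, str]:
    """One marker sequence per species, keyed by the species binomial.

    Genus ancestors diverge from a shared root at ``inter_genus_divergence``
    substitutions per site; species diverge from their genus ancestor at
    ``intra_genus_divergence``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    root = _BASES[rng.integers(0, 4, size=config.seq_length)]
    out: dict[str, str] = {}
    i = 0
    for genus in taxonomy.genera:
        ancestor = _mutate(root, config.inter_genus_divergence, rng)
        for _ in range(config.species_per_genus):
            lineage = taxonomy.species_lineages[i]
            seq = _mutate(ancestor, config.intra_genus_divergence, rng)
            out[lineage.species] = seq.tobytes().decode()
            i += 1
    return out


# ---------------------------------------------------------------------------
# reference with planted flaws


@dataclass
class TruthManifest:
    """Everything the generator planted, for exact downstream verification."""

    config: dict
    dropped_genera: list[str] = field(default_factory=list)
    swapped_pairs: list[tuple[str, str]] = field(default_factory=list)
    records: dict[str, dict] = field(default_factory=dict)  # acc -> true/labeled/mislabeled
    otus: dict[str, dict] = field(default_factory=dict)  # otu -> true lineage + per-method verdicts
    expected: dict = field(default_factory=dict)

    @property
    def swapped_accessions(self) -> set[str]:
        return {acc for pair in self.swapped_pairs for acc in pair}

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with Path(path).open() as fh:
            d = json.load(fh)
        d["swapped_pairs"] = [tuple(p) for p in d["swapped_pairs"]]
        return cls(**d)


def build_reference(
    taxonomy: SyntheticTaxonomy,
    sequences: dict[str, str],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    manifest: Optional[TruthManifest] = None,
) -> tuple[list[ReferenceRecord], TruthManifest]:
    """Reference records with genus dropout and cross-genus label swaps planted."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if manifest is None:
        manifest = TruthManifest(dataclasses.asdict(config))

    n_drop = int(round(config.genus_dropout_fraction * config.n_genera))
    dropped: set[str] = set()
    if n_drop:
        picks = rng.choice(config.n_genera, size=n_drop, replace=False)
        dropped = {taxonomy.genera[i] for i in picks}
    if len(dropped) == config.n_genera and config.n_otus > 0:
        raise ValueError("genus dropout removed the entire reference")
    manifest.dropped_genera = sorted(dropped)

    kept = [
        (i, lin)
        for i, lin in enumerate(taxonomy.species_lineages)
        if lin.genus not in dropped
    ]
    labels = [lin for _, lin in kept]  # labels start truthful, then swaps are planted
    accs = [f"REF{i:04d}" for i, _ in kept]

    n_pairs = int(round(config.mislabel_fraction * len(kept) / 2))
    swapped_pairs: list[tuple[str, str]] = []
    if n_pairs:
        if len({lin.genus for lin in labels}) < 2:
            raise ValueError("cannot plant cross-genus swaps with fewer than 2 genera")
        available = list(range(len(kept)))
        for _ in range(n_pairs):
            for _attempt in range(1000):
                pick = rng.choice(len(available), size=2, replace=False)
                ia, ib = available[pick[0]], available[pick[1]]
                if labels[ia].genus != labels[ib].genus:
                    break
            else:
                raise ValueError("could not find a cross-genus pair to swap")
            labels[ia], labels[ib] = labels[ib], labels[ia]
            swapped_pairs.append((accs[ia], accs[ib]))
            for used_idx in sorted((pick[0], pick[1]), reverse=True):
                del available[used_idx]
    manifest.swapped_pairs = swapped_pairs
    swapped = {a for pair in swapped_pairs for a in pair}

    records = []
    for (acc, (_, true_lin), label_lin) in zip(accs, kept, labels):
        records.append(ReferenceRecord(acc, label_lin, sequences[true_lin.species]))
        manifest.records[acc] = {
            "true_lineage": true_lin.to_plain_string(),
            "labeled_lineage": label_lin.to_plain_string(),
            "mislabeled": acc in swapped,
        }
    return records, manifest


# ---------------------------------------------------------------------------
# simulated assignment tables


def _nearest_reference(
    otu_set: frozenset, ref_sets: list[frozenset], records: Sequence[ReferenceRecord]
) -> tuple[ReferenceRecord, float]:
    best = None
    for rec, rset in zip(records, ref_sets):
        s = _set_similarity(otu_set, rset)
        key = (-s, rec.accession)
        if best is None or key < best[0]:
            best = (key, rec, s)
    return best[1], best[2]


def _intended_call(
    assignment: Assignment,
    true_lineage: Lineage,
    dropped: set[str],
    swapped: set[str],
    reference: Sequence[ReferenceRecord],
) -> dict:
    """The verdict the pipeline is expected to produce for this OTU/method."""
    if assignment.lineage.is_empty:
        return {"lineage": "", "misidentified": False, "cause": "not_misidentified"}
    mis = not is_consistent_truncation(assignment.lineage, true_lineage)
    if not mis:
        return {
            "lineage": assignment.lineage.to_plain_string(),
            "misidentified": False,
            "cause": "not_misidentified",
        }
    underrep = true_lineage.genus in dropped
    matched = records_matching_assignment(assignment, reference)
    mislabel = any(rec.accession in swapped for rec in matched)
    cause = (
        "both"
        if underrep and mislabel
        else "underrepresentation"
        if underrep
        else "mislabeled_reference"
        if mislabel
        else "unexplained"
    )
    return {
        "lineage": assignment.lineage.to_plain_string(),
        "misidentified": True,
        "cause": cause,
    }


def simulate_assignments(
    taxonomy: SyntheticTaxonomy,
    sequences: dict[str, str],
    reference: Sequence[ReferenceRecord],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    manifest: Optional[TruthManifest] = None,
) -> tuple[list[Assignment], list[Assignment], list[Assignment], dict[str, str], TruthManifest]:
    """Three assignment tables (QIIME-style, RDP-style, gold) plus OTU sequences.

    The simulated classifier assigns each OTU the lineage of its most
    k-mer-similar reference record (deterministic; ties by accession); the
    RDP-style table is truncated at genus; ``classifier_noise`` additionally
    truncates a method's call by one rank with that probability.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if manifest is None:
        manifest = TruthManifest(dataclasses.asdict(config))
    dropped = set(manifest.dropped_genera)
    swapped = manifest.swapped_accessions

    species_idx = rng.integers(0, taxonomy.n_species, size=config.n_otus)
    supports = rng.integers(80, 101, size=config.n_otus)
    noise_draws = rng.random(size=(config.n_otus, 2))

    ref_sets = [kmer_set(rec.sequence, _KMER_K) for rec in reference]
    qiime: list[Assignment] = []
    rdp: list[Assignment] = []
    gold: list[Assignment] = []
    otu_seqs: dict[str, str] = {}

    for j, si in enumerate(species_idx):
        otu = f"OTU_{j + 1}"
        true_lin = taxonomy.species_lineages[si]
        seq = sequences[true_lin.species]
        otu_seqs[otu] = seq
        gold.append(Assignment(otu, true_lin, supports[j] / 100.0, "binning"))

        nearest, sim = _nearest_reference(kmer_set(seq, _KMER_K), ref_sets, reference)
        conf = round(min(1.0, sim), 4)
        q_lin = nearest.lineage
        r_lin = nearest.lineage.truncated(Rank.GENUS)
        if noise_draws[j, 0] < config.classifier_noise:
            q_lin = q_lin.drop_deepest()
        if noise_draws[j, 1] < config.classifier_noise:
            r_lin = r_lin.drop_deepest()
        qa = Assignment(otu, q_lin, conf, "qiime_silva")
        ra = Assignment(otu, r_lin, conf, "rdp")
        qiime.append(qa)
        rdp.append(ra)

        manifest.otus[otu] = {
            "true_lineage": true_lin.to_plain_string(),
            "methods": {
                "qiime_silva": _intended_call(qa, true_lin, dropped, swapped, reference),
                "rdp": _intended_call(ra, true_lin, dropped, swapped, reference),
            },
        }

    manifest.expected = _expected_summary(manifest)
    return qiime, rdp, gold, otu_seqs, manifest


def _expected_summary(manifest: TruthManifest) -> dict:
    out = {}
    n = len(manifest.otus)
    for method in ("qiime_silva", "rdp"):
        calls = [o["methods"][method] for o in manifest.otus.values()]
        n_mis = sum(c["misidentified"] for c in calls)
        causes = {}
        for c in calls:
            if c["misidentified"]:
                causes[c["cause"]] = causes.get(c["cause"], 0) + 1
        out[method] = {
            "n_otus": n,
            "n_misidentified": n_mis,
            "misidentification_rate": n_mis / n if n else 0.0,
            "cause_counts": causes,
        }
    return out


# ---------------------------------------------------------------------------
# one-call generation and fixture writing


@dataclass
class SimulationResult:
    config: SimulationConfig
    taxonomy: SyntheticTaxonomy
    sequences: dict[str, str]
    reference: list[ReferenceRecord]
    qiime: list[Assignment]
    rdp: list[Assignment]
    gold: list[Assignment]
    otu_sequences: dict[str, str]
    manifest: TruthManifest


def generate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator with one seeded stream, in documented order."""
    rng = np.random.default_rng(config.seed)
    taxonomy = generate_taxonomy(config, rng)
    sequences = generate_sequences(taxonomy, config, rng)
    reference, manifest = build_reference(taxonomy, sequences, config, rng)
    qiime, rdp, gold, otu_seqs, manifest = simulate_assignments(
        taxonomy, sequences, reference, config, rng, manifest
    )
    return SimulationResult(
        config, taxonomy, sequences, reference, qiime, rdp, gold, otu_seqs, manifest
    )


def write_fixtures(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture directory: 2 FASTA + 3 TSV + manifest JSON.

    The reference FASTA is SILVA-dialect: headers carry
    ``accession lineage`` so it doubles as the reference taxonomy.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "qiime": outdir / "qiime_taxonomy.tsv",
        "rdp": outdir / "rdp_fixrank.tsv",
        "gold": outdir / "gold_standard.tsv",
        "reference": outdir / "reference.fasta",
        "otus": outdir / "otus.fasta",
        "manifest": outdir / "manifest.json",
    }
    write_qiime2_taxonomy(result.qiime, paths["qiime"])
    write_rdp_fixrank(result.rdp, paths["rdp"])
    write_gold_standard(result.gold, paths["gold"])
    with paths["reference"].open("w") as fh:
        for rec in result.reference:
            fh.write(f">{rec.accession} {rec.lineage.to_plain_string()}\n{rec.sequence}\n")
    write_fasta(result.otu_sequences, paths["otus"])
    result.manifest.to_json(paths["manifest"])
    return paths
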