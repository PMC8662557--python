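# Methods

## Scope and model

The package compares per-OTU taxonomic identifications from several
methods over one shared OTU set. One method (manual phylogenetic binning)
is designated the gold standard; the others (simple-matching classifiers)
are scored against it and against each other. Three model components carry
the analysis: a rank-weighted agreement score, a conflict-based
misidentification call, and a two-mechanism cause attribution for each
misidentification.

### The rank ladder

All source taxonomies (SILVA-style 6–7 rank ladders, RDP fixrank ladders,
free-form binning lineages) are projected onto five comparison levels:
species (5), genus (4), family (3), order (2) and a single "high" bucket
(1) that absorbs class, subclass, phylum, kingdom, domain and RDP's
rootrank. The projection is deliberate: supra-ordinal agreement carries
little identification value in metabarcoding practice, and collapsing it
into one level keeps the score interpretable. Because several source ranks
map to "high", a lineage keeps *all* its high-level names; matching at the
high level means any shared name, and consistency at the high level means
name-set inclusion. A comparison matching at no level scores 0, the only
choice that keeps Σs/(5N) within [0, 1] while leaving every OTU in the
denominator. Unknown rank labels (e.g. "subfamily") degrade to "high" with
a warning rather than erroring, so partially annotated references load.

### Misidentification

"Misidentified" is operationalized as a genuine conflict: the method
lineage is not an ancestor-consistent truncation of the gold lineage.
Coarseness is not an error (a genus-level call under a species-level gold
lineage is correct), and an empty assignment is "unresolved", kept in N
with score 0 and counted separately. Species names compare as full
binomials so congeners' shared epithets cannot collide across genera; all
name comparison is case-insensitive exact match after normalization — no
synonym or orthography reconciliation is attempted.

### Cause attribution

* *Underrepresentation*: the gold genus does not appear in any reference
  lineage. Genus absence is the primary criterion; species absence is
  computed and reported alongside but does not by itself constitute
  underrepresentation.
* *Mislabeled reference*: the classifier's chosen reference record is
  recovered by name (classifier tables carry no accessions): every record
  whose lineage matches the assignment at its deepest rank is a candidate,
  and the condition holds if any candidate is flagged by the neighbor-vote
  screen.
* *both* when both conditions hold; *unexplained* when neither does. Real
  data can produce unexplained cases (e.g. classifier noise); the
  simulator's noise-free runs cannot.

### The neighbor-vote mislabel screen

For each sequenced reference record, all other records are ranked by
**canonical k-mer containment similarity** |K(a) ∩ K(b)| / min(|K(a)|,
|K(b)|), where K(·) is the set of canonical k-mers (a k-mer identified
with its reverse complement; windows containing N are skipped). The record
is flagged when it has at least one *qualifying* neighbor — similarity ≥
`min_similarity` — and none of its `top_n` nearest qualifying neighbors
shares its labeled genus (a stricter conspecific criterion is available
via `flag_on="species"`).

Parameter defaults, with rationale:

| parameter | default | why |
|---|---|---|
| `k` | 8 | ~600 nt LSU D1–D3 fragments yield dense 8-mer profiles (~590 windows over a 65,536-word space), so unrelated sequences share few canonical 8-mers while congeners share most |
| `top_n` | 50 | mirrors the common practice of inspecting the top 50 database hits for a suspect sequence |
| `min_similarity` | 0.1 | the analogue of a database search reporting only significant alignments; at the divergence scales above, within-genus containment is ≈ 0.6 and cross-genus background ≈ 0.02–0.04, so 0.1 cleanly separates "real neighbor" from noise. Without a floor, any reference smaller than `top_n` would make every record everyone's neighbor and the screen could flag nothing |

The no-qualifying-neighbor case is deliberately *not* flagged: a record
with no close relative in the dataset provides no evidence about its
label. Ties in similarity are broken by accession order, so the screen is
fully deterministic and seed-free. One known symmetric ambiguity: if a
genus is represented by exactly two identical-cluster sequences and one is
mislabeled, both members of the cluster can be flagged — the screen cannot
tell which label is wrong, only that the labels disagree with sequence
similarity; three or more correctly labeled congeners resolve it.

## The synthetic-data generator

The generator emulates the structure of a small fungal LSU metabarcoding
benchmark: N query OTUs identified by (a) a gold-standard binning table
carrying the true lineages, and (b) two simple-matching classifiers run
against a flawed reference. It makes no attempt to imitate naive-Bayes
internals: the simulated classifier is nearest-reference by the same
canonical k-mer containment the screen uses, chosen so the propagation of
planted flaws into misidentifications is deterministic and analytically
predictable.

Components, in the order they are drawn from a single seeded stream
(numpy `default_rng`; names → sequences → dropout → swaps → OTU draws →
gold supports → noise):

1. **Taxonomy** — `n_genera` synthetic genera with `species_per_genus`
   species each, grouped 3 genera/family, 3 families/order, 3
   orders/class under one phylum and a "Fungi" kingdom. Names are
   collision-free syllable compounds with conventional suffixes
   (-aceae/-ales/-mycetes/-mycota).
2. **Sequences** — one random root of `seq_length` nt; each genus ancestor
   diverges from it by point substitutions at `inter_genus_divergence` per
   site, each species from its genus ancestor at `intra_genus_divergence`.
   Substitutions always change the base, so two sister species differ at a
   site with probability 2r(1−r) + (2/3)r². No indels, chimeras,
   secondary-structure constraints or abundance model.
3. **Reference** — one record per species (accession REFnnnn), then two
   planted flaws: a `genus_dropout_fraction` of genera removed entirely
   (underrepresentation) and round(`mislabel_fraction`·R/2) cross-genus
   record pairs whose *labels* are exchanged (mislabels). The truth
   manifest records every drop and swap.
4. **Assignments** — each OTU is a uniformly drawn species (dropped genera
   included, which is what forces underrepresentation cases); its sequence
   is the species sequence. The gold table carries the true lineage with
   an integer bootstrap support drawn from 80–100%. Each simple-matching
   table carries the lineage of the most similar reference record (ties by
   accession); the RDP-style table is truncated at genus, matching
   fixrank's genus-level resolution; with probability `classifier_noise`
   per OTU and method, the call is truncated by one further rank.

The manifest stores, for every OTU and method, the intended assignment,
misidentification verdict and cause, computed with the same published
definitions the pipeline uses (consistency for the verdict; genus dropout
for underrepresentation; a swap-flagged record matching the assignment by
name for mislabel). With `classifier_noise = 0` the pipeline must
reproduce the manifest exactly — that end-to-end faithfulness, the exact
recovery of planted swaps by the screen, and the monotone growth of the
misidentification rate in the dropout fraction are the core acceptance
properties of the test suite.

Default conditions (`SimulationConfig()`): 30 genera × 3 species, 71
OTUs, 15% genus dropout, 4% of reference records mislabeled (≈ 2 swap
pairs), 600 nt sequences, 20%/3% inter-/intra-genus divergence, 25%
classifier noise, seed 20. These emulate a modest survey in which
misidentification rates land in the tens of percent and more than half of
the misidentifications involve underrepresentation. The test suite runs
the deeper checks at 35 genera × 3 species with 200 OTUs (faithfulness,
monotonicity) and 105 reference records (screen recovery) — sizes at
which binomial fluctuations are small relative to the planted effects
while the whole suite stays interactive.

What passing these tests does *not* show about real data: real reference
mislabels are rarely clean cross-genus swaps, real classifiers are not
nearest-neighbor machines, real sequences have indels and variable length,
and a real binning gold standard has its own error rate (assumed zero
here). The pipeline's verdicts on real tables are therefore estimates
conditioned on the gold standard being right.

## File dialects and numerical conventions

* QIIME 2 taxonomy TSV: header `Feature ID/Taxon/Confidence`
  (case-insensitive); `Unassigned` and sub-threshold rows keep their OTU
  id with a blanked lineage, preserving a common denominator across
  methods. The default applies no confidence cutoff; a threshold is used
  only when the caller sets one.
* RDP fixrank TSV: headerless; an optional orientation field after the id
  is tolerated; the lineage keeps the deepest consecutive run of ranks
  with bootstrap ≥ the threshold (truncate at first failure; default
  threshold 0, i.e. unfiltered). Species triples are dropped: fixrank
  training sets resolve to genus.
* Gold-standard TSV: header `otu_id/lineage/support`, support on the
  0–100 scale, stored internally as a fraction.
* Plain (unprefixed) lineages carry no rank labels, so ranks are assigned
  positionally: top-anchored on kingdom…species for ≤ 7 tokens,
  bottom-anchored at the species binomial when the last token has two
  words. Converting a *sparse* lineage between dialects (e.g. writing
  `d__Fungi;g__Mucor` as a plain string) is therefore lossy; within each
  dialect read→write→read is idempotent and property-tested.
* Percentages are serialized with one decimal place; raw fractions are
  kept alongside in JSON summaries so round-trips are exact. Matching
  scores are integer ratios (Σs / 5N) and are never rounded internally.
* Degenerate inputs: empty tables score 0/0 → matching score 0; an empty
  reference or an all-sequence-free reference is an error for the
  diagnosis stage; OTU-set mismatches between tables are an error listing
  the symmetric difference, never a silent intersection.

## Known limitations

* No synonym handling: a reference using an outdated generic name will be
  scored as a conflict.
* The representation check is name-based; a genus present under a
  misspelled or reclassified name counts as absent.
* The screen's flag is evidence of label/sequence disagreement within the
  supplied reference, not proof of mislabeling; flagged accessions should
  be inspected, and the package deliberately does not propose corrected
  names.
* Cause attribution inherits the screen's ambiguities (see above) and, on
  real data, can return `unexplained`.
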