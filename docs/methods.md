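# Methods

## Overview

`phytomine` re-creates, at benchmark scale, a literature-mining pipeline that
links plant-based foods to their phytochemical content and to human disease
phenotypes, and then pushes those links down to the molecular level:

1. **Entity tagging** — dictionary lookup of plant, compound and disease
   names in abstract text.
2. **Relation classification** — a Naïve Bayes classifier over
   bag-of-context-words decides, per abstract, whether a plant-compound
   co-mention asserts content ("related" vs "unrelated") and whether a
   plant-disease co-mention is preventive, promoting, or neither.
3. **Association statistics** — Fisher's exact test over the plant universe
   asks which compounds concentrate in the plants linked to each disease,
   with Benjamini-Hochberg FDR control; the same machinery measures
   overrepresentation of compounds on the plant taxonomy.
4. **Chemoinformatics** — canonical structures join mined compounds to a
   compound-protein activity table; Tanimoto similarity transfers targets to
   untested compounds; a protein-disease table validates predictions and a
   disease-pathway protein set is overlaid with per-protein counts.
5. **Reporting** — the signed food-disease network under
   support/top-k filtering, yearly positive-minus-negative trend series, and
   Cytoscape-readable exports.

Because the real inputs (tens of millions of abstracts, curated dictionaries,
licensed activity databases) cannot ship with a package, a first-class
synthetic-data module generates miniature worlds with planted ground truth
for every stage, and the test suite measures the pipeline against that truth.

## Entity tagging

Tokens are maximal runs of letters and digits with internal hyphens (so
`5-fluorouracil` is one token), lowercased, with character offsets into the
original text. Matching is case-insensitive and exact on token boundaries: at
each position the longest dictionary match wins; equal-length ties are broken
by class priority (plant > compound > disease) and then lexicographic entity
id, and matched spans are consumed so mentions never overlap. There is no
stemming, fuzzy matching or abbreviation handling — the tagging layer is
deliberately the simplest defensible scheme, and its recall on synthetic
corpora (whose surface forms are emitted verbatim) is exactly 100%.

Relation candidates are unique (plant, partner) id pairs per abstract. The
context of a candidate is the union of token positions within a window
(default 10 tokens per side, configurable) of every mention of either entity,
minus the mention tokens themselves. Whole-abstract scope with a token window
is used rather than sentence scope; the synthetic templates are single
sentences, so the distinction has no force on the fixtures.

## Relation classification

**Feature ranking.** Candidate features are ranked by tf-idf with raw term
frequency across all candidate contexts and idf = ln(N/df), N the number of
contexts and df the number containing the token. Ties are broken
lexicographically so the ranking is a deterministic function of the corpus.

**Feature selection.** Starting from the top-ranked feature, features are
added one at a time; after each addition the leave-one-out cross-validation
accuracy on the shuffled training set (shuffle seed 42 by default) is
recorded. Selection stops at the first plateau — `patience` consecutive
steps (default 5) whose improvement over the previous step is at most
`tolerance` (default 0) — and returns the feature set at the start of that
plateau. A strictly improving trace keeps the whole ranking.

**Model.** Multinomial Naïve Bayes restricted to the selected features with
pseudo-count smoothing s = 1: prior(c) = n_c/n and
cond(c, f) = (count(f, c) + s) / (tokens(c) + s·|F|). Out-of-feature tokens
are ignored at training and classification time; a context with no known
feature falls back to the priors, with lexicographic tie-break. Posteriors
are computed in log space and normalized; in the degenerate one-feature
model the conditional is identically 1 by construction and is accepted as
such. The phytochemical task is binary (related/unrelated); the disease task
has three classes (preventive/promoting/noise), and only the first two emit
edges, signed positive and negative respectively.

**Extraction granularity.** A pair co-mentioned in several abstracts is
classified independently per abstract, and edges keep abstract-level
granularity; aggregation to pair level (support counting) happens only in
the reporting stage.

## Association statistics

The plant universe for compound-disease testing is the set of plants carrying
*both* annotation types (at least one content edge and at least one signed
edge). For compound c and disease d in one direction, the 2×2 table counts
plants by containment of c and linkage to d, and the one-sided "greater"
Fisher exact test asks whether c's prevalence is higher among d-linked
plants. P-values are exact: the hypergeometric tail is summed with integer
binomial coefficients as a rational number and converted to float once, so
there is no cancellation or approximation error; the test suite checks the
implementation against a brute-force fixed-margin enumeration on every table
with N ≤ 30 and against an independent library implementation.

The positive and negative directions are corrected as **separate BH
families** (the family structure is a genuine design choice; separating the
directions keeps each family interpretable as "compounds enriched among
preventers/promoters"). Tables with zero overlap (a = 0) can never be
significant under the one-sided test and are excluded from the family, which
reduces m and is recorded in the output.

**Taxonomy overrepresentation** first projects each node's compound content
upward (every node's set becomes the union of its own and its descendants' —
an idempotent operation that preserves the root's distinct-compound count),
then tests every (compound, internal node) pair with genus-level sampling
units: the table counts genera inside vs outside the node's subtree by
whether their projected content holds the compound. BH runs across the whole
(compound, node) family. A compound confined to one genus attains a minimum
p of 1/G, G the number of genera, so localization is detectable only on
taxonomies with enough genera relative to the number of tests; the
localization analyses in the tests use a forest of 128 genera (256 species)
for that reason, while the default pipeline world uses 60 genera and
honestly reports zero enrichment — matching the qualitative observation that
only a small minority of compounds is taxonomically localized. A compound is
*conserved* between a parent and child node when it is significantly
overrepresented on both.

## Chemoinformatics

Canonicalization keeps the largest covalent fragment (salt stripping; ties by
heavy-atom count then lexicographic canonical form), erases stereo
descriptors and isotope labels, and emits the toolkit-canonical SMILES. The
canonical string is the join key against the activity table. Fingerprints
are hashed linear-path fingerprints, 2048 bits, paths up to length 7 —
configurable so circular fingerprints could be swapped in. Tanimoto
similarity is |∩|/|∪| over on-bits; two all-zero fingerprints return 0.0
with a warning rather than claiming identity. The similarity cutoff 0.85 is
**strict** (> 0.85): a pair at exactly the threshold produces no hit.

Associated compounds are tripartitioned into *tested* (own canonical key in
the activity table), *similar* (untested but above-threshold similar to a
reference), and *unexplored* (the rest); the three sets provably partition
the input on every run. Validation counts tested compounds with a
significant positive disease association whose measured targets map, through
the protein-disease table, to one of those same diseases. The pathway
overlay reports, per pathway protein, how many disease-associated compounds
have direct activity on it and how many have only similarity-inferred
activity.

## Reporting

Edge support counts distinct abstracts per (food, disease, sign); opposite
signs between the same pair coexist and are never netted out — only the
yearly trend series subtracts negative from positive publication counts.
Network filtering applies the support threshold (default ≥ 5 publications)
first and per-disease truncation to the top-k strongest edges (default 5,
ties by food id) second. Variety-to-species collapsing, when a mapping is
supplied, happens before support counting. SIF export carries topology and
sign (the format has no attribute slot); GraphML and TSV carry sign and
support and round-trip exactly.

## The synthetic world

The generator emulates exactly the statistical structure the analysis
assumes, and nothing more:

* **Dictionaries** draw names from disjoint per-class consonant alphabets
  (so no surface string is ambiguous between classes), with every third name
  two tokens long to force longest-match tagging, and configurable synonym
  counts.
* **Abstracts** are templated token sequences, not prose: one to two cue
  tokens, the first mention, the relation's canonical cue (its lexicon's
  head word — mirroring how a few high-frequency words like "compound",
  "isolated", "extract" dominate real relation contexts) plus up to two
  more cues, the second mention, and one to two trailing cues. "None"
  abstracts use a disjoint filler lexicon throughout. Noise replaces each
  cue slot independently with a filler word at the configured rate — the
  simplest knob that degrades classifier accuracy smoothly (measured mean
  LOOCV accuracy falls from 1.00 through ≈0.99 to ≈0.96-0.97 across the
  noise grid 0/0.2/0.4).
* **Taxonomy and content**: a ranked forest (class > order > family > genus
  > species) built from per-rank branching factors; a configurable fraction
  of compounds is confined to a single genus, the rest dispersed across at
  least two genera.
* **Planted associations**: for each planted (compound, disease) pair the
  compound's plant set is resampled by membership probabilities that realize
  the configured odds ratio against the disease's plant set (default 40,
  the "strong" setting; an odds ratio of 1 yields a global null). Strong
  plantings are rejected and resampled until their exact one-sided p is
  below the realizability target (1e-3 by default), so every planted truth
  is recoverable in principle.
* **Activity classes**: configured fractions of compounds are directly
  tested (aromatic/phenolic scaffolds whose canonicals enter the activity
  table), similar-to-tested (even-length alkanols whose odd-length homologue
  is the active reference; adjacent homologues are nearly identical in
  path-fingerprint space), or unexplored (amine/ether/fluoro scaffolds far
  from both pools). A fraction of raw structure strings carries salt adducts
  to exercise canonicalization.
* **Edibility, years, publication skew**: a configurable subset of plants is
  edible; abstract years are uniform on 1980-2012; the survey corpus gives a
  configurable fraction of plant-disease edges 5-9 publications so the
  support-filtered network is non-trivial.

What the generator does **not** emulate: natural-language grammar, entity
ambiguity and abbreviations, citation metadata beyond year, correlated
publication bias, dose or assay semantics in the activity table, and ontology
structure on the disease side. Tests passing on this world therefore
demonstrate the correctness of the statistical and chemoinformatic machinery
and the end-to-end wiring — not NLP robustness on real MEDLINE text.

## Problem sizes and numerical choices

The default world has 60 plant species (a 2·2·3·5·1 forest), 24 compounds, 6
diseases, 4 planted associations, and 40 abstracts per relation; the
end-to-end run (three corpora, two classifiers with LOOCV feature selection,
full association/enrichment/chemoinformatics/network stages) completes in
about one second. Power and null simulations use 100 and 200 fresh worlds;
taxonomy-localization analyses use a 128-genus forest with 20 compounds.
All randomness flows from explicit integer seeds through `random.Random`;
identical seed and configuration reproduce every output byte for byte.
Degenerate inputs are handled explicitly: empty contexts fall back to
priors, empty p-value families return empty flag lists, zero-overlap tables
are excluded from FDR families, and empty fingerprints warn and score 0.

## Known limitations

* Tagging assumes dictionary surface forms appear verbatim (up to case); no
  recovery of inflected or abbreviated mentions.
* The plateau selection rule can, in principle, stop before informative
  features whose tf-idf rank falls below a long run of unhelpful features;
  the canonical-cue structure of the fixtures keeps the informative features
  at the top, as the original incremental procedure presumes.
* Genus-level enrichment has no power on taxonomies with few genera (minimum
  attainable p is 1/G); this is a property of the test, not of the
  implementation.
* Tanimoto inheritance transfers the reference's entire target set; no
  weighting by similarity or assay confidence is attempted.
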