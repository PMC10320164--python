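# Methods

## Problem and model

Producers of bioactive secondary metabolites frequently carry a resistant
second copy of the compound's essential target, often inside the compound's
biosynthetic gene cluster (BGC). The package screens fungal genomes for this
signature with three independent criteria evaluated per essential-gene
ortholog model:

* **Duplication (D).** The query genome's copy number for a model strictly
  exceeds a threshold derived from reference genomes.
* **BGC proximity (B).** At least one hit gene for the model overlaps a BGC
  interval on the same contig.
* **Resistance model (R).** The gene matches a profile of a known resistance
  factor.

The criteria are deliberately independent flags, not a combined score: a
`D, B` pattern is the canonical self-resistance signature, `B` alone is a
weaker prioritization cue, and the user is expected to combine them with the
per-model metadata (function class, dN/dS, ubiquity).

## Reference sets

A reference set is built from (i) a collection of annotated genomes and
(ii) an ortholog table mapping group → genome → member genes. Per group:

* **Copy statistics.** Counts are taken over the *whole* roster, zeros
  included — a genome lacking the group is evidence about the group's
  breadth, not missing data. The duplication threshold is
  `median + k·σ` with the *population* standard deviation and `k = 1` by
  default. The flag uses strict `>`, so an all-single-copy family
  (threshold exactly 1.0) flags at 2 copies and never at 1. `k` is exposed
  both at build time and as a per-run override (`--duplication-k`), which
  recomputes thresholds from the stored median/σ without rebuilding.
* **Ubiquity** = fraction of reference genomes with ≥ 1 copy;
  **single-copy frequency** = fraction with exactly 1. Both are descriptive
  metadata in the output, not filters.
* **Functional class.** One-letter COG categories. Default mode removes
  models whose class intersects `{Q, K, P, U}` — secondary-metabolite
  biosynthesis/transport/catabolism, transcription/regulation, and the two
  transport-annotated categories — as these are poor resistance-target
  candidates and inflate false positives. The excluded set is configurable;
  exploration mode disables the filter entirely. Unknown class letters are
  retained with a warning rather than silently dropped.
* **dN/dS metadata.** The median ω over all unordered pairs of member coding
  sequences (see below); pairs with undefined ω are excluded, and the field
  is `NA` when no pair is defined. Low ω indicates purifying selection, as
  expected for genuine essential genes.

The bundle format is a plain directory (`models.tsv`, `hmms/<model>.hmm`,
`manifest.json` with a content hash) so reference sets are diffable and
inspectable.

## Nei–Gojobori dN/dS

Implemented from first principles because the counting details matter:

* **Sites.** For each sense codon, `s` is the sum over the three positions
  of the fraction of single-base changes that are synonymous, with changes
  to stop codons removed from the denominator; `n = 3 − s`, so each codon
  contributes exactly 3 sites and `N + S = 3 × codons` holds to 1e-9.
* **Differences.** For codon pairs differing at ≥ 2 positions, observed
  synonymous/nonsynonymous counts are averaged with equal weight over all
  shortest substitution pathways; pathways passing through a stop codon are
  excluded. If every pathway is blocked (possible only for rare sense-codon
  pairs), the codon pair is skipped with a warning rather than guessed at.
* **Correction.** Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)`, applied to both
  pN and pS. `4p/3 ≥ 1` yields status `saturated`; `dS = 0` (including the
  identical-sequence case) yields `undefined_dS_zero`. Both leave ω
  undefined (`NA`) — explicit statuses instead of sentinel numbers.
* Sequences must be codon-aligned on input; gap codons (`---`) and
  ambiguous or stop codons are skipped. A protein-guided codon aligner
  (global Needleman–Wunsch on translations, BLOSUM62, gap open 10 /
  extend 0.5) is provided as a convenience for unequal-length members; the
  alignment parameters are plumbing, not results-bearing choices.

The entire counting path is checked in the test suite against an
independent brute-force oracle (exhaustive pathway enumeration, recursive
rather than permutation-based, Biopython translation) over all 61 × 61
sense-codon pairs and over random 60-codon sequence pairs, to 1e-9.

## Profile-HMM detection

Profiles are standard HMMER3 ASCII files; the search runs through pyhmmer's
reimplementation of the HMMER3 pipeline, single-threaded for deterministic
output, behind a small engine interface whose version string is recorded in
every run manifest. Per-model bitscore cutoffs come from the profile's
trusted-cutoff line when present, otherwise a configurable floor (25 bits).
A gene counts at most once per model (best full-sequence hit), so
multi-domain repeats inside one protein cannot inflate copy numbers. Known
resistance factors and DUF (domain of unknown function) profiles are
searched the same way under independently togglable flags, and custom core
models can be appended to a reference set at run time (they screen with a
neutral threshold of 1.0, since no reference counts exist for them).

## Coordinates and formats

All internal coordinates are 0-based half-open; GenBank/EMBL 1-based
inclusive locations are converted exactly once at the parsing boundary.
Overlap is "shares ≥ 1 base": a gene ending where a BGC starts does not
overlap. Joined (multi-exon) CDS locations are flattened to their outer
envelope for proximity, while the coding sequence is spliced for dN/dS.
FASTA input requires a sidecar TSV of gene coordinates because the package
does no gene calling. BGC regions come from antiSMASH-style region GenBank
(`region` features by default; `cluster`/`protocluster` selectable) or a
5-column TSV. A "BGC-only" mode accepts a single cluster record without a
flanking genome: proximity and core tables are produced but duplication
flags are suppressed, since genome-wide copy numbers are not observable.

## Synthetic study generator

The generator (`mycomine.fixtures`) emulates the screening problem, not
fungal biology. Each of the default 10 ortholog families is a random
120-codon coding sequence; members in each of the 5 reference genomes and
in query genomes derive from the family ancestor by uniform per-codon
substitution at rate 0.05 (one random position per mutated codon,
stop-creating changes resampled), giving realistic profile-HMM score
separation between family members (hundreds of bits) and unrelated filler
genes (never near the 25-bit floor). Query genomes carry one baseline copy
per family, random filler genes outside and inside the 3 BGC regions, and
*planted events*: extra family copies inside or outside a named BGC,
optionally a resistance-family gene inside a BGC, DUF genes, or the
omission of a family from a genome (to emulate gene loss in multi-genome
aggregation). All placement is on one 120 kb contig with 60–150 bp spacers;
the generator fails before writing anything if the genes cannot fit. Same
seed → byte-identical GenBank/TSV/HMM output (profile creation timestamps
are pinned for this reason).

What the generator does **not** emulate — introns, codon bias, paralog
families with intermediate divergence, fragmented assemblies, nested or
overlapping BGCs with realistic gene density — bounds what the passing
tests show: they validate the screening arithmetic and plumbing end to end,
not detection power on real fungal genomes, where HMM cutoff behaviour and
ortholog-table quality dominate.

## Numerical and design choices

* Population (not sample) σ in thresholds, `k = 1`, strict `>`: the
  threshold rule is stated loosely in the field; these are the package's
  defaults and all three pieces are configurable.
* Models with zero hits in a genome are omitted from that genome's rows but
  still count in the denominator of multi-genome frequencies; genomes that
  fail to parse are recorded in the manifest and excluded from the
  denominator.
* Row order is canonical: (number of true flags desc, copy number desc,
  model id asc); all TSVs are byte-deterministic for identical inputs, and
  free-text fields containing tabs/newlines are sanitized to spaces.
* The per-run summary reports criteria hits both as model counts and as
  gene counts, since the two diverge when one model has several flagged
  genes.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
recovery studies use 5 reference genomes × 10 families × 3 BGCs with 1–3
planted in-BGC duplications over 20 seeds; oracle checks cover all 3 721
sense-codon pairs, 1 000 random 60-codon sequence pairs, 200 random
interval layouts, and 1 000 random count vectors. These sizes give exact
(not sampled) coverage of the codon table and stable planted-truth
statistics while keeping a full run in tens of seconds.

## Known limitations

* No BGC prediction and no gene calling: both are consumed as input.
* Single-pass HMM search with profile/floor cutoffs; no BUSCO-style rescue
  pass and no E-value recalibration.
* Nei–Gojobori with Jukes–Cantor only; no transition/transversion weighting
  and no codon-model (ML) estimates of ω.
* Duplication is copy-number counting, not phylogeny: ancient paralogs and
  assembly duplications flag identically to recent self-resistance
  duplications.
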