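# mycomine

Target-directed (self-resistance-guided) genome mining for fungi.

Fungi that produce a bioactive secondary metabolite must avoid poisoning
themselves. A common resistance mechanism is to carry a second, modified copy
of the compound's essential target protein, and that resistant copy is often
encoded inside the biosynthetic gene cluster (BGC) of the compound itself.
`mycomine` turns this observation into a screening engine: given a fungal
genome and its predicted BGCs, it finds essential (core) genes that are
**duplicated** beyond expectation (criterion **D**), core or resistance genes
that **overlap a BGC** (criterion **B**), and hits of **known resistance
models** (criterion **R**), then reports prioritized BGCs in sortable TSV
tables for one genome or across a whole panel.

## Method

* **Reference sets.** For a collection of annotated reference genomes and an
  ortholog-assignment table (BUSCO/OrthoDB-style), each essential-gene
  ortholog group becomes a `CoreGeneModel` carrying a profile HMM and
  metadata: copy-number median and population standard deviation across the
  references (absences count as 0), the duplication threshold
  `median + k·stdev` (default `k = 1`), ubiquity (fraction of reference
  genomes with ≥ 1 copy), single-copy frequency, a COG functional class, and
  the median pairwise dN/dS across reference orthologs.
* **dN/dS.** Nei–Gojobori counting: per-codon synonymous/nonsynonymous site
  counts (stop-codon targets excluded from the denominators), observed
  differences averaged over all shortest substitution pathways with stop
  pathways excluded, Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)`, and
  `ω = dN/dS`. Saturation and `dS = 0` are reported as explicit statuses.
* **Detection.** Query proteomes are scanned with the profile HMMs through
  pyhmmer (HMMER3 pipeline); one gene counts at most once per model, so copy
  numbers are gene-level. In *default* mode, models whose COG class marks
  regulatory, transport, or biosynthesis-associated functions are filtered
  out before the search; *exploration* mode searches everything.
* **Screening.** `D` is flagged when copy number strictly exceeds the model
  threshold; `B` when a hit gene's interval overlaps a BGC on the same
  contig (0-based half-open coordinates, a shared boundary is no overlap);
  `R` for known-resistance profile hits. Multi-genome runs aggregate, per
  model, the frequency of genomes with at least one hit (0.0–1.0, failed
  genomes excluded from the denominator).

BGC prediction itself (antiSMASH/fungiSMASH) and BGC family networking
(BiG-SCAPE) are out of scope: regions are consumed from antiSMASH-style
region GenBank files or a plain coordinate table, and multi-genome runs can
emit a BiG-SCAPE-ready input folder.

## Worked example

The package ships a deterministic synthetic-data generator, so the full
pipeline runs without downloads. Generate a toy study (5 reference genomes,
10 core-gene families, 3 BGCs, one family duplicated into a BGC plus a
planted resistance gene), build the reference set, and screen the query:

```bash
cat > spec.yaml <<'YAML'
seed: 11
n_ref_genomes: 5
n_models: 10
n_bgcs: 3
planted_events:
  - {model_id: og0004, genome_id: qry01, extra_copies: 1, inside_bgc: true}
plant_resistance: true
YAML

mycomine make-fixtures --spec spec.yaml --out fx
mycomine build-refset --genomes fx/refs --orthologs fx/refs/orthologs.tsv \
    --hmms fx/hmms --name toyset --out refset
mycomine run --input fx/queries/qry01.gbk --refset refset --mode default \
    --custom-res fx/hmms_resistance/resfam0001.hmm --no-duf --out out
```

which prints

```
fixtures: 5 reference genomes, 1 query genomes, 10 models -> fx
reference set 'toyset': 10 models from 5 genomes -> refset
qry01: 10 core models, 1 with criteria hits, 3 BGCs -> out
```

and `out/coregenes.tsv` begins

```
model_id    category    criteria  copy_number  duplication_threshold  duplication  proximity
og0004      core        D, B      2            1.0                    True         True
resfam0001  resistance  B, R      1            NA                     False        True
og0001      core        Core      1            1.0                    False        False
```

Reading: family `og0004` is present twice although every reference genome
carries exactly one copy (threshold 1.0), and the extra copy lies inside a
BGC — the `D, B` pattern of a putative self-resistant target. The planted
resistance model also hits inside that BGC (`B, R`). All other families are
single-copy background (`Core`). The same run directory contains
`duplications.tsv`, `proximity.tsv`, `bgc_summary.tsv`, `summary.tsv`,
a static `report.html`, and `manifest.json` with the engine version and
input hashes. Passing several `--input` files produces per-genome
subdirectories plus `multi_summary.tsv` with the cross-genome hit
frequencies.

The same workflow is available as a library; see `mycomine.fixtures`,
`mycomine.refset`, `mycomine.detect`, `mycomine.screening`, `mycomine.report`.

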