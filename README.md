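# mutscape

Off-target mutation landscape analysis for adenine-base-editor (ABE)
experiments in plants.

High-activity ABEs — Cas9 nickases fused to engineered tRNA adenosine
deaminases (TadA8e, TadA9) — convert A•T base pairs to G•C at their
guide-directed targets, but the deaminase can also act independently of
the guide, on both the genome and the transcriptome. `mutscape`
implements the complete whole-genome / whole-transcriptome analysis used
to profile these effects in a transgenic rice cohort:

* **Consensus variant filtering** — keep SNVs called by all three
  variant callers and indels called by at least two; subtract pooled
  wild-type background; flag residual shared homozygous loci with an
  exact binomial test (under independent per-allele mutation probability
  *p*, genotypes occur as *p*², 2*p*(1−*p*), (1−*p*)²) and remove
  homozygotes.
* **sgRNA-dependent site search** — scan the genome for protospacers
  within a full-spacer Hamming budget (≤ 6 mismatches) or a
  seed-constrained budget (≤ 2 mismatches in the PAM-proximal 12 nt),
  mask on-target variants, and count variants at off-target sites per
  mismatch stratum.
* **Mutation-spectrum statistics** — six strand-collapsed substitution
  classes (A>G counts pool A>G and T>C), per-plant A>G percentages,
  genomic-region enrichment ratios, chromosome distributions, and
  one-tailed Wilcoxon group comparisons with the star categories
  \*, \*\*, \*\*\* at p < 0.1, 0.01, 0.001.
* **T-DNA analyses** — per-fragment insertion integrity from coverage
  tracks, copy number as T-DNA coverage over half the genome coverage
  (T0 plants are hemizygous), and the sibling-plant partition into
  shared (pre-division, stages 1–2) and unique (post-division, stage 3)
  SNV sets.
* **RNA editing** — transcriptome-only SNVs, per-locus editing ratios
  (G/(A+G) on reference-A strands, C/(C+T) on reference-T strands,
  coverage strictly above 10), per-plant rank-sum tests against the
  Cas-only pool, editor expression in reads per million, and sequence
  logos (position frequency matrix with per-column information content)
  that expose the YAN editing context (pyrimidine at −1).
* **Clustered editing** — the flanking-window statistic (fraction of
  eligible A/T positions within ±30 bp whose editing ratio exceeds
  0.05) and single-linkage DNA cluster calls with group-1/group-2 plant
  classification.

A first-class **synthetic cohort generator** (`mutscape.simulate`)
produces a complete desk-scale study — genome, annotation, truth table,
emulated three-caller VCFs, RNA pileups, T-DNA coverage — so every stage
is testable end-to-end without any downloads.

## Worked example

```bash
mutscape simulate --seed 7 --outdir cohort/
mutscape run --indir cohort/ --outdir report/
```

The first command writes a synthetic study (genome.fa, annotation.gff3,
per-plant per-caller VCFs, RNA pileups, T-DNA tracks, design table).
The second runs every stage and prints:

```
32 tables written to report/
```

Typical headline rows from `report/` for seed 7 (your values will match
exactly — the pipeline is deterministic given the seed):

* `spectrum.tsv` — control plants sit near the uniform-spectrum
  expectation of ~16.7% A>G, while ABE plants rise to ~35–40% because
  the planted deaminase lesions are A>G-class.
* `group_comparisons.tsv` — `ABE vs C2` on `pct_ag` reaches `**`
  (p < 0.01, one-tailed Wilcoxon).
* `tdna.tsv` — every partial insertion is flagged with its missing
  fragment, and rounded copy numbers match the design.
* `rna_per_plant_test.tsv` — high-expression plants show
  −log10 p > 100 against the Cas-only pool; low-expression plants are
  indistinguishable from controls.
* `dna_clusters.tsv` — the planted multi-SNV loci reappear with their
  exact member counts.

The same machinery is available as a library:

```python
from mutscape.simulate import SimulationConfig, simulate_cohort
from mutscape.pipeline import analyze_cohort, inputs_from_cohort

cohort = simulate_cohort(SimulationConfig(rng_seed=7))
result = analyze_cohort(inputs_from_cohort(cohort))
print(result.tables["spectrum"].head())
```

## Layout

```
src/mutscape/
  core_io.py     domain types; VCF/FASTA/GFF3-GTF/TSV readers and writers
  simulate.py    synthetic cohort generator with truth table
  consensus.py   caller intersection, background subtraction, binomial test
  guides.py      protospacer search (vectorised + brute-force oracle)
  spectrum.py    six-class spectra, enrichment, Wilcoxon machinery
  tdna.py        integrity, copy number, sibling stage attribution
  rna.py         editing ratios, per-plant tests, RPM, motif matrices
  clusters.py    flanking-window statistic, DNA cluster calls
  pipeline.py    stage orchestration (in-memory and file-level)
  cli.py         `mutscape` command-line interface
```

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
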