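# Methods

This note documents the statistical models, parameter choices, and
limitations of the `mutscape` pipeline and its synthetic study
generator.

## Variant confidence model

Each plant's genome is called by three independent germline callers.
The confidence rule is set intersection on normalized variant keys: an
SNV is kept only when all three callers report it; an indel when at
least two do (the third emulated caller reports no indels, matching the
common situation where one caller is SNV-only).  Keys are normalized
before matching — shared allele suffixes/prefixes trimmed, indels
left-aligned against the reference — so caller dialect differences
cannot break the intersection.  Zygosity disagreements are resolved by
majority vote with ties going to heterozygous; this is conservative
because the later filter removes only confident homozygotes.

Background subtraction removes any key observed in the pooled consensus
calls of the wild-type background plants (union semantics, zygosity
ignored).  The pipeline then removes homozygous calls entirely: with ten
background genomes the probability that a genuine background variant
escapes the pooled subtraction is (1 − s³)¹⁰ ≈ 6×10⁻⁹ at per-caller
sensitivity s = 0.95, so homozygous survivors are overwhelmingly
residual background rather than induced lesions.

### Homozygosity binomial test

At a locus carried by n_hom + n_het of N plants, the per-allele mutation
probability is estimated as p̂ = (2·n_hom + n_het)/(2N).  Under
independent alleles the genotype probabilities are p̂², 2p̂(1−p̂) and
(1−p̂)², so conditional on being a carrier, P(hom) = p̂/(2−p̂).  The
p-value is the exact upper binomial tail P(X ≥ n_hom) with
X ~ Binomial(n_hom + n_het, p̂/(2−p̂)); loci below α (default 0.01) are
flagged as non-binomial, i.e. residual background.  The exact tail makes
the test conservative; Monte-Carlo calibration over 10,000 null loci
confirms the type-I error stays at or below the nominal level.  The
test runs per locus; a pooled variant is not offered because locus
counts in the screen are small and heterogeneous.

## Guide-dependent target search

Protospacer search uses SpCas9 geometry (20-nt spacer, 3′-adjacent PAM)
on both strands.  Full mode bounds the Hamming distance over the whole
spacer (default ≤ 6); seed mode bounds only the PAM-proximal 12 nt
(default ≤ 2 mismatches) while still reporting the full-spacer count.
The PAM is required in both modes — a seed match without a PAM has no
biological meaning for SpCas9 derivatives — and pattern matching follows
IUPAC codes with genomic N matching nothing.  The production scanner is
a vectorised sliding-window comparison; a deliberately simple
per-position scanner ships in-tree and the test suite asserts exact
equivalence of the two on random genomes across modes, PAM patterns and
budgets.  On-target masking removes variants inside the
protospacer+PAM span of 0-mismatch sites of the plant's own guides
(flank 0 by default; the masking window is configurable).

## Spectrum and group statistics

Substitutions are collapsed with their reverse complements into six
classes anchored on A or C; the "A>G count" is therefore A>G plus T>C.
Percentages are undefined (reported missing) for plants with zero SNVs
rather than forced to 0.  Region enrichment assigns every SNV to exactly
one of exonic/intronic/intergenic (genic = exonic + intronic, UTRs are
inside the gene span) and reports both the raw SNV fraction and the
length-normalised ratio snv_fraction / genome_fraction; the ratio is the
headline number.  Group comparisons use the one-tailed Wilcoxon rank-sum
test: exact null distribution when both groups have ≤ 10 observations
without ties, otherwise the normal approximation with tie-corrected
variance and continuity correction.  Significance stars follow the
convention * p < 0.1, ** p < 0.01, *** p < 0.001, with no
multiple-testing correction (matching how such screens are usually
reported).  No correction is a deliberate reporting choice, not an
oversight.

## T-DNA analyses

A feature is called missing when its mean coverage is below 10% of the
LB..RB span mean; the 0.1 threshold separates true absence from mapping
noise at 40× coverage in simulation and is exposed as a flag.  Copy
number is the T-DNA mean coverage divided by half the genome coverage
(first-generation transformants are hemizygous).  For partial
insertions the mean is taken over the features called present —
including a missing 4-kb module would bias the estimate low by
construction.  Sibling plants regenerated from one callus are
partitioned into common (intersection) and unique (differences) SNV
sets; common mutations predate the first cell division (stages 1–2 of
transformation: before/just after T-DNA integration), unique ones arise
later (stage 3), so the A>G percentage contrast between unique and
common sets measures how much editing happens after stable integration.

## RNA editing

The editing ratio at a reference-A position is G/(A+G); at a
reference-T position (edited strand is the complement) it is C/(C+T).
Cells with total read coverage ≤ 10 are missing — the coverage rule is
strict ("higher than 10") and applies to total coverage, with a flag to
switch to A+G coverage.  Each ABE plant's ratio vector over the combined
locus set is compared against the concatenated ratios of the Cas-only
plants with an unpaired one-tailed rank-sum test.  A plant "has RNA
mutations" under a compound rule: at least 5 detected RNA-only A>G SNVs
and a significant ratio test.  Editor expression is
RPM = mean(Cas reads, TadA reads) / (total reads / 10⁶).  The motif
matrix counts bases in ±3 bp windows re-oriented so the edited A is
central; information content per column is 2 − H (Shannon entropy,
log₂), with no small-sample correction.  Endogenous A-to-I editing is
assumed absent (true for rice, which lacks ADAR enzymes), so no
background deamination stage exists.

## Clustered editing

The flanking statistic aggregates, for each offset −30..+30 (excluding
0) around every focal A>G locus, the number of eligible positions
(reference A/T, coverage > 10) and the number edited (ratio > 0.05),
reported as a per-offset fraction.  A resolution caveat: the fraction's
granularity is 1/n_eligible, so distinguishing "noise" from a bound like
0.01 requires more than 100 eligible foci per offset; the default
simulated locus count (300) was chosen with this in mind, and real
combined locus sets of this size are what the statistic was designed
for.  DNA clusters are single-linkage merges of a plant's A>G SNVs
within 30 bp (the same window as the flanking statistic; the merge
distance is a flag), keeping groups of ≥ 2.  Per-plant clustering is the
default; a pooled cross-plant mode exists behind a flag.  Plants with at
least one cluster form group 1; the group-1 vs group-2 comparisons reuse
the Wilcoxon machinery.

## Synthetic study generator

The generator emulates the study design at desk scale: a 2-Mb uniform
ACGT genome over two chromosomes with ~30% gene content (exponential
intergenic gaps, 1–3 exons per gene); 10 wild-type background plants;
3 tissue-culture and 3 infection controls; 3 Cas-only plants; four
editors (two NGG-PAM, two relaxed NG-PAM) × with/without guides × 3
plants; two sibling pairs sharing a callus; four partial-T-DNA plants;
and a segregation generation with two transgene carriers and two nulls.

Planted mutations:

* shared homozygous background (300 SNVs + 100 indels, all plants);
* per-plant Poisson heterozygous tissue-culture mutations of uniform
  spectrum (mean 300 SNVs + 150 indels), matching the 200–400 SNVs seen
  in regenerated control plants;
* induced heterozygous SNVs in ABE plants (Poisson mean 300, scaled
  ×0.3 in partial-T-DNA plants), a fraction f = 0.6 of them A>G-class
  placed on A/T bases with 1.5× genic length-enrichment; sibling pairs
  share a common subset (mean 120, A>G fraction 0.4, pre-integration
  stage) and carry disjoint unique subsets (A>G fraction 0.8,
  post-integration);
* clustered runs of 2–10 A>G SNVs on nearby A/T sites within 60 bp in
  one flagged plant per arm; a ±31 bp margin is reserved around each run
  so unrelated singletons cannot blur the cluster's member count;
* guide-directed on-target A>G edits inside each guide-carrying plant's
  protospacer.

Caller emulation detects each true variant independently per caller with
sensitivity 0.95 and adds 2 false positives per Mb per caller (het,
uniform positions); allele depths are Poisson(40) coverage with binomial
allele draws (0.5 het, 0.98 hom).  The three-way SNV intersection
therefore recovers 0.95³ ≈ 85.7% of truth, and independent false
positives essentially never survive it.

RNA editing places 300 loci on exonic adenines (or thymines for
minus-strand transcripts) with a pyrimidine at −1 with probability 0.9
(the YAN context); 20% of loci carry 2–6 satellite edits within 30 bp
that share the context bias.  Each locus has a Beta-distributed base
ratio (mean 0.3, shared across plants — the source of cross-plant ratio
concordance); plants with low editor expression, Cas-only plants,
infection controls, and transgene-free segregants sit exactly at the
sequencing noise floor (symmetric base error 0.002).  Germline-like RNA
background SNVs (shared by every transcriptome, subtracted via the
infection-control pool) are kept > 35 bp from edit loci so control
flanking profiles measure noise only.  Editor read counts are scaled so
the recomputed RPM equals the design value exactly.  T-DNA tracks are
Poisson with rate copies × coverage/2, with the missing fragment of
partial plants at near-zero rate.

All randomness flows through per-entity RNG streams derived from
(seed, entity label), so outputs are byte-identical across runs and
adding a plant never perturbs another plant's data.

### What the generator does not model

Read-level artifacts (mapping bias, strand bias, duplicates), indel
calling errors beyond presence/absence, linkage between mutations,
genome repeat structure (the uniform genome makes guide off-target
counts lower than a real genome's), transcript abundance variation
across loci, and partial-activity intermediate expression tiers.
Passing tests therefore demonstrate the correctness of the statistical
machinery under the stated generative model, not robustness to real
sequencing artifacts.

## Problem sizes and runtime choices

The default cohort (2-Mb genome, 43 sequenced genomes, 22 transcriptomes)
analyses in ~15 s.  Monte-Carlo checks use 20 DNA replicates and 10 RNA
replicates; the guide-search oracle comparison uses 50-kb genomes.  These
sizes give binomial standard errors comfortably inside every asserted
tolerance while keeping the full test suite under five minutes.

## Design notes

* Stage caching was considered and rejected: every stage re-runs in
  seconds at desk scale, and a cache would complicate the byte-identical
  rerun guarantee.
* The file-level pipeline (`run_all`) and the in-memory path
  (`analyze_cohort`) share all stage code; tests assert they agree.
* `pct` columns for empty variant sets are NaN in TSVs, never 0, so
  downstream means are not dragged toward zero.
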