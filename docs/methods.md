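# Methods

This note documents the models, conventions and design choices behind
`snp2mab`, in the order the pipeline runs.

## Data model and conventions

All genomic coordinates are 1-based inclusive; the only 0-based half-open
surface is BED export.  A genotype call is an unordered allele pair (phase is
never used) or missing; missing calls are excluded from every denominator
unless a function states otherwise.  Multiallelic SNVs are kept on ingest and
fall out of the cascade at the diallelic stage, so the stage accounting sees
them.  Percentages in reports round half-away-from-zero (0.05 % → 0.1 %, not
banker's rounding) — this is the convention that makes the published-style
accounting tables self-consistent at one decimal.

## Filter cascade

Stage order is fixed: homozygous/diallelic → distinguishability →
segregation ratio → flank pruning → MAB selection.  Each stage reports
(input, retained, removed, % removed) and the chain invariant —
stage i+1's input equals stage i's retained — is enforced structurally.

* **Homozygous & diallelic.** A marker for inbred-line genotyping must be
  fixed within lines: any heterozygous call disqualifies the site, exactly
  two alleles must be observed across the panel, and each allele must be
  carried by at least one accession.
* **Distinguishability.** "Able to distinguish at least k accessions"
  (default k = 15) admits two readings, and the package ships both as an
  explicit parameter rather than choosing silently: `callable` (default)
  requires at least k non-missing calls; `minor_class` requires the smaller
  genotype class itself to contain at least k accessions.  The default was
  chosen because a site that cannot be called in k lines cannot classify
  them, whichever way the phrase is read.
* **Segregation ratio.** Implemented as an inclusive window on the
  minor-genotype frequency among non-missing calls, default [0.3, 0.7].
  The window is configurable, and a chi-square-against-1:1 alternative
  (`seg_ratio_mode="chi2"`) is available for users who prefer a test to a
  window.  Sites with no calls are removed (logged), not an error.
* **Flank pruning.** A SNP is removed iff another surviving candidate on the
  same chromosome lies within the flank window (default 60 bp, boundary
  inclusive: 60 bp apart is a conflict, 61 bp is not).  Removal is symmetric
  — both members of a close pair go — because neither member has a clean
  probe flank; a greedy `keep_first` mode is available.  After every run the
  output is re-checked post hoc: minimum same-chromosome spacing must exceed
  the window.  Symmetric removal is stable (re-running changes nothing), the
  other three stages are idempotent by construction.
* **MAB selection.** See below.

## Even-spacing panel selection

"Evenly distributed across the chromosome" is made precise as a transportation
problem: chromosome of length L with quota q is split into q equal bins with
midpoints (i + ½)·L/q; each bin receives exactly one marker and the
assignment of candidates to bins minimises the total |pos − midpoint|.  This
subsumes the intuitive per-bin-nearest rule and settles its edge cases: a bin
without a local candidate is served by the nearest unused candidate, and two
bins never claim the same SNP.  Costs are held in exact integers (scaled by
2q) with a lexicographic low-coordinate tie-break term, so selection is fully
deterministic; the solver is the Hungarian method (`scipy`
`linear_sum_assignment`).  An exhaustive-assignment oracle verifies
optimality on small instances in the test suite.

Quotas are user inputs (how many markers each chromosome deserves is a
breeding-programme decision, not a statistical one); when omitted they
default to proportionality with per-chromosome candidate counts by largest
remainder, capped by availability, totalling `panel_total` (default 298).

Marker density is reported per chromosome as markers/Mb rounded to 2 dp,
plus a Total row whose density is computed from the summed counts and sizes
(not the mean of densities).

## KASP flanks and validation subset

Flank extraction takes 60 bp either side of the variant and renders the
centre as `[REF/ALT]`, giving a 125-character assay string with the bracket
at index 60; extraction fails loudly when the SNP sits within 60 bp of a
chromosome end or when the genome base disagrees with the declared reference
allele.  The validation subset is a seeded random draw constrained to
per-chromosome counts within a range (default 4–7) summing to a total
(default 50); infeasible constraint combinations are an error, not a silent
adjustment.

## Consequence classification

The classifier is deliberately coarse — region rules plus single-codon
translation — not a SnpEff re-implementation (no canonical-transcript
machinery, no regulatory features).  Rules: genes are considered within a
5 kb up/downstream window (configurable), otherwise the variant is
intergenic.  Intronic positions 1–2 bases from the exon boundary are splice
donor (5' side of the intron in transcription direction) or acceptor
(3' side); intronic bases 3–8 and the last 3 exonic bases at an internal
junction are splice region.  CDS variants are classified by translating the
affected codon on the coding strand under the standard code: start lost
(first codon ATG destroyed), stop gained/lost, synonymous, missense.
A substitution creating a new ATG in the 5' UTR is the premature-start-gain
case.  Per (variant, gene) pair exactly one consequence is kept — the most
severe by a fixed ordering — and multiallelic variants are classified per
alt with the most severe retained.  CDS whose length is not a multiple of
three are warned about and skipped for coding calls.

Impact is a total, fixed function of consequence following the conventional
SnpEff assignment (synonymous → LOW, missense → MODERATE, stop/start/splice
site → HIGH, UTR/intron/up/downstream/intergenic → MODIFIER).  Published
category-percentage figures derived from other schemes are intentionally not
reproduced; the mapping here is the standard one.

Gene-category tables (flowering-pathway membership, TF families) are driven
entirely by a GFF attribute tag (default key `note`), never by hard-coded
gene symbols; an accession is counted at a SNP when it carries the
non-reference allele (`carrier` mode) or merely when it is called
(`callable` mode).

## KASP genotype analysis

Homozygosity is 100 · homozygous / non-missing per line at 1 dp — the seed
purity statistic.  Dissimilarity defaults to simple mismatch (fraction of
both-called markers whose call states differ); an allele-sharing variant
(1 − shared/2 per marker: AA vs AB = 0.5, AA vs BB = 1) is provided because
the exact formula behind legacy "per-cent dissimilarity" matrices differs
between programs.  Missing calls are pairwise-deleted rather than imputed;
a pair of lines with zero shared markers is an error naming the pair.

UPGMA is implemented directly: merge the closest pair at height d/2, update
distances by the size-weighted mean, break distance ties toward the
lexicographically smallest min-leaf-label pair.  The deterministic tie rule
is the reason for not delegating to a generic linkage routine (whose tie
behaviour is platform/ordering dependent); generic average linkage is used
in the tests as an independent cross-check of the heights, and a naive
textbook implementation as a full merge-order oracle.  Newick branch lengths
are parent height minus child height at 6 dp.  Tree cuts at k clusters sit
between the (n−k)th and (n−k+1)th merge heights; tied heights straddling the
cut raise rather than guess.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes: nine
chromosomes with the radish assembly's per-chromosome sizes (25.86–53.29 Mb,
334.46 Mb in total), 33 accessions, residual per-line heterozygosity drawn
uniformly from 4–44 % (so that expected line homozygosity spans 56–96 %),
biallelic SNPs with allele splits drawn from a U-shaped Beta(0.5, 0.5)
(so a realistic majority of sites fail the segregation window), per-call
missingness of 10 % with an 8 % subpopulation of high-missingness sites
(70 %, so the distinguishability stage has work to do), and a configurable
fraction of SNPs deliberately placed within 60 bp of another to stress the
pruning stage.  A fraction of sites is made heterozygous-bearing,
multiallelic or monomorphic so every cascade stage removes a non-trivial
share.  Anchor SNPs are placed with guaranteed >120 bp spacing and clustered
SNPs at ±1–60 bp of a random anchor, which makes the intended prune outcome
derivable.  The truth table records each SNP's pass/fail per stage criterion,
evaluated directly on the generated calls (flank-pruning truth on the
survivor set), so cascade outputs can be compared to ground truth exactly.

KASP matrices are generated from per-cluster AA/BB prototypes with a 2 %
flip rate, per-line heterozygous-call rates from the same 4–44 % range and
2 % missingness.

What the generator does **not** emulate: linkage disequilibrium, coalescent
ancestry, expression-coverage-driven callability, realistic codon/GC content
(reference bases are i.i.d. uniform; only start/stop codons are imposed on
simulated CDS).  Tests passing on this generator therefore establish
algorithmic correctness — predicate semantics, accounting arithmetic,
spacing guarantees, recovery of planted structure — not calibration against
real transcriptome data.

### Problem sizes

Defaults are full-size chromosomes; the demo, CLI examples and the
acceptance script run at 1/100-scale chromosome sizes with 4,000 SNPs and
150 genes — ample to exercise every stage (hundreds of SNPs per stage
transition) while keeping a full run in seconds.  Oracle-equivalence tests
run up to 2,000 SNPs across 20 seeds; UPGMA oracles up to 12 lines across
100 seeds; cluster recovery uses 22-line, 50-marker, 3-cluster replicates
(the size of a typical validation dendrogram experiment).

## Numerical choices and degenerate inputs

* Half-away-from-zero rounding everywhere a report prints a percentage.
* Panel-selection costs are exact integers; no floating-point ties.
* Empty matrices flow through the cascade as all-zero accounting rows
  (0/0/0, 0.0 %) rather than erroring.
* All randomness derives from a single `numpy` `default_rng(seed)` per
  entry point; identical seeds give byte-identical artifacts, which the
  determinism tests assert on file digests.

## Known limitations

* The distinguishability criterion's intended reading is genuinely
  ambiguous; both implemented modes are defensible and give different
  retention counts.
* The consequence classifier evaluates genes independently; a variant in
  two overlapping genes yields two calls (by design), and no
  transcript-isoform logic exists.
* Cluster composition of real validation panels (which lines fall in which
  subgroup) depends on the actual germplasm and is out of scope; only
  recovery of planted structure is claimed.
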