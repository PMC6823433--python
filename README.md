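# snp2mab

Tools for turning transcriptome-derived SNP calls from a panel of inbred
lines into a genotyping-ready marker set for marker-assisted backcross (MAB)
breeding, and for analysing the KASP allele calls that come back from the
bench.  The package grew out of the radish (*Raphanus sativus*, 2n = 18)
setting — a few dozen highly homozygous accessions, nine chromosomes, a
~334 Mb genome — but nothing in it is crop-specific.

## What it does

Given a multi-sample VCF of SNP calls for N inbred accessions, a reference
FASTA and gene models in GFF3:

1. **Filter cascade** — five stages, each with retained/removed/% accounting:
   * *homozygous & diallelic*: every non-missing call homozygous, exactly two
     alleles observed, each carried by at least one accession (inbred lines
     should be fixed at a useful marker locus);
   * *distinguishability*: the SNP must be informative for at least k
     accessions (default k = 15; either "k callable" or "minor class ≥ k",
     both shipped);
   * *segregation ratio*: minor-genotype frequency within an inclusive
     window, default 0.3–0.7 (markers split ~1:1 are most informative);
   * *flank pruning*: any SNP with a neighbour within 60 bp is dropped
     (a second polymorphism under a KASP probe corrupts allele-specific
     hybridisation); removal is symmetric — both members of a close pair go;
   * *MAB selection*: per-chromosome quotas filled by an even-spacing
     criterion (equal bins, one marker per bin, total distance to bin
     midpoints minimised; deterministic tie-breaks).
2. **Marker panel** — per-chromosome counts and densities (markers/Mb, 2 dp),
   KASP flanks (60 bp either side, centre rendered `[REF/ALT]`), physical-map
   export as BED plus a MapChart-style table, and a seeded draw of a KASP
   validation subset (e.g. 50 markers, 4–7 per chromosome).
3. **Effect annotation** — a coarse SnpEff-style classifier: positional
   consequences (upstream/downstream, intergenic, intron, UTR, splice
   donor/acceptor/region) and codon-level consequences (synonymous, missense,
   stop gained/lost, start lost, premature start gain in the 5' UTR), each
   mapped to a HIGH/MODERATE/LOW/MODIFIER impact class; plus per-accession
   tables of SNPs in category-tagged genes (flowering-pathway and TF-family
   tags ride along in a GFF attribute).
4. **KASP genotype analysis** — per-line homozygosity
   (100·homozygous/called, the standard seed-purity statistic), pairwise
   per-cent dissimilarity with pairwise deletion of missing calls, UPGMA
   clustering (size-weighted average linkage, merge height d/2), Newick
   export and k-group tree cuts.
5. **Synthetic data** — a seeded generator for all of the above: reference,
   tagged gene models, a multi-accession VCF with controlled residual
   heterozygosity, allele-split distribution, missingness and 60 bp position
   clustering, plus a per-SNP truth table for every filter stage; and
   clustered KASP call matrices with known group labels and het rates.

## Worked example

```bash
snp2mab demo --seed 7 --outdir demo_out
```

simulates a 1/100-scale nine-chromosome panel (4,000 SNPs, 33 accessions),
runs the full pipeline and writes every artifact.  `demo_out/report.json`
shows the cascade accounting:

| stage                | retained | removed | % removed |
|----------------------|---------:|--------:|----------:|
| homozygous_diallelic |     2458 |    1542 |      38.6 |
| distinguishability   |     2297 |     161 |       6.6 |
| segregation_ratio    |      768 |    1529 |      66.6 |
| flanking_prune       |      748 |      20 |       2.6 |
| mab_select           |      298 |     450 |      60.2 |

Each row's retained+removed equals the previous row's retained (the
chaining invariant); the heavy segregation-ratio attrition is by
construction — allele splits are drawn from a U-shaped Beta, so most SNPs
are too skewed to be informative.  `demo_out/density.tsv` ends with

```
Total	298	3.3445	89.1	50
```

298 selected markers over 3.34 Mb of scaled genome (89.1 markers/Mb; on
the full-size genome the same panel is 0.89/Mb), 50 of them flagged for
KASP validation.  `demo_out/panel.tsv` carries the assay-ready flanks, e.g.

```
Chr1_3997  Chr1  3997  C  T  GGTACC...CTTAT[C/T]CCTAG...
```

and `demo_out/homozygosity.tsv` plus `demo_out/tree.nwk` hold the per-line
homozygosity (e.g. `L001 92.0`, `L002 65.3`) and the UPGMA dendrogram of a
simulated 22-line KASP experiment.

The same steps are available as library calls
(`snp2mab.run_cascade`, `select_mab_panel`, `classify_matrix`,
`homozygosity`, `upgma`, …) and as the `simulate`, `filter`, `panel`,
`annotate` and `kasp` subcommands for file-based use.

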