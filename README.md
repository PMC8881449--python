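# equimeta

A desk-scale re-implementation of a shotgun-metagenomics analysis pipeline of
the kind used in comparative gut-microbiome studies (e.g. domestic vs
free-ranging horse cohorts). The pipeline covers paired-end read quality
control, reference-genome curation, subsample-and-average taxonomic profiling,
carbohydrate-active enzyme (CAZy) and antimicrobial-resistance (ARG)
functional profiling, a resistance-phenotype × genome co-assignment network,
and diversity / ordination / association statistics — all exercised on
synthetic, ground-truthed communities so every stage can be validated against
a known answer without touching external databases or sequencing data.

## Scientific problem and model

Given paired-end shotgun reads from several fecal samples grouped into
cohorts, the pipeline answers: *which species are present and at what relative
abundance, which functional gene families do they carry, which genomes carry
which resistance phenotypes, and which species differ between cohorts?*

The computational model, stage by stage:

1. **Read QC** (`equimeta.qc`) — five rules per read: trim up to 29
   low-quality (Q<20) bases from the 3' end, then discard reads with ≥2
   ambiguous bases, ≥30 low-quality bases, adapter contamination (detected by
   sliding overlap after clipping the first 6 adapter bases, ≤10% mismatches,
   minimum overlap 16), or host-genome alignment (≥90% identity, E<1e-5).
   Adapter/host failures discard the whole pair; the other rules orphan the
   mate into a singleton stream.
2. **Reference curation** (`equimeta.refdb`) — per species, drop genomes
   whose length or GC content falls outside Tukey's fences (k=2, quartiles by
   linear interpolation), keep the 3 longest per completeness class, and
   collapse unnamed ("Genus sp.") genomes within a genus by complete-linkage
   clustering of canonical 12-mer Jaccard distances at threshold 0.9.
   Plasmid records ride along with their parent chromosome.
3. **Taxonomic profiling** (`equimeta.taxprofile`) — subsample a fixed number
   of pairs, align both mates against the curated genomes with the built-in
   exact-k-mer-seeded ungapped aligner (+1/−2 scoring, Karlin–Altschul
   E-values, both strands), fractionally assign multi-species pairs by
   unique-hit proportions, normalize by mean genome length, repeat, and
   average the candidate profiles. Species seen in ≤2 samples are dropped.
   Study scale is 15 million pairs × 100 repeats; desk scale defaults to
   50,000 × 10.
4. **Functional profiling** (`equimeta.cazy`, `equimeta.resistome`) — merge
   mate hits against protein (six-frame, CAZy) or DNA (ARG) catalogs with
   score > 60 and E < 1e-5, split each pair's unit weight across its mapped
   genes, and divide by gene length; ARG weights roll up to resistance
   phenotypes.
5. **Co-assignment network** (`equimeta.resistome`) — a pair assigned to both
   a phenotype and a genome links them; per-sample frequencies (genome share
   split across ties) are averaged over each cohort, zeros included, and
   emitted as GraphML.
6. **Statistics** (`equimeta.stats`) — Shannon/Simpson/Gini, Chao1 and ICE
   richness, Faith's phylogenetic diversity; classical PCoA on 1 − Spearman
   distances; exact one-sided Wilcoxon rank-sum for small groups; and a
   covariate-adjusted log-linear association model with Benjamini–Hochberg
   correction.

A synthetic-community generator (`equimeta.synthetic`) produces genomes,
spiked ARG/CAZy genes, designed cohort effects, and reads whose per-read
defect labels and species of origin form the ground truth the tests check
against.

## Worked example

Run the full default pipeline (5 species, 3+3 samples, 3,000 pairs each,
2% of reads carrying each QC defect) into a run directory:

```bash
equimeta run --out runs/demo --seed 0
```

Each stage writes into `runs/demo/<stage>/` with a manifest; re-running skips
verified stages, so deleting one stage's directory re-executes only that
stage. Selected actual outputs from the command above:

`profile/species.tsv` (rows sum to 1; host/defect reads were removed by QC,
so nothing is left unassigned here):

```
sample_id  Bacteroides equinus0  Clostridium equinus2  Fibrobacter equinus3  Prevotella equinus1  Streptococcus sp. 4  unassigned
S001       0.45292               0.01947               0.06185               0.00339              0.46237              0.0
S002       0.23538               0.01001               0.01152               0.0                  0.74310              0.0
```

`diversity/diversity.tsv`:

```
sample_id  observed_species  shannon  simpson  gini     chao1  ice  faith_pd
S001       5.0               0.98352  0.57686  0.54056  5.0    5.0  11.0
S002       4.0               0.65862  0.39217  0.60579  4.0    4.0  9.0
```

`resistome/edges.tsv` (cohort-mean co-assignment frequencies):

```
phenotype                  genome   replicon    cohort    weight
aminoglycoside resistance  EQM0001  chromosome  domestic  0.00653
aminoglycoside resistance  EQM0001  chromosome  feral     0.01069
beta-lactam resistance     EQM0002  plasmid     domestic  0.00786
```

`associate/association.tsv` (no effect was planted in this demo, so no
feature reaches significance):

```
feature               coefficient  p_value  q_value  trans_co  significance
Bacteroides equinus0  0.18809      0.60671  0.89237  0.18809
Clostridium equinus2  0.89604      0.41413  0.89237  0.89604
```

Individual stages are also exposed (`equimeta simulate|qc|build-db|profile|
cazy|resistome|diversity|associate --out RUN_DIR [--config cfg.yaml]
[--seed N] [--force]`); a YAML config overrides any default one level deep.
Exit codes: 0 success, 1 user error, 2 internal error.

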