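# psychromark

Comparative-genomic and metagenomic analysis of cold-adapted bacterial
clades: clade diagnosis, group-specific marker-gene discovery, and
over-representation screening across environmental metagenomes.

Cold-adapted (psychrophilic) lineages inside a large bacterial genus —
here modeled on polar/alpine members of an *Arthrobacter*-like soil genus
— leave correlated signatures across scales: a monophyletic clade on the
phylogenomic tree, lower genomic G+C, shifted amino-acid usage,
destabilized proteins at sub-zero temperatures, a private complement of
gene families, and over-representation of those families in cold-soil
metagenomes. `psychromark` implements the full inference chain that links
these observations, together with a synthetic-data generator that plants
every effect with known ground truth, so each stage — and the chain
end-to-end — is testable without any downloads. It is aimed at
microbial comparative genomicists and metagenome ecologists who want the
analysis as a reusable, tested library rather than a pile of one-off
scripts.

## What it computes

- **Operational monophyly** (`monophyly`): for a labeled group on a tree,
  scan both sides of every bipartition and report the node maximizing
  `F = 2PR/(P + R)`, with precision `P` = labeled tips under the node /
  tips under the node and recall `R` = labeled tips captured / all
  labeled tips. The group is operationally monophyletic when `F ≥ 0.95`.
- **Genome preparation** (`genome_prep`): QC filtering (remove genomes
  with > 300 contigs, N50 < 20 kb, completeness < 95 %, contamination
  > 5 %), average amino-acid identity (AAI) from reciprocal-best-hit
  protein pairs, single-linkage dereplication at AAI ≥ 99.5 %, and
  gene-family clustering at e ≤ 1e-5, identity ≥ 70 %, bidirectional
  coverage ≥ 70 %.
- **Marker discovery** (`markers`): group-specific families under the
  95/95 rule (present in ≥ 95 % of the target group's genomes, present in
  ≤ 5 % of each other group's), the pan genome, per-group normalized
  marker counts, and per-family copy-number ANOVA.
- **Composition** (`composition`): G+C content, amino-acid usage,
  per-residue group ANOVA and usage-vs-G+C regressions, Bray-Curtis
  amino-acid bias per functional category, and Kruskal-Wallis enrichment
  of functional-category content.
- **Protein stability** (`stability`): two-state Gibbs-Helmholtz folding
  free energy `ΔG(T) = −ΔHm(1 − T/Tm) + ΔCp(Tm − T + T ln(T/Tm))`
  evaluated at −1 °C (272.15 K) and compared between groups.
- **Metagenome screen** (`metascreen`): Smith-Waterman search (BLOSUM62,
  gap open 11 / extend 1) of marker and pan-genome proteins against gene
  catalogs, accepting hits at identity ≥ 70 %, query coverage ≥ 70 %,
  E ≤ 1e-5; counts are catalog genes hit per query set.
- **Abundance statistics** (`abundance`): per-sample regression of
  group-specific hits on pan-genome hits, MAT-based climate binning, and
  one-way ANCOVA (k = 2) with a slope-homogeneity gate before the
  intercept (adjusted-means) comparison.
- **Co-occurrence** (`cooccurrence`): SparCC-style basis correlations for
  compositional OTU counts (abundance/prevalence filter: mean ≥ 2,
  detection in ≥ 56/76 samples), 100 shuffle-null datasets for add-one
  pseudo p-values (minimum 1/101), and strong-edge extraction at
  |ρ| > 0.5.
- **Synthetic data** (`simulate`): generates genome collections,
  metagenome catalogs, stability parameters and OTU counts with planted,
  recoverable effects; `io` reads and writes the FASTA/newick/TSV formats
  everything else consumes.

## Worked example

```python
import pandas as pd
from psychromark import simulate, monophyly, markers, abundance

cfg = simulate.SimConfig(seed=1)   # 74 + 22 + 10 genomes, 30 markers/group
records, matrix, tree, truth = simulate.simulate_genome_collection(cfg)

res = monophyly.max_f_measure(tree, "C")
# F(C) = 1.000  precision = 1.000  recall = 1.000  monophyletic = True

sets = markers.group_specific_genes(matrix, truth.genome_groups)
print(markers.normalize_marker_counts(sets))
#        n_families  n_genomes  families_per_genome
# group
# A              30         74             0.405405
# B              30         22             1.363636
# C              30         10             3.000000

ht, meta, _ = simulate.simulate_hit_counts(
    simulate.SimConfig(seed=1, n_metagenomes=60, enriched_sample_count=5),
    matrix, sets)
cohorts = pd.Series(
    ["enriched" if m.cohort == cfg.enriched_cohort else "background" for m in meta],
    index=[m.sample_id for m in meta])
fit = abundance.fit_group_regression(ht.loc[cohorts == "background"], "C")
# background fit: y = 0.0394x + -1.3722, R^2 = 0.8857 (n=55)
r = abundance.ancova_two_cohorts(ht, cohorts)
# slope homogeneity p = 0.251 -> lines parallel, comparison valid
# intercept difference p = 1.71e-25
# adjusted means: {'background': 10.73, 'enriched': 36.38}
```

Reading the output: the ten cold-adapted genomes form an exclusive clade
(`F = 1`), every planted marker family is recovered and normalizes to 3.0
families per genome for the 10-genome group, group-specific hit counts
across 60 simulated metagenomes track pan-genome hit counts (`R² ≈ 0.89`,
the shared sequencing-depth signal), and after removing that covariance
the five enriched cold-soil samples sit on a parallel line ~26 hits
higher — the ANCOVA calls the over-representation at `p ≈ 1e-25`.

A thin CLI mirrors the library (`psychromark simulate`, `validate`,
`monophyly`, `markers`, `stability`, `abundance`, `cooccur`).

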