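# Methods

This note documents the models, statistical procedures, numerical
choices and known limitations behind `psychromark`, in the order the
pipeline runs them.

## Operational monophyly by maximum F measure

A group label on a tree is summarized by the best-matching node:
precision is the fraction of tips under the node carrying the label,
recall the fraction of all labeled tips captured, and
`F = 2PR/(P + R)`. Both tip sets of every bipartition are scanned, so
the result is invariant to where the input tree happens to be rooted;
trees are accepted rooted or unrooted. Ties are broken toward the node
with fewer tips (the most specific clade claim), then toward the earlier
pre-order position. The group is called operationally monophyletic when
`F ≥ 0.95`, boundary inclusive. `F` is defined as 0 whenever
`P·R = 0`.

## Genome preparation

**QC filter.** A genome is removed iff contigs > 300, N50 < 20 000 bp,
completeness < 95 % or contamination > 5 %. The inequalities are strict,
so a genome sitting exactly on every boundary passes. Assembly metrics
are inputs; the package does not recompute them.

**AAI.** All-vs-all local alignments between two proteomes are screened
at e ≤ 1e-5, identity ≥ 30 % and coverage ≥ 70 % of the shorter protein;
AAI is the mean percent identity over reciprocal-best-hit pairs (each
pair's two directional identities averaged, making the statistic
symmetric by construction). A pair of proteomes with no accepted RBH
pair yields NaN and a log message rather than a fabricated value.

**Dereplication** is single-linkage clustering at AAI ≥ 99.5 %; the
cluster representative is the genome with the highest completeness,
ties broken by lowest contamination, then lexicographic id. Genomes are
sorted by id before clustering so the result is independent of input
order. Greedy representative picking would give the same answer on
well-separated clusters; single linkage was chosen because it is
deterministic and order-free.

**Gene families** are connected components of the protein alignment
graph with edges at e ≤ 1e-5, identity ≥ 70 % and coverage ≥ 70 % on
*both* query and subject. Connected components replace Markov
clustering: on families that are well separated at a 70 % identity
cutoff the two agree, and components are deterministic and fast at desk
scale. Each family is represented by its longest member sequence.

## Marker discovery (95/95 rule)

A family is specific to group G when the fraction of G's genomes with
copy count ≥ 1 is ≥ 0.95 and, for every other group evaluated
separately (not pooled), the fraction of carriers is ≤ 0.05. Fractions
are compared exactly, without rounding. Copy number plays no role in
specificity; it is analyzed separately by per-family one-way ANOVA on
per-genome counts, with a family called `absent_in_C` when it never
occurs in group C but does in group A. Marker-set sizes are reported
both raw and as families per genome, since groups of unequal size are
compared.

## Compositional statistics

Amino-acid usage is the residue frequency vector over a genome's entire
proteome (X ignored). Group effects are tested per residue by one-way
ANOVA with significance at raw p < 0.05; "non-parametric one-way ANOVA"
of functional-category content is implemented as Kruskal-Wallis. No
multiple-testing correction is applied by default because the
significance convention of the analysis this mirrors uses raw p-values;
a Benjamini-Hochberg flag exists for users who prefer FDR control.
Category-level amino-acid bias concatenates all proteins of a category
across a group's genomes before computing frequencies, then takes the
Bray-Curtis distance `BC = Σ|x_i − y_i| / Σ(x_i + y_i)` between the two
group vectors; larger BC = stronger bias. G+C content excludes N from
the denominator and returns NaN for empty/all-N input.

## Protein stability

Stability curves are two-state Gibbs-Helmholtz models parametrized by
melting temperature `Tm` (K), unfolding enthalpy `ΔHm` (kcal/mol, > 0)
and heat-capacity change `ΔCp` (kcal/mol/K, > 0). The folding free
energy is

    ΔG(T) = −ΔHm (1 − T/Tm) + ΔCp (Tm − T + T ln(T/Tm)),

which satisfies ΔG(Tm) = 0 identically, is negative between cold and
heat denaturation, and has a single interior stability maximum. The
folding sign convention (negative = stable) was chosen so that a
cold-adapted group with destabilized proteins shows *higher* ΔG at the
evaluation temperature, the direction the group contrast takes.
Temperatures are kelvin internally; the CLI accepts °C. Groups are
compared at −1 °C (272.15 K) by one-way ANOVA on per-curve ΔG.

"Robust" curves are operationalized by a parameter-sanity filter —
`Tm ∈ [273.15, 400] K`, `ΔHm > 0`, `ΔCp > 0`, `|ΔG(298.15 K)| ≤ 50`
kcal/mol — because no formal criterion is available; the thresholds are
configuration, exposed to the caller.

## Metagenome screen

Queries (marker and pan-genome representatives) are aligned to every
catalog gene by Smith-Waterman with BLOSUM62 and BLAST-convention
affine gaps (a gap of length L costs 11 + L). Hits are accepted at
identity ≥ 70 % (matches over all alignment columns, gaps included),
query coverage ≥ 70 % and E ≤ 1e-5, with the simplified E-value model
`E = m·n·2^(−bits)` (bits from the standard gapped BLOSUM62
Karlin-Altschul constants λ = 0.267, K = 0.041). At the 70/70 operating
point the decisions are insensitive to the E-value refinements this
model omits (edge corrections, length adjustment). The counting unit is
catalog genes (subjects): a gene counts once per query set no matter how
many queries hit it, making counts a proxy for gene abundance.

A shared-5-mer prefilter skips hopeless pairs. For random substitution
patterns at ≥ 70 % identity over ≥ 50 aligned residues the probability
of no shared 5-mer is negligible, but the guarantee is probabilistic,
not adversarial (a pathological mismatch-every-third-residue pattern at
exactly 70 % identity has no 5-run of matches); `prefilter=False` gives
the exhaustive search.

## Abundance regression and ANCOVA

Group-specific hits `y` are regressed on pan-genome hits `x` across
samples by OLS; `x` absorbs the shared sampling-depth signal, so cohort
effects appear as vertical offsets. The one-way ANCOVA (k = 2) first
tests slope homogeneity via the cohort × covariate interaction
(F-test); only when slopes are parallel (p ≥ 0.05) are adjusted means
(equivalently y-intercepts) compared in the common-slope model, per the
principle that intercepts of non-parallel lines are not comparable.
Counts are analyzed untransformed by default (a log option exists).
Climate classes come from an explicit tag when present, else from mean
annual temperature with cutpoints MAT < 0 °C → polar/alpine,
0–18 °C → temperate, ≥ 18 °C → tropical — a stand-in for a full
Köppen-Geiger classification, exposed as configuration.

## Co-occurrence (SparCC)

OTU counts are compositional, so correlations are inferred on the
log-ratio scale: fractions are estimated by Dirichlet resampling of
each sample (counts + 1), the variation matrix
`T_ij = var(log(x_i/x_j))` is formed, basis variances solve the linear
system `[(D−1) diag + 1] w = rowsums(T)` under a sparsity assumption,
and `ρ_ij = (w_i + w_j − T_ij) / (2√(w_i w_j))`, clipped to [−1, 1].
The most correlated pair above |ρ| = 0.1 is iteratively excluded from
the system and it is re-solved, up to `iterations` rounds; estimates
are averaged over `iterations = 20` Dirichlet resamples. Input OTUs
are pre-filtered to mean count ≥ 2 and detection in at least
⌈(56/76)·n⌉ samples.

Significance uses 100 shuffle-null datasets: each OTU's counts are
bootstrap-resampled across samples independently (destroying inter-OTU
association, preserving marginals — the per-OTU reading of "shuffling
with replacement"), the full estimator is re-run, and add-one pseudo
p-values are computed, so the smallest attainable p is 1/101. Strong
edges require |ρ| strictly above 0.5 and p ≤ 0.05.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions the test suite and
acceptance script run under:

- **Genome collection** — 74/22/10 genomes in groups A/B/C; 120 core
  families, 30 group-specific families per group (presence probability
  1.0 in-group / 0.0 out-group, resampled if a draw would violate
  95/95, so planted markers satisfy the rule by construction), 60
  accessory families at presence 0.3. Proteome residues are i.i.d.
  draws from per-group frequency vectors (uniform 1/20 shifted for
  group C by +N/K/I/S, −A/E/R, net zero); ~150-residue proteins.
  G+C targets 0.655/0.645/0.605 (A/B/C) with sd 0.008 over a 20-kb
  nucleotide sequence. The tree places each group as an exclusive
  clade. Family membership is emitted directly in the matrix, so marker
  discovery is tested independently of sequence clustering (which has
  its own small-fixture tests).
- **Metagenome catalogs** — every catalog gene is a point-mutated copy
  of a pan-genome representative (per-residue substitution at rate
  1 − identity/100 with BLOSUM62-favored replacements, default target
  90 %). Per-sample copy numbers are Poisson with a log-normal depth
  factor (σ = 0.5); marker families carry lower per-family rates
  (0.1–0.5 vs 0.5–2.0) so pan hits dwarf marker hits, as in real
  surveys. Enrichment is site-level and uniform: each enriched sample
  receives the same additional group-C marker copies, apportioned by
  largest remainder to total (factor − 1) × the expected baseline, and
  cohort depth is nearly homogeneous (σ = 0.05, cores from one site).
  This plants an intercept offset — the signature a single enriched
  site leaves — rather than a slope change; per-sample multiplicative
  enrichment would leak shared Poisson noise into both axes and steepen
  the cohort-internal slope, confounding the slope-homogeneity gate.
- **Stability curves** — per protein, Tm ~ U[310, 350] K and ΔCp are
  drawn, a target ΔG(−1 °C) ~ N(−8, 1.5) kcal/mol sets ΔHm (a realistic
  folding-energy spread that keeps the planted contrast detectable at
  n = 80 curves/group), and the group-C copy is offset by exactly
  +0.7 kcal/mol at −1 °C before per-curve noise (sd 0.3) is added.
- **OTU counts** — 50 OTUs × 76 samples at depth 10⁴; log-normal basis
  abundances with unit log-variance and planted correlations ±0.8
  between designated pairs, multinomial sampling at fixed depth so rows
  sum exactly to depth. Planted-pair OTUs are pinned to above-average
  abundance (+0.5 log-mean): correlations planted in rare taxa are
  attenuated by sampling noise, the regime the abundance/prevalence
  filter exists to exclude.

All draws flow through `numpy.random.default_rng` seeded from a single
integer; identical configurations give byte-identical outputs.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: phylogenetically realistic sequence
evolution (residues are i.i.d., so alignment scores are optimistic for
diverged homologs); genome contamination and fragmented assemblies;
catalog genes with no source in the pan genome (real metagenomes are
dominated by them; here absent, so screen specificity against unrelated
proteins is exercised only by the random-sequence tests); overdispersed
(non-Poisson) gene counts; spatial/temporal autocorrelation among
samples; and OTU networks with dense, structured correlation beyond a
few planted pairs.

## Problem sizes and numerical notes

The test and acceptance runs use the 106-genome collection with
~270 families, 60 metagenomes (50-seed replication of the
ANCOVA experiment uses the counts-only path, identical draws to the
catalog path minus sequence mutation), 240 stability curves and
50 × 76 OTU matrices — sizes chosen so the full chain, including the
quadratic-DP alignment oracle comparisons, runs in well under a minute.
Degenerate inputs are handled by convention rather than exception where
a value is statistically meaningful: constant responses give p = 1,
zero-variance covariates raise, undefined AAI returns NaN. Basis
variances in SparCC are clipped below at 1e-12 before the square root;
correlation estimates are clipped to [−1, 1] and symmetrized by
averaging with their transpose.

## Known limitations

- The screen is protein-vs-protein only; no translated (six-frame)
  search or frameshift handling, and scores are not meant to reproduce
  any particular aligner's output beyond the shared scoring scheme.
- ANCOVA is limited to two cohorts; the slope-homogeneity gate at
  α = 0.05 is slightly anti-conservative under strong count
  heteroscedasticity (~6 % trips in calibration runs).
- Families-per-genome is one reasonable normalization of marker-set
  size across unequal groups; others (e.g., rarefaction to equal group
  size) are not implemented.
- The pseudo p-value floor of 1/101 with 100 nulls means edge-level
  significance below ~0.01 is unresolvable without raising `n_null`.
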