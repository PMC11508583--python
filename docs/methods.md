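# Methods

## Genetic codes and synonymous families

All statistics are defined on the partition of sense codons into
synonymous families. Codon→amino-acid maps come from the NCBI
translation-table registry shipped with Biopython; the family structure
and degeneracy-class census are derived from them at build time and
validated (table 5: twelve 2-fold, six 4-fold, one 6-fold (Leu), one
8-fold (Ser) family, 62 sense codons, stops TAA/TAG; table 1: 61 sense
codons with two single-codon families). The registry covers tables 1
and 5; other tables are an additive extension. Codons are held
internally as uppercase DNA (U→T on input) because GenBank CDS features
are DNA.

The historical CodonW label "Insects and Platyhelminthes Mitochondrial
code" is implemented as NCBI transl_table 5, the table insect
mitogenomes are annotated with.

## Sequence handling

CDS sets are read from multi-FASTA (header `species|gene`) or GenBank
flat files via Biopython; minus-strand features are extracted in coding
orientation, and gene names are normalised through an editable alias
table (COI→COX1, COB→CYTB, NAD2→ND2, ...). Validation is report-only:

- a 1–2 nt overhang past the last full codon is flagged as a
  *truncated* terminal stop (mitochondrial genes completed by
  polyadenylation), never an error;
- internal stops are reported loudly (0-based codon indices, final
  codon excluded) and the offending codons are routed out of all
  metric counts — they indicate annotation problems and would corrupt
  family counts if translated;
- codons containing ambiguity codes are excluded from every count and
  tallied separately: neither RSCU nor ENC is defined for an ambiguous
  triplet.

The terminal stop codon is always excluded from codon counts (stop
codons are not synonymous codons).

## Per-gene metrics

**RSCU.** `X_j / (Σ_family X / k)`. A family never observed in a gene
yields *missing* for all its codons, while an unobserved codon inside an
observed family yields 0 — a real absence, distinct from missingness.
The distinction matters downstream: missing entries are dropped
pairwise in distances and tests, zeros participate.

**GC3s.** The G+C fraction at third positions of codons in degenerate
families (k ≥ 2). Under table 5 every family is degenerate; under
table 1, ATG and TGG are excluded from numerator and denominator.

**ENC.** Wright's estimator. Per family with n ≥ 2,
`F̂ = (n·Σp² − 1)/(n − 1)`; per degeneracy class the mean of defined F̂
excluding F̂ = 0 (one zero would contribute an infinite 1/F̄ and destroy
the estimator); `ENC = N1 + Σ N_k/F̄_k` with N_k the *code's* census,
capped at the sense-codon count (62/61) because small balanced samples
can push the estimator past it. A class with no usable family — short
mitochondrial genes routinely miss the single 6- or 8-fold family — is
imputed as the average of the nearest available class below and above
(one-sided at the edges), the customary interpolation for missing
classes.

**Length cutoff.** Genes under `min_codons` (default 60) report no ENC.
The cutoff is chosen so that mitochondrial ATP8 (~53 codons), too short
for a stable F̂ in the sparse high-degeneracy classes, is excluded while
every other PCG (next shortest: ND4L, ~98 codons) passes. Both the
cutoff and a by-name exclusion flag are configurable.

**Null curve and selection screen.**
`ENC_exp = 2 + GC3s + 29/(GC3s² + (1−GC3s)²)`, evaluated exactly as
printed. This curve is the classic standard-code expectation (asymptote
near 61) applied under a 62-sense-codon code; the ~1-unit tension at the
top of the range is inherited from the field's practice and documented
rather than corrected. The ENC ratio is `(ENC_exp − ENC_obs)/ENC_exp`
and the selection flag uses a *strict* threshold (> 0.15).

## Comparative layer

Per-species RSCU defaults to *concatenated* mode (pool codon counts over
all PCGs, compute RSCU once), which preserves the family-sum invariant
per species; gene-averaged mode is available. Codons are partitioned by
their across-species mean RSCU (strictly > 1 = frequent). Clustering
uses Euclidean distance with complete linkage by default (both
configurable), computed with pairwise deletion of missing entries;
results are deterministic given inputs, and the emitted leaf order
reproduces heatmap row order.

Pairwise comparisons are paired t-tests on codon-wise RSCU differences
within a codon subset (the frequent and infrequent sets by default,
configurable to all codons). Shapiro–Wilk normality of the differences
is assessed and reported, but the t-test is always computed (reported,
not silently branched). A variance-homogeneity F-ratio of the two
species' RSCU variances is reported alongside, although it is not an
assumption of the paired design. No multiple-testing correction is
applied by default.

**A caution on calibration.** RSCU values within a synonymous family sum
to the degeneracy *k* for every species, so codon-wise RSCU differences
sum to zero within each family. Any subset containing two or more codons
of one family therefore has negatively correlated differences, and the
paired t-test is *conservative*: in simulations with two species drawn
from the same distribution it rejects at roughly 0.01–0.03 rather than
the nominal 0.05 (on the full 62-codon set the differences cancel
exactly and t ≡ 0). A subset with one codon per family restores nominal
behaviour (~0.05 in the same simulations). This is a property of the
published analysis design itself, not of this implementation;
significant results from the test are, if anything, understated.

The selection summary tallies flagged genes by gene and by species and
reports unweighted mean ENC per species over the analysed (non-missing)
genes and per gene across species.

## Synthetic data

The generator emulates sets of mitochondrial PCGs with controlled
codon-usage structure. Amino acids are drawn i.i.d. from a
mitochondrial-like composition (Leu 0.15, Ser 0.11, Ile 0.09, ... — rich
in the 6- and 8-fold families so every degeneracy class is exercised;
fully overridable). Per-gene lengths default to realistic mitochondrial
values (COX1 512 codons ... ATP8 53 codons, deliberately under the ENC
cutoff). Genes start with ATG, end with an appended TAA, and never
contain internal stops by construction (corrupted fixtures for the
validator are built separately in tests).

Regimes:

- **uniform** — within-family probabilities 1/k; no bias, ENC near the
  62 cap; serves as the weak-bias outlier regime.
- **mutation_gc3** — within-family probabilities proportional to a
  third-base composition with G+C mass = `gc3_target` (split equally
  G/C and A/T). Because every table-5 family has balanced third-base
  pairs, the expected GC3s equals the target, and genes land on the
  ENC_exp curve: across a GC3s grid of 0.1–0.9 (50 genes of 300 codons
  per point), the mean |ENC_obs − ENC_exp| is ≈ 1.8–2.0 units,
  dominated by estimator noise at this length.
- **biased** — per-family probability vectors drawn per gene from a
  symmetric Dirichlet; concentration 0.1 gives strong skew, ENC far
  below the null curve, and near-certain selection flags — power by
  construction for the screen.

Sampling reproducibility flows from a single integer seed. The
generating distribution (the Dirichlet draws) lives on a separate RNG
stream controlled by `distribution_seed`, which defaults to the sampling
seed; species panels pin it to the shared spec's seed so panel members
are noisy replicates of *one* codon-usage profile while an optional
outlier species follows its own spec. Per-species child seeds derive
from `SeedSequence(parent, spawn_key=(index,))`, stable across
platforms.

What the generator does **not** emulate: phylogenetic covariance between
species, amino-acid composition differences between genes, strand
asymmetry of the mitogenome, indels, or overlapping genes. Passing tests
therefore demonstrate correctness of the statistics and the qualitative
behaviour of the screens, not that real Chironomidae data will show any
particular effect size.

## Numerical and design choices

- Skews are `(A−T)/(A+T)` and `(G−C)/(G+C)`; undefined skews (zero
  denominator) are reported as missing, never 0. Mitogenome window
  profiles default to circular with the window wrapping past the end.
- Composition percentages are taken on the unambiguous base total.
- Tabular outputs are TSV, UTF-8, Unix newlines, fixed column order,
  floats at 3 decimals by default, `NA` for missing; row order is
  deterministic (species, then gene, then codon), so reruns are
  byte-identical.
- Problem sizes in the test suite and acceptance script (300-codon
  genes, 50 genes per grid point, 1000 replicates for calibration,
  6-species panels) are chosen as the smallest sizes at which the
  binomial/estimator error bounds quoted above are meaningful.

## Known limitations

- ENC values for genes of 60–100 codons are noisy (±5 units is common);
  comparisons should rely on many genes, as the per-species means do.
- The paired RSCU test's conservativeness (above) means its p-values
  are not exchangeable with those of an independent-sample design.
- Gene-averaged RSCU mode does not preserve the family-sum invariant
  when genes differ in which families they observe.
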