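# Methods

## Mechanism and privacy model

`dpgenome` releases a generalized, count-perturbed view of a genotype table
under ε-differential privacy in its unbounded form: for any two datasets
differing in at most one record and any released table,
Pr[Ag(D) = D̂] ≤ e^ε · Pr[Ag(D′) = D̂].

The release pipeline has four stages — blocking, taxonomy, randomized
top-down specialization, Laplace-noised counts. The privacy accounting rests
on three observations:

* block boundaries depend only on (m, block_size), never on genotypes;
* candidate selection is uniform over the cut of the taxonomy forest and the
  partitioning induced by a specialization is fully determined by the
  (public) taxonomy — so the whole specialization phase, conditioned on its
  random trace, is a data-independent function;
* the leaf partitions are disjoint, so adding Lap(Δf/ε) with Δf = 1 to every
  leaf count costs ε once under parallel composition, not once per leaf.

Hence the ledger written into each release's metadata: 0 + 0 + 0 + ε = ε.
The guarantee covers releases built on *user-supplied* taxonomies only. A
data-derived (flat) taxonomy is itself a function of the data; releases
built on one are stamped `taxonomy_private: false` and are outside the
guarantee.

Two independent RNG streams (selection, noise) are spawned from the single
seed. This makes a run exactly reproducible and lets the audit replay the
*same* trace on a neighboring dataset while drawing fresh noise — the
conditioning that the parallel-composition argument needs.

## Empty partitions: two release variants

Specializing a node splits every affected partition into one child per
taxonomy child, including children that receive no records. What happens to
those empty partitions defines two variants, exposed as
`PrivacyParams.keep_empty`:

* **`keep_empty=True` (default).** Every cut-defined leaf is released with
  noise. The support of the release is a deterministic function of the
  taxonomy and the trace — it reveals nothing — so this is the variant the
  privacy audit targets. Its cost: the number of rows is the product of the
  child counts of all specialized blocks. For the hand-sized examples in the
  tests this is at most a few dozen rows.
* **`keep_empty=False` (observed support).** Only record-bearing partitions
  are released. With realistic block diversity this is the only tractable
  variant: a six-SNP block of a 200-individual cohort typically shows
  ~100–300 distinct values, so five specializations under the full-support
  rule would imply on the order of 10^10 rows; materializing and noising
  them is impossible, and the clamped noise mass (≈ 0.5 per row) would
  drown the ~200 records of real signal, destroying utility entirely. The
  evaluation pipeline therefore uses this variant at benchmark scale.
  **Limitation:** the row *set* then depends on the data (a partition
  appears iff its true count is positive), which is a side channel the
  count-vector audit does not cover. The audit conditions on the count
  vector over the full cut support; the observed-support variant should be
  read as the pragmatic experimental mode, not the proof-carrying one.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| ε | 1.0 | total privacy budget (dimensionless); Laplace scale is 1/ε per count |
| h | 5 | number of specializations; small h keeps most blocks generalized |
| block_size | 6 SNPs | balances block-value diversity against granularity; data-set dependent |
| sensitivity Δf | 1 (fixed) | one record moves exactly one disjoint partition count by 1 |
| rounding | raw | `rounded_nonnegative` adds a max(0, nearest-even-int) presentation column; pure post-processing |
| fpr | 0.05 | false-positive rate anchoring attack power at the 95th test-group percentile |
| cutoffs | 5e-2, 1e-2, 1e-3, 1e-5 | p-value grid for significant-SNP recovery |
| trials | 100 | evaluation repetitions; cohorts are fixed per run, trials vary only mechanism randomness |

## Attack details

The per-individual statistic is evaluated per allele copy (`per_allele`):
each of the two copies at a SNP is one Bernoulli entry against the *allele*
frequency, doubling m. A `dominant` carrier coding is available for
sensitivity analysis. Population frequencies p come from the test group
(individuals unrelated to case and control); pool frequencies p̂ come from
the uniform-over-leaves reconstruction of the release (below). All
frequencies are clamped to [1/(2n+1), 1 − 1/(2n+1)] because the statistic's
logarithms are undefined at 0 and 1; minor-allele ties break toward the
lexicographically smaller letter, and a monomorphic SNP takes the smallest
absent letter as its (clamped-frequency) minor allele.

The power threshold is the nearest-rank (1−fpr) percentile of the
test-group statistics, with strictly-greater comparison — no interpolation,
so the definition is exact for small groups.

A null calibration with p̂ literally equal to p is degenerate (every
statistic is exactly 0, so power is 0). The meaningful null used in the
acceptance checks draws the pool from an independent population sample and
scores a group disjoint from pool, test and reference; power then sits at
the nominal false-positive rate (measured ≈ 0.05).

## Utility details

The analyst-facing question is how many truly significant SNPs survive
anonymization. Truth is the allelic 2×2 chi-square scan (genotypic 2×3
available) on the original case/control tables at each cutoff; the
prediction is the same scan on counts reconstructed from the two releases
(case and control anonymized separately at full ε each — the groups are
disjoint, so parallel composition applies across them).

**Reconstruction rule.** Each released row's count, clamped at 0, is spread
*uniformly* over the leaf block-values under each of its generalized labels,
and per-SNP genotype/allele masses are accumulated (fractional counts are
fine for the chi-square). Uniform spreading is the maximum-entropy default
for a question the release alone cannot answer; the rule's name is recorded
in report metadata so alternatives can be compared. Fully specialized rows
contribute exactly their count to their literal genotypes, so the
reconstruction is lossless in the ε→∞, full-specialization limit — the
suite verifies sensitivity = precision = 1 there.

Chi-square tables drop all-zero rows/columns first (df shrinks
accordingly); a table that collapses below 2×2 carries no signal and
reports χ² = 0, p = 1. Tail probabilities come from `scipy.stats.chi2`.

## Synthetic cohorts: what they do and do not emulate

The generator reproduces the *shape* of the benchmark data the method is
discussed against: three groups (case/control/test) of 200 individuals,
panels of 311 or 610 SNPs, minor-allele frequencies uniform on
[0.05, 0.5], and a set of effect SNPs (20 and 40 respectively) whose
case-group frequency is shifted by +0.15 — the simplest mechanism that
makes "significant SNPs" a well-defined ground truth. Alleles are sampled
independently within and across SNPs (Hardy–Weinberg, no linkage
disequilibrium, no population structure).

The no-LD assumption matters for one qualitative result. Real chromosome
panels have strongly correlated neighboring SNPs, so six-SNP blocks carry
few distinct values; uniform-over-leaves reconstruction of mostly
generalized blocks then distorts allele frequencies heavily and produces
the "high sensitivity, very low precision" regime (almost everything looks
significant). Independent SNPs give diverse blocks (~150 distinct values),
the uniform prior is much closer to the truth, and spurious associations
are milder: the evaluation still shows sensitivity above precision at the
default seed, but the margin at the strictest cutoff (1e-5) is small and
can invert for other cohort draws. Passing tests therefore demonstrate the
pipeline's mechanics and direction of effects, not the magnitude of the
false-positive flood expected on real, LD-structured data.

Similarly, the raw-data membership attack on the 311-SNP panel (622
per-allele entries, 200-member pool) reaches a measured mean power of
≈ 0.87 at 5% FPR; the ≥ 0.9 regime starts at wider panels (≈ 0.99 at 610
SNPs). Both numbers are recomputed by the suite and the acceptance script.

## Numerical and representational choices

* Genotypes are normalized to alphabetical letter order (`GA` → `AG`);
  partition labels must be canonical strings.
* Taxonomy roots are `Any_<i>` internally but print as `Any` in release
  rows; the block position disambiguates when parsing a release body.
* Non-leaf labels are unique among non-leaf nodes, leaf labels among
  leaves; a leaf may repeat an ancestor's label (a merged category named
  after its representative value), which multilevel genotype hierarchies
  need. Labels are either a single space-free token or exactly
  interval-length genotype tokens, so release rows re-parse unambiguously.
* Children are ordered, flat-taxonomy leaves sorted lexicographically, cut
  candidates enumerated in (block, preorder) order: a seed fully determines
  a run.
* Released counts serialize via `repr`/`float` for bit-exact round trips.
* When random selection exhausts the cut before h steps, the run stops
  early and logs it (`early_stop` in metadata) rather than failing.
* Negative reconstructed masses are clamped at 0 per row. This introduces a
  small upward bias on near-empty partitions; the pool-frequency check in
  the tests budgets for it explicitly.

## Known limitations

* The observed-support variant leaks the release support (see above).
* Data-derived taxonomies are convenient but not private; the stamp in the
  metadata is the only enforcement.
* The audit addresses the count-release step (pure ε-DP, no δ) conditioned
  on the trace; it does not model post-hoc choices such as which of several
  releases to publish.
* No LD, no population structure, no missing genotypes in the synthetic
  cohorts; VCF import rejects multiallelic sites rather than splitting them.
* Heuristic (data-driven) block sizing and score-guided candidate selection
  are deliberately out of scope; both would consume privacy budget.
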