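# Methods

This note records the model, the numerical choices, and what the synthetic
data do and do not establish. It is written for a reader who wants to
audit or extend the package, not as a results report: every number quoted
here is computed by the test suite or the example scripts.

## Genotype encoding

A panel is an ordered set of L ≥ 3 biallelic loci, each with a major and a
minor allele and two independent positions: a *cycle position* (order of
partitions around the closed path) and a *report position* (column order
of haplotype strings). The default CTLA-4 panel uses cycle order
CT318 → AG49 → CT60 → JO30 → JO27 → JO31 (the hexagon closes JO31 back to
CT318) and report order AG49, CT60, CT318, JO27, JO30, JO31, so the
all-major haplotype reads `AACCAT`.

Two codings map an unordered allele pair to a vertex:

* **three-state** (`a`/`ab`/`b`): full zygosity;
* **two-state** (`a`/`b`): the dominant model — one or two minor alleles
  are treated identically, so a heterozygote occupies the minor vertex.
  The dominant reading of the 2-state encoding is this package's choice;
  it is the coding under which the 2-state graph's components line up
  with carrier patterns rather than chromosomes.

Missing genotypes are a hard load error by default (`drop_incomplete`
opts into dropping whole records); no imputation or strand flipping is
attempted. Cohort labels form the closed vocabulary
{case, control, unknown}.

## Study graphs and edge weights

A subject's cycle contributes +1 to each of its L edges of the cumulative
study graph (subject mode, `weight_unit = 1`). The graph is stored as one
dense S × S weight matrix per adjacent locus pair — the cycle structure
makes this representation lossless, and no general graph container is
needed. Invariants checked after every build: nonnegativity, per-pair
conservation (each pair's weights sum to `n_subjects x weight_unit`) and
vertex balance (in-weight equals out-weight at every vertex).

An alternative **dosage** construction (`weight_unit = 2`) adds
`d_x * d_y / 2` per adjacent pair, where `d` are allele doses (0/1/2), so
each subject contributes two chromosome equivalents. On fully homozygous
cohorts this is exactly twice the subject-mode graph. Weights are stored
as doubled 64-bit integers, making subject weights and dosage halves both
exact; serialization round-trips bit-exactly.

A caveat worth stating plainly: for a subject heterozygous at both loci
of a pair, the dosage rule spreads 0.5 over all four edges — a 50/50
phase guess. Linkage disequilibrium usually concentrates the true phase
on one diagonal, so on strongly linked panels the dosage graph
systematically underweights the common haplotypes' edges relative to
chromosome-level truth, and *no* exact decomposition of it can reach the
EM frequencies (the linear-programming bound over all decompositions
falls short by ~0.1 on the most common haplotype at the default pool).
EM, which resolves phase through the likelihood, is the estimator to
trust for chromosome-level frequencies; the dosage decomposition is kept
as the graph-native approximation.

## Greedy decomposition

A reference profile is a cycle whose L edges carry equal weight; its
multiplicity is that weight. Extraction proceeds in order of decreasing
multiplicity: at every step the candidate cycle with the largest
*removable* multiplicity is subtracted. A cycle's removable multiplicity
is bounded by its bottleneck (minimum edge weight along it), but
subtracting a full bottleneck can strand weight — the residual stays
balanced yet contains no one-vertex-per-partition cycle (the stranded
part is a multi-wrap circulation). The extraction amount is therefore the
maximum of the cycle's coefficient over exact decompositions of the
current graph, computed with a small integer program over the ≤ S^L
candidate cycles (≤ 729 at L = 6); in the common case the widest cycle
passes at its full bottleneck and the check costs one feasibility solve.
This guarantees exact termination on subject-mode graphs (tolerance 0,
integer arithmetic throughout) and at most one cycle extraction per
candidate. Dosage-mode graphs first try half-integer extractions and fall
back to the continuous relaxation when none exists, stopping at a
relative residual of 1e-9.

Ties between equally wide cycles go to fewer non-major states, then
lexicographic state order (`a < ab < b`) — determinism, nothing deeper.
Reference sets may also be injected from a file (multiplicity 0), which
is how a combined-cohort reference set is reused on a sub-cohort.

## EM haplotype estimation and HWE check

Standard multilocus EM under HWE: a record with h heterozygous loci is
compatible with 2^(h−1) unordered haplotype pairs; the E-step weights
them by `2^[h1 != h2] f(h1) f(h2)`, the M-step divides expected haplotype
counts by 2n. Initialization is uniform over haplotypes observed in at
least one compatible pair (never all 2^L); convergence at max frequency
change < 1e-8 or 1000 iterations; the observed-data log likelihood is
asserted non-decreasing at every step; final frequencies below 1e-6 are
dropped and renormalized. Reported standard errors use the binomial
approximation `sqrt(f(1-f)/2n)`, which can differ slightly from
likelihood-based estimators. The per-locus Hardy–Weinberg check is the
1-df chi-square goodness of fit (monomorphic loci return statistic 0,
p = 1 by convention); no exact test is provided.

## Distances, deltas, discrimination

The cycle distance counts mismatching adjacent-pair edge slots; it is a
metric (verified exhaustively over all 64 × 64 two-state cycles) with
maximum L attained exactly by vertex-disjoint cycles. Distances are kept
as nonnegative counts; a `signed` flag provides the negated presentation
variant. Δᵢⱼ = dᵢ − dⱼ for reference ranks i < j: positive means closer
to reference j. Cohort comparison plots per-pair case means against
control means; pairs with both means inside a ±0.5 band are discarded
(subjects there are on average equally far from both references), the
rest ranked by |case − control|/√2. The absence marker selects subjects
at distance exactly L from a reference. Classification uses a CART
decision tree with cost-complexity pruning (fixed `ccp_alpha = 0.005`)
under stratified k-fold cross-validation with a fixed seed; any pruned
tree with stratified folds serves here — acceptance of the classifier is
property-based (separable cohorts → high accuracy; permuted labels →
chance), not tied to a specific tree implementation.

## Survival analysis

Overall survival is dichotomized at a threshold; censoring is ignored by
design (event flags are carried but unused). For each threshold from 800
to 1900 days (step 10 by default) the short/long groups are compared on
every Δ pair with Welch's t-test (Mann–Whitney by flag); raw p-values are
primary and Benjamini–Hochberg values co-reported since K(K−1)/2 tests
run at once. Degenerate pairs (zero variance in both groups) get p = 1
when the constants agree, p = 0 otherwise.

The best split is the statistically most significant one: smallest
minimum p first, then most significant pairs, then balance. The count of
significant pairs is deliberately *not* primary: once an effect is real
it saturates across a wide threshold band and its sampling noise (±2
pairs) picks thresholds far from the change point, while the minimum p
stays sharply peaked at the true grouping. Thresholds leaving a side with
fewer than `min_group = 10` subjects are skipped — a two-subject group
with zero variance produces arbitrarily small Welch p-values and would
hijack the minimum-p ranking.

The logistic model for the short-survival category is a maximum
likelihood fit on selected Δ features; on (quasi-)perfect separation it
warns and refits with a small fixed ridge penalty so coefficients stay
finite. The fitted model serializes to JSON, and the odds calculator
(`netphen odds`) evaluates probability and odds of short survival for a
new subject's Δ row.

## Synthetic data: what it emulates, what it does not

Subjects are two independent haplotype draws (HWE) from a pool with
strong linkage disequilibrium. The default pool is the five published
CTLA-4 haplotypes, renormalized from their 95.4% total to 1 rather than
inventing a residual haplotype: AACCAT 0.4926, GGCTGG 0.3075, AGTTGG
0.1024, AGCTGG 0.0680, AGCCAT 0.0295. Cohort sizes default to the study
design (286 cases, 288 controls). Optional structure: a separate case
pool; an absence constraint drawing a fraction of cases only from
diplotypes vertex-disjoint from a designated reference cycle
(HWE-conditional probabilities within the allowed set); and planted
survival, where a logistic score on a designated Δ feature ranks
subjects, the top `short_fraction` (default 145/282) form the short
group, and times fall exponentially (scale 300 days) below/above the
threshold (default 1820 days). The exponential clustering is a
deliberate choice: it gives the threshold scan a realistic, sharply
identifiable change point, where uniform times leave the
misassignment gradient too shallow for any selection rule to localize.
All randomness flows from one seed through a named generator; runs are
bit-identical.

Scenario sizes used by the test suite — cohorts of 200–600 for the
conservation properties, n = 1000 for EM recovery, 282 cases for the
survival scenarios, 100 replicates for calibration — are chosen so the
binomial/t-test sampling errors are comfortably inside the asserted
tolerances. For the 20-reference survival scenarios the pool is extended
with five rare one-step variant haplotypes at 2% each: the published five
cover only 95.4% of chromosomes, and it is the rare tail that pushes the
three-state decomposition to ~20 natural components, the reference-set
size the survival analysis works with. Padding with arbitrary injected
cycles instead would create near-constant Δ columns whose tests are
miscalibrated.

What passing tests do **not** show: the generator has no recombination,
mutation, genotyping error, missingness or population structure — it is
exactly the HWE-with-LD model the EM estimator assumes, so EM recovery
here is a correctness check, not evidence about model misspecification on
real cohorts. Cohort-specific published quantities (the exact component
counts 8 and 20, specific p-values, the 77%/219 absence rate as a data
property) depend on unavailable patient data; the package emulates these
scenarios and verifies the machinery's behaviour on them, nothing more.

## Known limitations

* Decomposition candidates are enumerated brute force; panels beyond
  ~12 three-state loci would need a smarter candidate search.
* The dosage-graph decomposition structurally underestimates common
  haplotype frequencies on strongly linked panels (see above); use EM
  for chromosome-level frequencies.
* No LD statistics (D′/r²), no Cox or censoring-aware survival models,
  no exact HWE test — all outside the method's scope.
* The VCF reader matches loci by rsid in the ID column only and requires
  complete diploid calls.
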