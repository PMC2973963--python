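# Methods

This note documents the models, algorithms, and numerical choices behind
`epiensemble`, in the order a user meets them: data model, base classifiers,
ensemble fitness, the genetic-algorithm search, interaction calling, the
epistasis simulator, and the evaluation statistics.

## Data model and preprocessing

Genotypes are categorical codes 0/1/2 for aa/Aa/AA, with code 2 the major
homozygote; environment factors are small non-negative category codes.
Missing cells are tracked by an explicit mask (text token "NA", configurable;
the PLINK `.raw` dialect uses its own missing code). Two pre-filters are
provided for real data: a missingness filter that drops factors with a
missing fraction *strictly greater* than 20% (a factor at exactly 20% is
kept), and an allelic association filter — a plain Pearson chi-square on the
2×2 allele-by-class table (genotype g contributes g copies of the major
allele), 1 df, no continuity correction, keeping SNPs with p < 0.05. A
degenerate margin (monomorphic SNP) is reported as statistic 0, p = 1 rather
than an error, so genome-scale sweeps do not abort.

Remaining missing genotypes are imputed to the column mode, ties to the
smaller code. This is a deliberate, documented choice; any imputation rule
could be substituted upstream.

Age is discretized by the Gaussian rule: with mean μ and **population**
standard deviation σ (the n-denominator form, fixed for reproducibility),
x ≤ μ − σ/2 is "young", x ≥ μ + σ/2 is "elderly", the open band between is
"medium". Both boundary comparisons are inclusive on the outer categories.

## Base classifiers

All five committee members treat genotypes as unordered categories and are
fully deterministic; every tie-break is fixed:

* **Gain-ratio decision tree** — multiway categorical splits chosen by gain
  ratio; ties go to the lowest factor index, and an impure node splits even
  at zero gain while an unused factor with ≥ 2 observed values remains (this
  is what lets the tree crack pure XOR patterns whose single-factor gain is
  zero). Each factor is used at most once per path; leaves take the majority
  label, ties to control; a factor value unseen at a split routes to that
  node's majority. No pruning; depth is unlimited by default and
  configurable. Internally the tree is grown level-wise over flat arrays
  (all open nodes of a depth scored by one contingency pass), and the five
  cross-validation folds of one evaluation are grown together as a single
  forest; this is an implementation detail with no effect on predictions.
* **k-nearest-neighbour (k = 1, 3, 5)** — overlap (Hamming) distance;
  neighbours ordered by (distance, training-row index); vote ties (possible
  only for even k) fall back to the training class prior, prior ties to
  control. Exact neighbour search; the three k values share one distance
  matrix per fold.
* **KStar-style entropic learner** — the transformation probability from a
  training row to a test row is a per-factor product: a matching factor
  contributes (1 − b) + b·π(v), a mismatch contributes b·π(v), where
  π(v) is the Laplace-smoothed training frequency of the test value and
  b = 0.20 is the blend. Class score is the class-mean transformation
  probability; ties to the prior. The blend and the smoothing are
  package choices (the method family does not fix them); the committee is
  configurable, so any fifth classifier can be substituted.

The k-NN members stand in for cover-tree k-NN: a cover tree is an index that
changes lookup speed, not predictions, so exact search is used. The tree is
a gain-ratio C4.5-family tree without error-based pruning.

## Ensemble fitness

A subset is evaluated by stratified 5-fold cross-validation with pooled
out-of-fold predictions: each classifier predicts every sample exactly once.
The fold assignment is derived from a protocol seed and reused for every
subset scored under one configuration — and across all restarts of one
search — so fitness differences between subsets are paired, not split-noise.
If the minority class is smaller than the fold count, the fold count is
reduced with a warning.

Three components, each in [0, 1]:

* blocking = mean over classifiers of BC/100, with BC = (Se + Sp)/2,
  Se = 100·N_TP/N_case, Sp = 100·N_TN/N_control;
* voting = BC of the majority-vote prediction /100; consensus needs
  k = M/2 + 1 votes (M even) or (M + 1)/2 (M odd); an exact even split falls
  back to the training prior;
* diversity = 1 − mean pairwise double-fault rate over the M(M−1)/2 pairs.

The raw blocking definition is a *sum* of BC percentages over classifiers,
which is not commensurate with a single BC (voting) or a [0, 1] statistic
(diversity); the combination weights only make sense on a common scale, so
blocking is normalized to mean-BC/100 and voting to BC/100. Default weights
are 0.425/0.425/0.15 (blocking/voting/diversity), the tuned configuration
under which the committee beat its best single member.

Balanced accuracy is used throughout because half the study designs are
imbalanced (67 cases : 133 controls); a constant-class predictor scores 50
regardless of the class ratio.

## Genetic-algorithm search

A chromosome is a length-d string of factor ids with 0 marking an empty
position; the decoded subset is the set of distinct non-zero ids, so one
population explores subset sizes 2..d in parallel. Duplicates introduced by
crossover or mutation are collapsed to 0 (set semantics); a chromosome left
with fewer than two distinct ids has random genes re-grown. Initialization
draws each gene as empty with probability 0.5, else a uniform factor id.

Operators: tournament selection of size t with replacement (winner = highest
combined fitness; exact ties prefer the smaller decoded subset, then
lexicographic order — the complexity-regularization rule); single-point
crossover with probability 0.7; multi-point mutation in which a first
mutation fires with probability 0.1 and each subsequent one continues with
probability 0.25 (geometric chain, mean length 4/3 given at least one); one
elite survives unchanged per generation, which makes the best-fitness trace
non-decreasing and the final-generation best the best subset seen.

Search-budget parameters scale with the panel size, interpolating linearly
from (d = 15, p = 40, g = 8, t = 3) at 20 factors to (d = 25, p = 340,
g = 20, t = 7) at 100 factors and clamping outside that range. The full
protocol restarts the GA n = 30 times with seeds master_seed + i; subset
scores are cached across restarts (the folds are shared, so a subset's score
is restart-invariant).

## Interaction calling

The n best subsets are mined for all size-k combinations (k = 2..3 by
default; configurable upward — enumeration grows as C(d, k)). A
combination's frequency is (number of best subsets containing it)/n; by
containment, a triplet can never outscore a pair inside it. Two calling
criteria: frequency strictly greater than a cut-off (default 0.8), or dense
rank ≤ a cut-off with all boundary ties included. Ranks are assigned both
within each size class and pooled across sizes; rank-based calling uses the
per-size ranks by default and the pooled ranks on request. Combinations may
mix SNP and environment factors, so gene–environment calls (e.g. a
SNP × Sex pair) need no special casing.

## Epistasis simulator

A two-locus model is a 3×3 penetrance table f over genotype pairs plus
minor-allele frequencies; genotype probabilities are Hardy–Weinberg,
(q², 2q(1−q), (1−q)²) with q the MAF. Derived quantities: prevalence
K = Σ p_i p_j f_ij and heritability h² = Σ p_i p_j (f_ij − K)² / (K(1−K)) —
the penetrance-scale definition standard for purely epistatic simulation
models.

`find_penetrance_table` draws a random 3×3 deviation, projects it by
HWE-weighted double-centering onto the exact null space of both loci's
marginal effects (every genotype's marginal penetrance equals K to machine
precision), draws K ~ U(0.05, 0.5), solves the deviation scale analytically
from the target h², and accepts the first draw with all penetrances inside
[0, 1]. The search is seeded and deterministic; an infeasible target (e.g.
h² = 0.999 at MAF 0.05) exhausts max_iter and raises. This replaces an
approximate hill climb with an exact construction — the target heritability
and the no-main-effect property hold by algebra, not by tolerance chasing.

Datasets are drawn by conditioning: cases sample the nine genotype-pair
cells with probability ∝ p_a p_b f, controls ∝ p_a p_b (1 − f), via
inverse-CDF (exact, no rejection). Noise SNPs are independent HWE draws with
MAFs uniform in [0.05, 0.5] per SNP; the functional pair's MAF defaults to
0.2 (the one value the study conditions fix). The two functional columns are
placed at seeded-random positions so detectors cannot exploit column order.
Nine named designs cover the study grid: balanced (100:100) and imbalanced
(67:133) 200-sample panels of 20 or 100 SNPs at h² ∈ {0.2, 0.1, 0.05};
replicate i of a set uses seed base_seed + i with one shared penetrance
table per set.

What the simulator does *not* emulate: linkage disequilibrium between loci
(all SNPs independent), higher-than-pairwise functional models, quantitative
covariates, genotyping error, or population structure. Passing tests on
these data show that the detector recovers a purely epistatic pair embedded
in independent noise — not that it is robust to LD-induced redundancy or
confounding in real panels.

## Evaluation statistics

Power = 100 · (successful replicates)/N, where success means the true pair
is the top-ranked size-2 combination; a rank-1 tie containing the true pair
counts as success (inclusive reading). FDR(c) = false accepted / accepted
and TPR(c) = accepted-true / (accepted-true + rejected-true) at a rank or
frequency cut-off c, averaged per replicate; a replicate accepting nothing
contributes FDR 0 (the 0/0 convention). At rank cut-off 1, TPR equals
power/100 identically.

For two detectors, per-replicate outcomes cross-tabulate into SS/SF/FS/FF;
single fault SF = N_SF + N_FS, double fault DF = N_FF, complementarity
CD = SF/(DF + SF) (undefined when both detectors are perfect — reported as
not applicable), pair joint power = 100·(N − FF)/N, triple joint power =
100·(N − N_FFF)/N. When only marginal success counts and a joint power are
published, the fault table is reconstructed by inclusion-exclusion
(FF = N − union, SS = n_x + n_y − union), with a consistency check that
rejects impossible count triples. External detectors are consumed as
per-replicate success vectors from TSV; nothing about them is reimplemented.

## Problem sizes used in the automated checks

The published power studies used 100 replicates per condition with
penetrance tables that are not public. The package's acceptance checks
regenerate the conditions with its own simulator at 20 replicates per
heritability (balanced, 20 SNPs, MAF 0.2, default search configuration) and
assert properties rather than point values: power ≥ 70% at h² = 0.2 against
a ~0.5% random baseline, a non-increasing power trend over
h² ∈ {0.2, 0.1, 0.05}, and mean FDR ≤ 0.05 at the 0.8 frequency cut-off.
The GA-versus-exhaustive oracle check runs on a 200 × 10 panel where all
subsets of size ≤ 3 can be enumerated exactly. Complementarity arithmetic is
checked exactly against the published per-condition success counts; one
published CD cell (balanced, h² = 0.2, 100 SNPs, GE+MDR) is internally
inconsistent with its own marginals and is excluded from the regression.

## Known limitations

* The committee is tuned for 200-sample panels; very small folds (minority
  class < 5) trigger automatic fold reduction and noisier fitness.
* Enumeration-based calling is practical for k ≤ 4 on d ≤ 25 chromosomes;
  higher orders need a larger k_max and grow combinatorially.
* KStar's blend and the tree's lack of pruning are fixed, documented
  substitutes for unspecified originals; both are configurable.
* The AMD-style real-data workflow (LD-block construction, tree-based
  pre-screening of a 100k-SNP panel) is out of scope; only the two simple
  pre-filters (missingness, allelic chi-square) are provided.
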