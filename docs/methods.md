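# Methods

## Profile re-ranking model

A screening profile is an ordered set of N kinases, each labeled target
or anti-target, with one or more docking runs (crystal structures) per
kinase.  All runs score the same molecule library; a molecule's only
input to the model is its ordinal rank r in each run and the run's
library size m.

Per kinase, a molecule's scaled ranks R over that kinase's structures
are aggregated to the most favourable one and log-transformed:

* target: `P_k = log_b(min_s r_{k,s}/m_{k,s})` — the molecule is
  credited with its best structure;
* anti-target: `P_k = log_b(max_s (1 − (r_{k,s}−1)/m_{k,s}))` — the
  inverted rank, maximised over structures, so a molecule is penalised
  if it docks well into *any* structure of the anti-target.

The combined score is `S = mean(P) + (max(P) − min(P))/2`, lower
better.  The logarithm concentrates resolution at the top of the
ranked list, where docking scores actually discriminate: in a
multi-million-compound library the difference between ranks 100 and
1,000 matters, that between 2,000,000 and 2,100,000 does not.  The
spread term penalises molecules whose per-kinase performance is
unbalanced; for N = 2 targets S reduces to max(P), i.e. a molecule is
only as good as its worse target.

### Anti-target inversion offset

The naive inversion `R = 1 − r/m` assigns the worst-ranked molecule
(r = m) a scaled rank of exactly 0, whose logarithm is undefined.  We
use `R = 1 − (r−1)/m` instead, which maps ranks onto [1/m, 1] —
exactly mirroring the target case — while inducing the same ordering.
This is a deliberate regularisation of the inverted-rank formula, not
a property of the data.

### Numerical and convention choices

* **Log base** — default 10, configurable.  The molecule ordering by S
  is invariant to the base, because both the mean and the spread are
  homogeneous of degree one in P; the base only rescales reported
  magnitudes.  This invariance is asserted by the test suite.
* **Tie-breaking in ranks** — docking scores are sorted ascending
  (lower energy = better; a flag inverts this) and exact score ties
  are broken by lexicographic molecule id.  Ordinal, reproducible
  ranks matter more here than tie symmetry, because the score consumes
  integer ranks and downstream rank correlations assume permutations.
* **Exact S ties** — different rank combinations can give exactly
  equal S (for two targets, any pair sharing the same worse scaled
  rank ties).  Floating-point summation noise (~1e−16) would break
  such ties differently under different log bases, so `profile_score`
  sums components in sorted order (making permuted rank multisets tie
  bitwise) and the final sort quantizes S at 1e−12, far below any real
  score difference, letting exact ties fall through to the molecule-id
  tie-break.
* **Coverage rule** — a molecule is scored only if it has a rank in at
  least one structure of *every* profile member; others are dropped
  and counted.  Eq.-style scoring needs every P_k, and imputing
  missing ranks would invent data.  An optional `missing_as_worst`
  mode imputes rank m+1 instead, for libraries docked incompletely.
* **Duplicate score rows** — collapsed to the best score, the tabular
  analogue of keeping a molecule's best pose.
* **Expected hit rate** — `expected_profile_hit_rate` multiplies
  per-kinase success probabilities (target hit rates, anti-target
  avoidance rates) under an independence assumption; it is a
  back-of-envelope planning number, not a calibrated model.

## Similarity measures

All four measures produce labeled symmetric matrices; undefined
entries are NaN, never silently zero.

**LigProfSim.**  Bioactivity records are filtered to binding-assay
IC50 values; records with a `>` qualifier are dropped (they cannot
confirm potency), `<` and `=` are taken at face value.  Within one
(compound, kinase, assay) the lowest IC50 is kept, and the minimum is
taken again across assays — "most active" is the convention applied at
both levels, although only the within-assay rule is standard; the
cross-assay minimum is this package's choice.  A pair is active below
500 nM (strictly; 500.0 itself is inactive).  The pairwise similarity
is common-actives / common-tested; the diagonal (actives/tested) is
the kinase's promiscuity.  No compound tested on both kinases → NaN.

**PocSeqSim.**  Identity fraction over the fixed 85-position pocket
alignment, denominator always 85.  A gap matches nothing, including
another gap — no residue is present to be identical.  This is a
convention: alignment sources do not state how gap–gap positions
should count, and counting them as matches would inflate similarity
between poorly covered pockets.

**IFPSim.**  Tanimoto similarity |a∧b|/|a∨b| on 595-bit fingerprints
(85 residues × 7 interaction types, residue-major bit order).  Two
all-zero fingerprints score 0 with a warning — an interaction-free IFP
shares nothing, and NaN would silently poison max-reductions.
Structure lists are first reduced to orthosteric-ligand entries, one
per PDB structure: highest quality score wins, ties going to the
lexicographically smallest structure key so the filter is invariant to
input order.  DFG/αC conformation annotations are carried through and
filterable but not filtered by default.  Kinase-level similarity is
the maximum over structure pairs; the diagonal uses distinct
structures of the same kinase and is NaN for single-structure
kinases.

**DockRankSim.**  The top-N molecules (default 25,000, configurable;
the cutoff is a discrimination device, not an optimised constant) of
two runs are intersected, the intersection's ranks renumbered 1..k
preserving each run's order, and Spearman's rank correlation taken —
via `scipy.stats.spearmanr`; the renumbered ranks are tie-free
permutations, so no tie correction is involved, and the test suite
cross-checks against the closed-form `1 − 6Σd²/(k(k²−1))`.  k < 2
yields NaN rather than an error so matrices over many structure pairs
degrade gracefully.  Kinase-level similarity is again the maximum over
structure pairs.

**Summaries and cross-measure comparison.**  Per-kinase summaries
report mean ± s.d. of the kinase's row *including* the diagonal
(self-similarity is part of a kinase's profile here), excluding NaN
pairwise; the s.d. is the sample flavour (ddof = 1) by default.
`compare_measures` correlates two measures' off-diagonal upper
triangles (Pearson, parametric two-sided p), pairwise-complete.
Diagonals are excluded because self-similarity means different things
per measure (promiscuity vs conformational spread vs nothing).  Fewer
than 3 complete pairs → NaN with a warning.

## Synthetic-data generator

The generator defines the study conditions under which the package is
exercised and tested; it emulates structure, not chemistry.

* **Docking runs** — each molecule draws a standard-normal reference
  affinity z; kinase k's latent affinity is `ρ_k·z + √(1−ρ_k²)·ε`,
  and each structure adds independent noise on top.  Between two
  kinases the latent scores correlate at ρ_a·ρ_b, so ρ dials the
  expected rank correlation.  Default structure noise 0.1 (one tenth
  of the affinity spread) keeps structures of one kinase strongly but
  not perfectly correlated, as crystal forms of one kinase are.
* **Activity tables** — the exact-count mode builds disjoint compound
  blocks: one block per kinase pair carrying exactly the planned
  common-tested compounds (the planned number active on both, the
  rest inactive on both), then per-kinase blocks topping up the
  marginal totals.  Promiscuity and LigProfSim then equal the planned
  ratios *exactly*, which is what unit tests need.  Infeasible plans
  (pair actives > pair tested, or pair blocks exceeding a marginal)
  raise before emitting records.  Active values are drawn in
  10–400 nM, inactive in 600–10,000 nM, clear of the 500 nM threshold
  on both sides.  A stochastic Bernoulli mode serves property tests.
* **Pocket sequences** — a base 85-mer (random or supplied) with an
  exact number of positions mutated per kinase, always to a different
  residue, so identity to the base is (85 − mutations)/85 by
  construction.
* **IFPs** — a shared base bit vector of planned density (default
  0.15, a sparse fingerprint as interaction fingerprints are) with
  independent per-bit flips at each structure's planned rate.

Random streams are keyed per component (reference scores, each
kinase, each structure), so adding a kinase to a plan does not perturb
the data generated for existing ones, and every generator is a pure
function of (config, seed): re-running writes byte-identical files.

What the generator does *not* emulate: real chemical series and
scaffold effects in docking scores, assay heterogeneity and censoring
patterns in bioactivity data, phylogenetic structure in pocket
sequences, or the residue-wise correlation of real interaction
fingerprints.  Passing tests therefore demonstrate that the
*computations* are correct and well-behaved under controlled
conditions — not that any particular real kinase pair has a given
similarity.  Published kinase-pair values depend on database snapshots
and full docking campaigns and are out of desk-scale reach; the test
suite covers those code paths with property-based checks (symmetry,
ranges, oracle equivalence, parameter recovery) instead.

## Problem sizes used in tests

The test and acceptance workloads are sized for a single CPU: rank
correlation recovery uses libraries of 10,000 molecules with a top-500
cutoff over 50 replicate seeds per latent-correlation setting;
permutation oracles enumerate all intersections up to k = 7
exhaustively and sample k = 8; bitwise oracles run 1,000 random
instances.  The package itself has no size limits beyond memory —
score tables are parsed with pandas and rank aggregation is
dictionary-based, linear in the number of molecules.

## Known limitations

* The anti-target aggregation (max over structures of the inverted
  rank) keeps the *least* favourable evidence: one structure in which
  a molecule docks well is enough to void its anti-target credit.
  This is by design but makes anti-target scores sensitive to single
  noisy runs.
* LigProfSim inherits the sparsity of the underlying bioactivity
  matrix: pairs with few commonly tested compounds produce unstable
  ratios, and the package reports the companion counts so users can
  judge support.
* Cross-measure correlations use a parametric Pearson p-value; with
  the small number of kinase pairs in typical panels this is
  indicative, not inferential.
* Scores are treated as exchangeable across structures of one kinase;
  no per-structure normalisation is applied before rank aggregation
  (ranks are already scale-free within a run).
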