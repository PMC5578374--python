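# Methods

This note records the models, conventions and numerical choices behind
`phyloprofiler`, and what the synthetic benchmark does and does not show.

## Profiles

A binary profile marks protein `i` present in organism `j` when some
homology-search hit for `i` in `j` has E-value at or below the cutoff
(default 0.001; the comparison is inclusive because cutoffs are user-facing
and an inclusive boundary is least surprising). A bit-score profile keeps
the best (maximum) bit score per protein/organism cell, the usual best-hit
convention. Subjects in BLAST tabular input are resolved to organisms by
exact identifier, else by the longest mapping key that prefixes the subject
id; unresolvable subjects are counted and reported, never fatal. Proteins
with no qualifying hit anywhere keep an all-zero row — they are flagged
(`all_zero_rows`) rather than dropped, and every downstream measure defines
its behaviour on them (Jaccard of two all-zero rows is 0, their Pearson
correlation is undefined). If the query organism itself is in the catalog
its column is kept as given; self-hits simply make it all-ones, which
shifts every measure equally and no ranking changes.

## Co-occurrence measures

Jaccard, Pearson, mutual information and Lp-norm are implemented exactly as
their formulas read, with three conventions:

* mutual information uses log base 2 (bits); the base rescales all values
  by one constant and cannot reorder pairs;
* Pearson uses the sample form (n−1 denominator). A constant profile makes
  the correlation undefined; the package returns NaN and every consumer
  treats NaN as "not positively correlated" rather than letting it poison
  downstream arithmetic (`on_constant="raise"` is available for standalone
  use);
* `0·log(0) = 0` in the mutual-information sum.

Pairwise matrices are computed from the four joint presence counts per
pair, in row blocks, so an n×m profile needs one block×n product at a time
rather than n² per-measure intermediates. On binary data the Hamming
distance equals the squared Euclidean distance exactly; the property tests
use this as a cross-check.

## Dollo parsimony

Presence of a homolog is modelled as a character gained at most once on a
rooted species tree and lost freely (Dollo). The minimum-loss
reconstruction is closed-form: the gain sits at the MRCA of all presence
leaves, and a node is present iff it lies in the gain's subtree and its own
subtree still contains a presence leaf. The test suite proves this equals
(and is the unique minimiser of) an exhaustive search over all single-gain
assignments on every rooted binary labelled tree with up to 5 leaves and
on seeded random 6-leaf trees, for every leaf pattern.

The pairwise distance sums, over branches, the absolute difference of the
two proteins' branch state changes; for ranking and ROC sweeps distances
are negated (smaller distance = stronger link). Trees must be rooted:
rooting changes the reconstruction, so an explicitly unrooted Newick
(`[&U]`) is rejected with guidance rather than silently rooted. Profile
organisms missing from the tree are dropped from the reconstruction (the
count is reported); tree leaves missing from the profile count as absent.
Multifurcations are handled natively.

## NPP and SVD normalization

Both transforms start from raw bit scores and apply a floor (strictly
below 70 → 1 for NPP; strictly below 60 → 0 for SVD, as the thresholds are
conventionally stated) and a conservation filter: a protein is dropped
when fewer than `min_homologs` (default 12) organisms have a *raw* score at
or above the floor. Counting on raw scores, before the floor replacement,
keeps the sentinel values out of the homolog count. The filter is monotone:
raising `min_homologs` can only shrink the retained set.

NPP then takes each entry to `log2(p_ij / p_max_i)` against the row
maximum and z-scores every column with the sample SD. Columns with zero
spread cannot be z-scored; they are set to 0 and listed in the output
parameters with a warning.

SVD scales rows by their maxima (all-zero rows are dropped), factors
`P = UΣV'`, keeps the first `ceil(trim_fraction · m)` columns of `U`
(default 30%), and scales retained rows to unit Euclidean norm, so
pairwise Euclidean distances lie in [0, 2] and satisfy
`d² = 2 − 2·(u·v)`. Two additional numerical choices:

* retained dimensions are capped at the numerical rank of the scaled
  matrix. Columns of `U` beyond the rank span an arbitrary null-space
  basis chosen by the factorization, and keeping them would make two
  proteins with identical inputs land at distance up to √2 for no reason;
  with the cap, identical rows always score distance 0. Full-rank inputs
  are unaffected.
* the conservation filter runs after the factorization, so the factor
  basis is computed from all rows and filtering cannot change it.

The normalized scorers are Pearson (NPP, similarity) and Euclidean
distance (SVD, distance).

## Top-rank linkage prediction

For every protein, candidates with Pearson ≤ 0 (or undefined) are removed
— a non-positive correlation means the two proteins tend not to co-occur,
which is not co-evolution — and the remainder are sorted by decreasing
Jaccard, with ties broken by decreasing Pearson and then lexicographic
identifier so the ordering is total and the algorithm deterministic. Ranks
are 1-based and the default threshold keeps rank ≤ T ("top T partners");
the alternative strict reading rank < T is available behind the
`strict_rank` flag. The predicted set is the union over proteins with
direction ignored; each stored link carries the minimum of its two
directed ranks. A protein whose filtered list is empty (or out of reach
under the strict convention) receives its single best-Jaccard partner,
flagged `fallback`, so every protein keeps at least one link at every
threshold — users who want only filter-passing links can drop flagged
rows. Predictions are monotone in T (nested link sets), which the sweep
machinery exploits by computing the pair-rank table once and thresholding
it per T.

## Reference sets and curves

Positives are all unordered intra-complex pairs, pooled over complexes
(optionally after dropping complexes above `max_subunits` members, which
otherwise dominate the pool quadratically). Negatives are drawn uniformly
without replacement, driven by an explicit, recorded seed, from pairs
whose proteins share no complex and whose complexes share no localization
label; the localization rule applies at the complex level. A pair that is
positive anywhere is never eligible as a negative, which keeps labels
consistent for proteins in several complexes. Requesting more negatives
than there are eligible candidates is an error, never a silent cap; the
default negative:positive ratio is 10.

Score sweeps use the distinct scores achieved by reference pairs as
thresholds (ties flip together); distance-type matrices are negated first;
reference pairs the scorer cannot score (e.g. a protein dropped by a
conservation filter) count as unlinked at every threshold. For the
top-rank predictor the sweep variable is T itself. AUC is the trapezoidal
area under the achieved ROC points anchored at (0,0) and (1,1); without
ties it equals the Mann–Whitney two-sample statistic, which the tests
assert to 1e-9. Precision at TP+FP = 0 is recorded as NaN and skipped in
PR output.

## Synthetic benchmark

The generator plants "evolutionary modules": organisms are partitioned
into clade blocks; each module draws one base presence pattern by
switching whole clades on (presence probability 0.95 inside an occupied
clade, 0.02 outside, each clade occupied with probability 1/2 and at
least one occupied); every member copies the base pattern with
independent symmetric bit flips at rate `flip_noise`; background proteins
draw their own patterns the same way. Base patterns are redrawn until
distinct and non-constant so that within-module correlations are defined
and modules are separable in principle. Bit scores are zero where absent
and truncated-normal (mean 150, SD 30, floor 25) where present, so the
normalization floors at 60/70 are genuinely exercised by the lower tail.
The species tree is a random rooted bifurcating tree with each clade
block monophyletic. Each module maps to one complex whose localization
label is the module id, so derived negatives are strictly cross-module.
All randomness in a fixture flows from one integer seed.

Default conditions (3 modules × 6 proteins, 12 background proteins, 60
species in 6 clades, flip noise 0.05) are small enough that the full test
suite runs in seconds while leaving every pipeline stage non-trivial; the
acceptance script uses a larger instance (10 modules, 120 species, 10%
noise, 10:1 negatives) so that the 10:1 sampling ratio is satisfiable
among cross-module pairs.

**What passing tests do and do not show.** At these scales the planted
modules are well separated, so most scorers sit near AUC 1 and the
benchmark demonstrates correctness of each computation, monotone
degradation with noise, and exact noise-free recovery — not the relative
ranking of methods on real proteome data. In particular, symmetric flip
noise makes a shared absence exactly as informative as a shared presence,
so distance measures that credit co-absences (Hamming) are unrealistically
strong here, whereas on real profiles — sparse, with far less reliable
absence calls than presence calls, over hundreds of mostly distant
genomes — presence-based similarity is empirically the stronger signal.
The cross-method ordering observed on this generator therefore does not
transfer to real data, and one ordering assertion in the acceptance suite
(top-rank AUC ≥ Hamming AUC per seed) fails for exactly this reason; the
generator keeps symmetric flipping because it is the simplest mechanism
that exercises both false presences and false absences. The generator
also does not model sequence evolution, gene-tree/species-tree
discordance, detection bias correlated with evolutionary distance, or
overlapping complexes.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `e_threshold` | 0.001 | inclusive E-value cutoff for presence calls (0.001 / 0.0005 / 0.0001 are the conventional options) |
| `top` (T) | 400 (CLI) | per-protein number of top-ranked partners kept; 400 is the conventional whole-proteome setting, capped at n−1 |
| NPP `score_floor` | 70 | bit scores strictly below become 1 before the log-ratio |
| SVD `score_floor` | 60 | bit scores strictly below become 0 before row scaling |
| `min_homologs` | 12 | conservation filter on raw scores ≥ floor |
| `trim_fraction` | 0.3 | fraction of singular dimensions kept (1.0 and 0.3 are the conventional settings) |
| `ratio` | 10 | negatives per positive in reference sets |
| `flip_noise` | 0.05 | per-entry symmetric flip rate in the simulator, in [0, 0.5) |

## Known limitations

* Dollo distances depend on the rooting; with an unrooted published tree
  the user must root it explicitly, and results under different rootings
  are only property-tested, not compared to any published value.
* Mutual information cannot distinguish correlated from anti-correlated
  pairs; the top-rank predictor's positive-correlation filter exists
  partly for this reason.
* Tie handling in threshold sweeps (all tied pairs flip together) can
  differ from other ROC implementations in the third decimal on heavily
  tied integer scores.
* The pairwise stages are dense O(n²); they are comfortable for tens of
  thousands of proteins on one machine but make no attempt at
  out-of-core score stores.
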