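# Methods

This note documents the models, conventions and design choices behind
`vlamy`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open decisions were made.

## Data model and coordinates

A V_L record is a 20-letter amino-acid string plus seven region
boundaries (FR1, CDR1, FR2, CDR2, FR3, CDR3, FR4) that must tile the
sequence exactly, in order, with no gaps or overlaps.  All file
coordinates are 1-based and inclusive on both ends, matching
human-readable antibody numbering exports; conversion to Python's
0-based half-open slices is internal and lossless.  Region annotation is
consumed, never computed: assigning IMGT boundaries requires a numbering
HMM and is deliberately out of scope, as is isotype calling (isotype is
carried as metadata only and never enters the feature vector).

Records violating the tiling invariant, or containing nonstandard
residues under the default `strict` policy, are excluded with a logged
reason — the same curation a real light-chain database applies when it
drops sequences with missing or unmatched FRs/CDRs.  An alternative
`mask` policy keeps such records and excludes masked positions from all
composition statistics; how rare nonstandard residues were treated in
the original data curation is not documented anywhere we know of, so
`strict` is a package choice, not an inherited rule.

## Property scales

Five published per-residue scales are bundled (in AAIndex1 format, read
by the package's own parser): Eisenberg's normalized consensus
hydrophobicity (`HNC`), the Bull–Breese transfer free energy to surface
(`BULH740101`, kcal/mol), the Chou–Fasman β-sheet conformational
parameter (`CHOP780202`), the TOP-IDP intrinsic disorder propensity
(`TOPIDP`), and the Charton charge-transfer capability parameter
(`CHAM830107`).  The bundled values were transcribed from the published
tables.  `CHAM830107` is stored as the 0/1 indicator of the residues
bearing a charge-transfer accepting group (–COOH/–CONH2: D, E, N, Q);
users who prefer a verbatim AAIndex dump can load one with
`load_aaindex` and register it over the fixture.  Any AAIndex1 flat file
can extend the registry to the full 70-scale panel; entries with `NA`
values are rejected with a warning rather than silently imputed.

Residue categories are fixed sets: gatekeepers {D,E,R,K,P}, non-polar
{A,G,I,L,M,P,V}, charge-transfer acceptors {D,E,N,Q}, aromatic {F,W,Y},
charged {D,E,K,R} and uncharged-polar {C,H,N,Q,S,T,Y}.  Histidine is
excluded from `charged` and `aromatic` by default; the sets live in one
table (`vlamy.scales.CATEGORIES`) so a different convention is a
one-line change.

## Feature engine

Every feature is either the arithmetic mean of a scale over a region
(`F_avg = Σ F_i / N`) or a category fraction.  "CDR" features pool all
CDR residues into one string before averaging, i.e. longer loops carry
proportionally more weight; this is the simplest reading consistent with
feeding a single CDR feature to the classifier.  The alternative —
averaging the three per-CDR means — is available via
`FeatureConfig(cdr_pooling="mean_of_means")` and matters only when loop
lengths differ.  The gatekeeper feature is stored as a fraction in
[0, 1] and rendered as a percentage in reports.

The extended panel adds every registered scale × {V_L, pooled CDRs,
pooled FRs}, every category fraction over the same three region sets,
and the composition-style extras: aromaticity (fraction of F/W/Y) and a
symmetric-charge term defined here as `(n_pos − n_neg)² / len²` with
n_pos = #{K,R}, n_neg = #{D,E}.  No published formula exists for the
latter in the lineage this feature comes from; the definition is a local
convention isolated in one function so it can be swapped.

## Disorder

The built-in disorder provider smooths the TOP-IDP propensity scale over
an 11-residue window centred on each position, truncated at the termini;
smoothed values therefore never leave the raw scale's range.  This is a
propensity profile, not an energy-based disorder probability — it is a
deliberately simple, dependency-free provider, and results derived from
a specific external disorder predictor are reproduced by importing that
predictor's per-residue scores (`id  position  score` TSV, positions
1..N checked for gaps and duplicates) instead.  The window length (11)
is a conventional smoothing width for per-residue profiles; with an
imported profile the V_L disorder feature is exactly the file's mean.

## Rule classifier

The learner is a separate-and-conquer rule inducer over partial
C4.5-style trees:

1. On the not-yet-covered instances, grow a partial tree: candidate
   splits are all (feature, midpoint-between-consecutive-distinct-values)
   pairs; candidates whose information gain falls below the mean gain of
   all candidates are screened out; the admissible candidate with the
   highest gain ratio wins, ties broken toward the lower feature index
   and then the lower threshold.
2. Nodes are expanded best-first by class entropy (ties by creation
   order).  A node is terminal when pure, smaller than `min_leaf`
   (default 2, interpreted as a node-expansion floor, not a per-branch
   minimum), or unsplittable; the first terminal node reached becomes
   the extracted rule, with its class counts.
3. Remove the covered instances and repeat.  A terminal with no
   conditions (the remainder is pure or unsplittable) becomes the
   default; single-class inputs yield a rule-free model.

No pruning is applied at any point.  The training loop is fully
deterministic given the data and recorded parameters; models serialize
to human-readable JSON (ordered rules with leaf counts) and round-trip
exactly, so a trained model is as inspectable as the rule list printed
in the README.

Probabilities are Laplace-smoothed leaf frequencies,
`(n_pos + 1)/(n_covered + 2)`, chosen because rule-learner
implementations rarely define their probability output precisely and
Laplace smoothing keeps empty or tiny leaves away from 0/1.  The
decision threshold is fixed at 0.15 with ties called positive; the low
threshold is the imbalance-handling mechanism (no instance weighting is
used).  A data-driven sweep (`max_balanced_accuracy` / `max_youden`,
ties toward the smaller threshold to favor sensitivity) is available but
off by default, because the provenance of the conventional 0.15 value
is a manual optimization whose exact criterion is not recorded.

This module re-implements the algorithm family, not any particular
toolkit bit-for-bit; agreement is enforced instead against an in-repo
exhaustive gain-ratio search oracle on small instances.

## Evaluation

Accuracy, sensitivity and specificity are the three confusion-table
ratios with the amyloidogenic class positive; an undefined ratio (empty
class) is flagged as `None`, never silently zero.  ROC curves come from
a full threshold sweep with one step per distinct score; AUC is the
trapezoidal area, which equals the Mann–Whitney pair-ordering
probability with ties counted half (asserted against a brute-force
pairwise oracle in the tests).  Protocols: self-consistency, LOOCV,
stratified k-fold (k = 10 default) and repeated stratified 90/10
subsampling without replacement per iteration, aggregated as
mean ± sd.  Stratification is used everywhere because the resampling
design samples per class; the fixed 0.15 threshold is applied to every
split and the model is retrained per split.  Feature ablation retrains
under the same protocol and seed with each feature removed, and with
each feature alone.  Percentages are reported to one decimal.

## Conservation

Per-column Shannon entropy uses log base 2 (bits; configurable) over the
20 standard residues, with gaps excluded from the distribution and
reported separately as occupancy — the convention that lets a gappy
column read as "low occupancy" rather than as artificially high entropy.
An all-gap column has undefined entropy (NaN, occupancy 0).  Consensus
is the modal non-gap residue, ties broken alphabetically, with a gap
emitted below a configurable occupancy floor (default: only all-gap
columns).  The entropy computation was checked against the standard R
alignment-analysis package on gap-free columns, where the two gap
conventions coincide.  Alignments are consumed as aligned FASTA; no
alignment is computed.

## APR flank analysis

Aggregation-prone-region intervals come from any external predictor as a
BED-like TSV (1-based inclusive, like everything else here); no
propensity algorithm is reimplemented.  Gatekeepers are counted in the
±k flanks (k = 3 default), truncated — not discarded — at sequence
termini, and an APR is "protected" when at least one gatekeeper occurs
in the union of both flanks.  The region map assigns each APR its
overlapped segments with residue counts; per-APR overlaps always sum to
the APR length.

## Synthetic data generator

The generator emulates the study conditions end to end: seven-segment
sequences with IMGT-like length ranges (FR1 23–26, CDR1 5–12, FR2 17,
CDR2 3, FR3 36–39, CDR3 8–13, FR4 10–11), residues drawn from
region-specific categorical distributions.  Base composition is uniform
over the 20 residues in CDRs; in FRs the five gatekeepers carry 0.25
total mass (0.05 each) so depletion has headroom.  These are documented
generator constants, not biological claims.

Positive-class distributions are exponentially tilted:
`w(a) ∝ base(a) · exp(delta_hyd·H_nc(a) + delta_dis·TOPIDP(a))` in CDRs
and, in FRs, the disorder tilt redistributes mass only *within* the
gatekeeper and non-gatekeeper groups while the total gatekeeper mass is
fixed at `0.25 · exp(−delta_gk)`.  The group-structured FR tilt exists
because disorder propensity intrinsically favors charged residues and
proline — the gatekeepers themselves — and a naive joint tilt would
cancel the planted gatekeeper depletion; fixing the group mass keeps the
three planted effects orthogonal and interpretable in scale units.
All-zero deltas make the classes exactly exchangeable (the null model).
Defaults are the strong planted condition used by the end-to-end tests
(`delta_hyd = delta_dis = 1.5`, `delta_gk = 0.5`); the imbalanced
variant draws 19% positives, the prevalence in curated real light-chain
data.  Isotype labels (75% of positives λ, 45% of negatives) exist only
to exercise group-wise reporting.

What passing on synthetic data does and does not show: the generator
plants exactly the compositional effects the features measure, with
i.i.d. residues and no germline structure, somatic hypermutation,
position-specific conservation or real length/composition coupling.
End-to-end recovery (LOOCV AUC ≥ 0.9 at the strong condition, ≈ 0.5 at
the null) therefore validates the plumbing — features measure what they
claim, the learner finds planted structure, the protocols leak nothing —
but says nothing about accuracy on real antibody repertoires, which
additionally depends on the disorder provider used and on the biology
the generator does not model.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline at
600 sequences (balanced 300+300 and imbalanced 19%), with 10-fold CV and
200 resampling iterations — sizes chosen so a complete run stays in the
minutes range on one CPU while keeping Monte-Carlo noise well inside the
asserted bands.  Numeric conventions: split midpoints guard against
floating-point rounding onto the right-hand value; gain-ratio ties use a
1e-12 tolerance; entropy uses 0·log 0 = 0; probabilities are written
with six decimals in prediction tables.  Known limitations: no
missing-value handling in the learner (inputs are complete by
construction), no pruning, no calibration of the Laplace probabilities,
and the built-in disorder profile is a propensity smoother, not a
predictor.
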