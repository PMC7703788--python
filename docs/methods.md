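# Methods

This note documents the models and procedures contactlens implements, the
defaults it ships, and the choices made where the conventions in the field
are genuinely open.

## Sequence weighting and Neff

An alignment is query-anchored: columns correspond to query positions, the
query is row 0 and carries no gaps. Reading aligned FASTA drops any column
where the query row holds a gap (an insertion relative to the query), which
is exactly what stripping lowercase states does for A3M; after either
normalization the two dialects yield the same in-memory object.

Pairwise identity between aligned rows is the number of columns where both
rows carry the same amino acid, divided by the number of columns where at
least one row is non-gap. Gap-versus-residue counts as a mismatch, so a
short fragment is *not* 100% identical to a full-length sequence it matches
locally — identity here measures redundancy, and a fragment does not make a
full row redundant. Gap-versus-gap columns are excluded from the
denominator. `X` (and any unrecognized character) matches nothing, not even
itself; `-` and `.` are both gaps; comparison is case-insensitive. An
alternative denominator — the full alignment width, i.e. coverage-normalized
identity — is available via `denominator="full_length"` for users whose
pipelines define identity that way; the union denominator is the default.

The pairwise weight is binary: 1 when identity ≥ 0.62, else 0. This is the
convention the Neff formula reduces to — `weight_i` is simply the number of
neighbors within the identity threshold, self included, so `weight_i ≥ 1`
and `1 ≤ Neff ≤ N` always hold. The 0.62 threshold is the standard
redundancy level for coevolution pipelines and is a parameter everywhere it
appears.

Domain-level Neff slices columns `[start, end]` from every row first. Rows
that are entirely gaps inside the segment are dropped: they contribute no
evolutionary signal in that region and would leave pairwise identity
undefined. The query row is always retained.

Weights are computed with a vectorized row-against-all comparison,
O(N²L) time but with the inner loop in numpy; the test suite checks it
against a literal double-loop recount.

## Coverage profiles and hard domains

The coverage profile counts, per column, the rows with a non-gap character.
The cutoff is the median of the counts; for even L the mean of the two
central order statistics (possibly non-integer, which is fine — only
comparisons use it).

A hard domain is a maximal run of consecutive positions with coverage
*strictly* below the cutoff, at least `min_len = 30` residues long. Strict
comparison means a flat profile yields no domains, and ties at the median do
not count as under-covered. No smoothing is applied. A `merge_gap` knob
(default 0, i.e. off) merges below-cutoff runs separated by at most that
many above-cutoff positions before the length filter, for profiles where
brief one-or-two-column excursions would otherwise split one under-covered
region in two.

`plan_domain_prediction` emits the work list downstream code consumes: the
full-length segment plus each hard segment, in ascending order. Hard
segments are non-overlapping by construction; the complement of the hard
segments needs no explicit entry because the full-length map covers it.

## Contact maps, merging, distance distributions

Contact maps are dense symmetric L×L probability matrices with zero
diagonal; the RR text format (both the 5-column `i j d1 d2 p` and 3-column
`i j p` dialects circulate) and plain square matrices are read and written,
with unlisted RR pairs defaulting to probability 0 — the convention that a
submission lists only its confident pairs. Round-trips are lossless to six
decimals.

Merging a domain map into a full-length map takes the elementwise maximum
over the domain block and leaves everything else untouched. Consequences
worth stating: merging never decreases an entry, is idempotent, and commutes
across disjoint segments; a one-residue overlap between reported domain
boundaries is immaterial under max.

A native contact is a pair with Cβ–Cβ distance strictly below the threshold
(8.0 Å default); when building distance matrices from coordinates the
caller supplies Cα in the Cβ slot for glycine, the CASP convention. Missing
distances are NaN and mark the pair unassessable.

Per-threshold maps at (6, 7.5, 8, 8.5, 10) Å sample a per-pair CDF. Because
the five predictions are made independently, nothing forces monotonicity;
`monotone_project` applies the running maximum across increasing thresholds —
the smallest pointwise correction yielding a valid CDF, and idempotent.
`interval_distribution` then takes successive differences plus the
`1 − P(d < 10)` tail, giving six non-negative masses per pair that sum to 1
and cumulative-sum back to the CDF exactly. Whether a second-stage predictor
should consume raw or projected stacks is left to the caller: both are
exposed, and `interval_distribution` refuses non-monotone input rather than
silently clipping.

## Evaluation conventions

Separation bands are short 6–11, medium 12–23, long ≥ 24; band membership
uses `|i − j|` on the original chain indexing. Domain-restricted evaluation
takes the submatrix over the segment — since both residues of an assessed
pair shift by the same offset, separations and hence band membership are
unchanged, which is the point of the convention.

Ranking is by probability descending with a fully deterministic tie-break
(separation descending, then (i, j) ascending). Top-k precision uses
`k = floor(L · fraction)`, minimum 1. Only pairs the predictor actually
asserted — probability > 0 — are assessed, so the denominator is
`min(k, #predicted)`; this is the assessor convention under which a
prediction identical to the native binary map scores 100% at every fraction,
and it is what makes top-2L precision meaningful for sparse maps. A
`include_zero_prob=True` escape hatch ranks the whole band instead, where
the deterministic tie-break alone fixes the list. Unassessable pairs
(missing native distance) are skipped and replaced by the next-ranked pairs,
not counted as wrong.

Coverage is `100 · TP / N` with N the number of native contacts in the band,
non-decreasing in k. AUC is computed over *all* assessable pairs in the band
with the mid-rank tie convention (delegated to scikit-learn's
`roc_auc_score`; the test suite checks it against a directly coded
Mann–Whitney rank statistic). Mean false-positive distance averages the
native distances of the non-contacts among the top-k predicted pairs; its
default k is floor(L/5), exposed as a parameter since different studies cut
at different depths. The one-per-residue filter is a greedy scan of the
ranked list keeping a pair only when neither residue was kept before — a
de-redundancy device for top-k lists that pile into one contact cluster.

## Architecture arithmetic and the two-stage flow

For stride-1 stacks of odd k×k kernels the receptive field side is
`1 + n·(k − 1)`; the tests verify this against explicit dependency tracing
through an n-layer convolution cascade. Even kernels are rejected (no center
cell). `compose_stages` adds layer counts. The default two-stage topology —
five threshold-specific networks of 7 layers each feeding one final
network — accounts its total receptive field with 13 effective layers
(12 increments of 4), giving 53; the plain 7 + 7 composition would give 14
layers and 57, and both conventions are available because published
accountings differ on whether the hand-off layer is double-counted.

`run_two_stage` is deliberately training-free: the five stage-1 predictors
and the stage-2 predictor are injected callables with a map-in/map-out
contract (correct shape, probabilities in [0, 1]). The orchestrator
symmetrizes each output as `(M + Mᵀ)/2`, zeroes the diagonal, and packages
stage 1 into a `ThresholdStack` that stage 2 receives together with the
original features. Violations of the contract raise immediately rather than
being clipped, so a misbehaving predictor is caught at the boundary.

## Synthetic data

`gen_msa` builds alignments from redundancy blocks (size, per-position
mutation rate). Blocks draw from disjoint slices of the amino-acid alphabet,
so rows of different blocks share zero identity by construction; with
mutation rate 0 a recipe of B blocks therefore has Neff = B exactly, a
closed form the acceptance checks use. The query is the unmutated base
sequence of the first block. Coverage dips gap the stated fraction of
non-query rows over the stated interval, carving a trough the domain parser
should recover. Default study conditions used by the tests and the
acceptance script: L = 150, one 60-row block at mutation rate 0.3, one
planted dip of 30–60 residues gapping 80% of rows — deep enough that the
median cutoff sits at full coverage and the dip is unambiguous, the regime
the parser is designed for.

`gen_chain` produces toy 3D chains: an ideal α-helical spiral (2.3 Å
radius, 100° twist, 1.5 Å rise — constant consecutive distances), or a
self-avoiding random walk with 3.8 Å steps and a 3.6 Å clash radius,
confined to a sphere of radius `3.5·L^(1/3)` Å so the chain collapses into
a compact globule at roughly constant packing density. Confinement matters:
an unconfined walk is too extended to form contacts at separation ≥ 24, and
long-range contacts are precisely what the evaluation machinery targets.
Chains of L = 40–60 give tens of long-range contacts in a few milliseconds.

`gen_predictions` emulates a predictor of tunable quality:
`clip(tp_signal · truth + N(0, noise_sd), 0, 1)`, noise drawn on the upper
triangle and mirrored. `tp_signal = 1, noise = 0` reproduces the truth;
`tp_signal = 0` gives label-independent scores with AUC ≈ 0.5.

What the generators do **not** emulate: real evolutionary processes (no
phylogeny, no substitution matrices, no correlated mutations between
contacting columns — so coevolution signal itself cannot be tested here),
real protein geometry beyond compactness (no secondary-structure contact
patterns, no beta-sheet stripes), and realistic predictor error structure
(noise is i.i.d. Gaussian, whereas real predictors err in clusters). Tests
passing on these fixtures validate the *bookkeeping* — weighting, parsing,
merging, ranking, scoring — not the biological performance of any predictor.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is a pure function of
its recipe; there is no global random state. The test suite and the
acceptance script run on small instances chosen to exercise the mathematics
rather than to benchmark: random MSAs up to N = 50 × L = 100 for the
weighting oracle, 500 random profiles up to L = 500 for the parser oracle,
chains of L = 40–60 for evaluation, 200-seed Monte-Carlo loops for the
AUC ≈ 0.5 and precision-equals-density baselines (3-standard-error
assertions). The whole suite completes in well under a minute on one CPU.

## Known limitations

- Sequence weighting is exact O(N²L); alignments of 10⁵ rows would need the
  usual subsampling or MinHash-style approximations, which are out of scope.
- The RR reader requires L up front (the format does not carry it).
- `parse_hard_domains` reports maximal strict runs; the `merge_gap` knob is
  the only tolerance mechanism, and choosing it is left to the user.
- Precision of an all-zero prediction is undefined under the
  only-predicted-pairs convention (returned as `None`); use
  `include_zero_prob=True` when a fully-ranked-band reading is wanted.
- No training, no feature extraction, no 3D model building: the two-stage
  orchestrator moves maps, it does not learn them.
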