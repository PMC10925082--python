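# Methods

This note documents the models and procedures implemented in `rkit`, the
assumptions behind them, and the choices made where the underlying
conventions are genuinely open.

## Reactivity pipeline

Chemical probing with SHAPE-type (2A3) or DMS reagents modifies nucleotides
that are not sequestered into base pairs; mutational profiling reads those
adducts out as mutations and deletions during reverse transcription.  The
pipeline in `rkit.reactivity` goes from per-position event counts to
normalized profiles in five steps.

1. **Deletion redistribution.**  A deletion inside a homopolymer run cannot
   be assigned to a position by alignment; within each maximal run of
   identical nucleotides the run's deletion total is redistributed in
   proportion to the (unambiguous) per-position mutation counts.  When a run
   carries no mutation signal at all, proportionality is undefined and the
   total is split uniformly — the maximum-entropy fallback.  Per-run totals
   are conserved to 1e-9.
2. **Rates and errors.**  `rate = (mutations + deletions) / coverage`, with
   a counting-statistics error `sqrt(events + 1) / coverage`.  The +1
   pseudocount keeps errors strictly positive at zero-event positions, which
   matters downstream because the signal-to-noise estimate divides by the
   mean error.  Zero-coverage positions become missing (NaN), never an
   exception.
3. **Background subtraction.**  The no-modification control rate is
   subtracted and errors are propagated in quadrature
   (`e = sqrt(e_mod^2 + e_ctrl^2)`).  Negative subtracted reactivities are
   retained — the public training data contain them, and clipping happens
   only inside the MAE metric.
4. **Normalization.**  One scale factor — the 90th percentile (linear
   interpolation) of all non-missing reactivities pooled over the whole
   collection — divides both reactivities and errors.  Normalization is per
   collection (library); callers choose whether to pool libraries.  An
   optional exclusion mask removes 3' barcode-hairpin positions *before*
   the percentile is taken, and masked positions are written as missing.
5. **Quality metrics.**  The profile signal-to-noise is the mean reactivity
   over the mean error at positions with nonzero reactivity, trimming the
   first and last such positions when at least four exist (end positions
   sit next to primer-masked regions and are unreliable).  Negative values
   count as "nonzero"; because the ratio can come out negative after
   subtraction while the quantity is defined as a nonnegative quality
   score, it is floored at 0.  The boolean quality flag requires
   signal-to-noise > 1.00 **and** reads > 100, both strict.

Mutate-and-map (M²) utilities: column-wise Z-scores use the population
standard deviation over non-missing entries (zero-variance columns map to
zeros), and row averaging groups profiles by mutated position, ignoring
missing values elementwise.

## Structures and decoding

Structures are sets of 0-based pairs; crossing pairs (i < m < j < n) are
first-class, which is what distinguishes pseudoknot-aware evaluation from
the classic nested-only conventions.  Dot-bracket I/O supports 30 bracket
levels; the writer assigns each pair greedily to the first level where it
crosses nothing, which round-trips with the parser on all generator output
(property-tested on 1000 random pseudoknotted structures).

Two decoders turn a symmetric pair-score/probability matrix into a
structure:

- **Assignment ("Hungarian") decoding** solves a maximum-total-score linear
  assignment (`scipy.optimize.linear_sum_assignment`) with per-position
  unpaired weights on the diagonal, defaulting to `1 - row max` clipped to
  [0, 1] (interpreting scores as pairing probabilities).  Pairs are kept
  only when the assignment is mutual, the score is at least 0.5, and
  |i - j| >= 4 (hairpin loops of length 0-2 are sterically impossible).
  Lone pairs are retained — they carry tertiary-structure signal.  The
  assignment is solved on the symmetrized matrix and maximizes score; the
  mutual-assignment pruning guarantees a valid pairing even if the optimal
  permutation contains longer cycles.
- **ThreshKnot decoding** emits pairs that are mutual row maxima above a
  threshold (default 0.3, the value conventional for this rule), resolving
  residual conflicts by descending score with smaller-index tie-breaks.

## Scoring

- **Classic data-fit score** (0-100): the percentage of non-missing
  nucleotides whose reactivity is consistent with a candidate structure —
  paired positions need reactivity < 0.5, unpaired > 0.125, strictly.
  Masked/missing positions are excluded from numerator and denominator.
- **OpenKnot score** (0-100) estimates whether the structure that best fits
  the data is pseudoknotted.  All candidates within 5 classic-score units
  of the best fit enter the best-fit set; each contributes the mean of its
  classic score and a pseudoknot subscore (the classic rule restricted to
  nucleotides in crossed pairs, which are all paired, hence reactivity
  < 0.5).  Crossing-free candidates get subscore 0 — a deliberately
  punitive convention, since a crossing-free best fit is evidence against a
  pseudoknot.  Ties at the top all enter the best-fit set.
- **F1 / crossed-pair F1.**  Exact-pair precision, recall and F1; empty
  prediction vs nonempty reference gives 0, two empty structures give 1.
  The crossed-pair variant filters both pair lists to crossed pairs first;
  it is *undefined* (excluded from aggregates) when both structures are
  crossing-free, and 0 when exactly one of them has crossings.
  A per-cluster aggregation helper supports similarity-clustered test-set
  summaries.
- **Clipped MAE** clips predictions and data to [0, 1] before averaging
  absolute differences — reactivity beyond that range is dominated by
  normalization noise.  **MCRMSE** is the unweighted mean of per-channel
  RMSEs over non-missing positions.
- **Confidence (eF1) relations.**  Linear maps from the mean predicted pair
  score over the decoded structure to an estimated F1:
  `eF1 = 2.25 <M>_ss - 1.29` and `eF1,crossed = 2 <M>_crossed - 1.19`,
  clipped to [0, 1] because an F1 estimate outside that range is
  meaningless.  The coefficients are fixed constants of the method;
  refitting them requires held-out validation data and is out of scope.
- **Scaling law.**  `MAE = a + b * N^-c`, fitted by bounded nonlinear least
  squares (`scipy.optimize.curve_fit`, c >= 0).  Constant inputs return the
  degenerate fit (a = mean, b = c = 0); non-convergence is reported as a
  failure status rather than an exception.

## Library design

Constructs are `flank5 + insert + pad + barcode + flank3` with the constant
priming flanks `GGGAACGACUCGAGUAGAGUCGAAAA` (a GAGUA-capped hairpin) and
`AAAAGAAACAACAACAACAAC`.  Barcodes are stem-loops `stem + UUCG +
reverse-complement(stem)` drawn by seeded rejection sampling under a
minimum mutual Levenshtein distance (default 2, computed with edlib);
infeasible requests fail loudly with the number of barcodes placed.  Pads
are unstructured A/C-rich below 8 nt, a single UUCG stem-loop up to 30 nt,
and chained stem-loops beyond — structured pads fold on themselves instead
of pairing with the insert.  Candidate pads are ranked by a pluggable
pairing-propensity oracle; the default counts reverse-complementary matches
of length >= 6 between pad and context, a dependency-free stand-in for an
ensemble base-pair-probability model, and any callable with the same
signature can replace it.

## Dropout baselines

Read counts across a library span orders of magnitude and are approximately
log-normal; homopolymer repeats (synthesis failure) and long stable helices
(reverse-transcription blocks) depress them.  Features: longest homopolymer
run (with a longest-repeated-substring alternative behind a separate
function, since "repeat" is ambiguous) and longest helix in base pairs
(maximal run of stacked pairs).  Reads are rescaled so the library mean is
1000 (the nominal per-sequence read budget), the loss is the MSE of natural
log reads with a +1 stabilizer so zero-read dropouts stay finite, and the
per-bin estimator shrinks each feature bin's mean toward the global mean
with pseudo-count strength k (default 10): `(n * bin_mean + k * global) /
(n + k)`.  Unseen bins predict the global mean.  Natural vs base-10 log is
immaterial to ranking — the loss rescales by a constant.

## The pair-track network

`rkit.nn` implements a compact two-track architecture on a self-contained
numpy reverse-mode autodiff core (`rkit/nn/autodiff.py`): one-hot
nucleotides are embedded into a sequence track; a pair track is spawned
from projected outer products of a low-rank ("downsampled") sequence
representation — the rank is a config knob (`downsample_rank`, default 4) —
plus a relative-position embedding shared by all offsets clipped at ±8.
Each block applies, in order: 1D convolution (residual, ReLU), multi-head
self-attention whose logits are biased by a per-head projection of the pair
track (pair → sequence information flow), an outer-product-mean update of
the pair track (sequence → pair), and triangular multiplicative updates in
the outgoing and incoming directions with sigmoid gating, the standard
gating for this module family.  Convolution precedes attention, and each
block carries one outer-product-mean and one triangular pair per direction;
both orderings and multiplicities are open in the wider literature and
these were fixed for simplicity.  Heads: per-position channels (2A3/DMS
reactivity, or multi-channel degradation), a scalar dropout head (dense
layer, mean over positions, exponential — hence strictly positive), and a
pairwise secondary-structure head whose logits are symmetrized before loss
and decoding.

The structure loss is elementwise binary cross entropy against the 0/1
connectivity matrix with positive cells up-weighted by 2 (positives are
sparse) and, optionally, a per-sequence factor of L² reflecting the
information content of long structures.

**Training demos.**  `train_overfit_demo` exists to show the architecture
learns, not to produce reusable weights: plain Adam, cosine-annealed
learning rate (the clipped-MAE objective has constant-magnitude gradients,
so without annealing Adam plateaus at a floor set by the step size),
minibatches of 10, straight-through gradients through the [0, 1] clip.
Optional 3'-5' flip augmentation doubles the training set with reversed
sequence/label copies; it measurably improves the network's
flip-equivariance on held-out sequences.  Checkpoints serialize the config
and weights to `.npz`.  Training is deterministic given the config seed on
one thread.  Desk-scale
limits (<= 200 sequences, <= 60 nt) are enforced.  The demo problem sizes —
50 profiles of length 40, 300 epochs for the reactivity head — fit the
demonstration purpose; larger models and datasets require GPU-scale
training, which this package deliberately does not attempt.  Pseudo-label
distillation is represented by nothing more than this documented omission.

## Synthetic data

`rkit.simulate` emulates the statistical structure of large-scale chemical
mapping, not its biochemistry:

- **Structures**: recursive placement of nested helices (3-6 bp) with
  hairpin loops >= 3 nt, so every pair has |i - j| >= 4; with probability
  `pk_prob` a hairpin loop is paired to a downstream unpaired run, creating
  an H-type pseudoknot (crossed pairs guaranteed when requested, with a
  deterministic fallback construction if random placement fails).
- **Reactivities**: gamma draws with mean 0.1 at paired and 0.7 at unpaired
  positions — the separation that makes probing informative.
- **Counts**: modified-channel events ~ Binomial(reads, 0.005 + 0.05 x
  reactivity), control events ~ Binomial(reads, 0.005); the shared
  background makes subtraction unbiased.  20% of events are recorded as
  deletions to exercise the redistribution step.  At 5000 reads the
  pipeline-recovered profile correlates with the generating reactivity at
  r > 0.9.
- **M² matrices**: each mutant row boosts reactivity at the mutated site
  and its pairing partner by 0.5, the signature that column Z-scoring makes
  visible.
- **Reads**: log-normal with mu = log(1000), sigma = 0.8, depressed by 0.15
  per repeat unit and 0.05 per hairpin base pair — effect sizes chosen to
  make dropout detectable but not trivial.

What the generator does *not* emulate: sequence-dependent probe biases,
alignment artifacts, replicate structure, ligand-dependent conformational
switching, or real synthesis chemistry.  Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms on
data with the asserted statistical shape, not performance on real
libraries.

## Numerical conventions

Missing values are NaN in memory and empty cells in CSV.  Percentiles use
linear interpolation.  Z-scores use the population (ddof = 0) standard
deviation.  Strict inequalities everywhere a threshold is printed (quality
flag, classic-score thresholds, decode threshold uses >=0.5 to mirror
"values lower than 0.5 were ignored").  Ties in ThreshKnot conflict
resolution break by smaller i then smaller j; ties at the top of the
OpenKnot candidate ranking all enter the best-fit set.  The minimum pair
separation (4 nt) is a parameter wherever community conventions differ.
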