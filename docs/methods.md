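# Methods

## The alignment model

The pipeline treats ontology alignment as nearest-neighbour search in
an embedding space.  Two corpora are encoded with the same sentence
encoder: the lexicon side contributes the concatenation of each term
with its public explanation (joined by a single space; the separator is
a reader option), and the ontology side contributes the surface string
of each atom.  Texts are encoded in batches of B (default 10), each
text mean-pooled over the sequence into one row of an embedding matrix;
the dense cosine matrix between the two stacks is computed in a single
pass, and each lexicon row is mapped to the ontology row with maximal
cosine.  The mapping is many-to-one by construction — each source row
is resolved independently, with no global assignment — and the cosine
at the argmax is read as the mapping value, the score of equivalence
between the two entries.

The dense formulation is deliberately the naive O(n²) one: at the
scales this package targets it is exact, fast enough, and directly
comparable against a brute-force scan, which the tests do.

## The encoder

The encoder is a deterministic stand-in for the large pretrained
transformers used in production alignment systems, which are outside
this package's scope.  It keeps every contract the pipeline relies on
while staying small enough to verify numerically:

- a deterministic tokenizer: normalize, whitespace-split, stable
  64-bit hash (BLAKE2b) of each token modulo the vocabulary; layout
  `[CLS] tokens [SEP]` (or `[CLS] A [SEP] B [SEP]` for pairs), truncated
  to `max_len` and padded;
- token embeddings plus a fixed sinusoidal positional signal;
- `n_layers` positionwise blocks of matmul → bias-add → relu (the final
  block omits the relu) — exactly the operator set the quantized
  execution path supports;
- mean pooling over the full padded length by default, with a
  mask-aware mean available as a config flag.  With positionwise layers
  the padding positions contribute a component that is identical for
  texts of equal length, so the full-length mean preserves the argmax
  structure while staying faithful to the batch-level formulation.

There is no cross-token attention; alignment behaviour is driven by
token content through the pooling step, which is sufficient to exercise
every quantization and alignment contract.

Weights draw from a seeded standard normal scaled by 1/√fan-in (biases
at 0.1 standard deviations), keeping activations O(1) so the int8 grid
is used meaningfully.  Forward passes run one sequence at a time, so
embeddings are bit-identical under any batch partition; two encoders
built from the same config are bit-identical across runs.

Default desk-scale dimensions (`small_config`): vocabulary 2048,
embedding and hidden width 256, 2 layers, sequence length 16.  The
width is chosen so that the quantized weight payload — int8 grids plus
one float32 scale per output channel and one float32 smoothing value
per input channel, i.e. a fraction ≈ 0.25 + 4/d + 4/H of the float32
payload — sits clearly below 30%.  The sequence length covers the
synthetic texts (≤ 11 tokens plus specials) without letting padding
dominate the full-length mean.  `EncoderConfig` itself defaults to
`max_len = 512`, the budget typical of the encoders this one stands in
for.

## Quantization (W8A8)

Symmetric signed int8 on the grid [−127, 127] with zero-point 0: the
symmetric range keeps negation exact and every tensor needs only scale
parameters.  Rounding is half-to-even (unbiased, platform-stable);
values are clamped to the grid after rounding.  An all-zero tensor
receives a floor scale ε = 1e−12 so dequantization stays well-defined.

- **Weights** are quantized per-channel along the output-column axis
  (one scale per column, `maxabs/127`), or per-tensor when requested.
- **Activations** are quantized dynamically per-tensor, one scale per
  individual sequence per forward call.  Per-sequence (rather than
  per-batch) scales are what make the quantized path batch-size
  invariant; calibration statistics are never used for activation
  ranges.
- **Linear layers** accumulate in int64 (exact for these sizes — the
  products are bounded by 127² per term) and rescale by the product of
  the operand scales.  Bias-add and relu follow dequantize-then-apply
  semantics.
- A per-channel-quantized **activation** operand, or weights quantized
  per-channel along the contraction axis, put scales inside the
  accumulation where they cannot be factored out; the operators reject
  the combination as non-dequantizable rather than silently
  approximating it.

### Smoothing

Activation outliers — a few input channels with much larger magnitude
than the rest — stretch the per-tensor activation scale and waste grid
resolution.  The smoothing transform migrates that difficulty into the
weights: with per-input-channel calibration maxima `maxabs(X_j)` and
weight-row maxima `maxabs(W_j)`,

    s_j = max(maxabs(X_j), ε)^α / max(maxabs(W_j), ε)^(1−α)

and the layer is rewritten `X′ = X · diag(s)⁻¹`, `W′ = diag(s) · W`,
which leaves `XW` mathematically unchanged.  α ∈ [0, 1] balances the
migration (α = 1: all burden stays on activations' normalization;
α = 0: all on weights); the default is α = 0.5.  The ε floor (1e−8)
guards channels that are zero in calibration.  The closed form follows
the SmoothQuant family of post-training methods.

Calibration runs the FP32 model over a representative text set and
records per-input-channel maxabs and variance for every linear layer.
Because the quantized model encodes both corpora, the calibration set
should contain both the lexicon concatenations and the ontology
strings; the search and acceptance drivers do exactly that.

## Postprocessing

- **Min–max rescaling** maps raw cosine scores affinely onto the 0–5
  annotation scale, fitted on the score vector being rescaled, per run.
  A constant vector maps entirely to the lower bound — with no
  similarity contrast there is no evidence for a high grade.
- **Complementarity merge** walks ratings 5 → 0; at each rating it
  admits the primary model's alignments for uncovered sources first,
  then the secondary model's.  The result covers exactly the union of
  source keys with at most one alignment per source, and primary
  rating-5 alignments survive verbatim.  Which model is primary is a
  caller/CLI choice; a `--min-rating` flag optionally drops low-rated
  rows after merging.
- **Configuration search** evaluates a finite candidate space
  exhaustively (the spaces here are tiny, so exhaustive search subsumes
  any sequential optimizer).  Quality is argmax agreement with the FP32
  alignment; cost is the serialized weight payload in bytes — a
  deterministic proxy for the latency/memory gains that motivate
  quantization, since wall-clock latency is hardware-dependent.
  Feasibility requires degradation ≤ 0.01% and size reduction ≥ 20%
  (both configurable); the report carries the full candidate list, the
  Pareto frontier (computed by a cost-ascending sweep, checked against
  pairwise dominance), and the best feasible frontier point (highest
  quality, ties to lowest cost).  An empty feasible set is reported,
  not raised.

## Evaluation metrics

- **EDRM**: predictions are clamped to [lo, hi] (default [0, 5]), then
  each pair contributes `1 − |h−r| / d_max(r)` with
  `d_max(r) = max(r − lo, hi − r)`, the largest distance any legal
  prediction can have from r.  If `d_max = 0` (only possible when
  lo = hi) the pair contributes 1 iff the prediction is exact.
  Clamping keeps the metric inside [0, 1] for arbitrary raw scores.
- **Triplet MAP**: targets are ranked by cosine to the source
  (descending, ties to the smaller index); with one correct answer per
  group, average precision is the reciprocal rank, and MAP its mean.
  The general multi-answer average precision is implemented for
  completeness but unused by the triplet task.
- **Spearman** is delegated to `scipy.stats.spearmanr` (average ranks
  for ties); constant vectors are rejected as undefined.  The test
  suite checks it against an independent rank-then-Pearson computation.

## Synthetic data

The generators emulate the *shape* of the real study inputs with
planted ground truth, no licensed resources, and full determinism per
seed (one named generator per call, no global state).

- **Aligned corpora**: each concept owns six base tokens (two feed the
  term, four the explanation); lexicon and ontology each emit
  `synonyms_per_side` variants (default 2) distinguished by an affix
  token, under one synthetic CUI per concept, so top-1 accuracy against
  the truth map is well-defined.  Every emitted base token is replaced
  by a pool token with probability `noise_rate` (default 0.1, pool
  size 100); the pool is disjoint from concept tokens, so noise
  degrades difficulty monotonically.  Defaults: 50 concepts.
- **Scored pairs**: an overlap fraction ρ ~ U(0, 1) per pair; the two
  ten-token sentences share ⌈10ρ⌉ tokens and the gold mark is
  round(5ρ), so the token-overlap signal is monotone in the annotation.
- **Triplets**: the correct target is the source with tokens dropped at
  the configured rate (at least one survives); distractors are other
  groups' sources and share no tokens; the correct position is
  randomized uniformly.

What the generators do **not** emulate: morphological and translational
variation, subword structure, polysemy and context-dependence,
cross-lingual noise, class imbalance, or annotator disagreement.
Passing tests show the pipeline's arithmetic, contracts and recovery
behaviour are correct under controlled conditions; they do not certify
performance on real lexicons or ontologies, which hinge on encoder
quality.

A note on near-ties: synonym variants of the same concept differ only
by an affix and by noise, so a lexicon row can sit almost exactly
between two ontology rows of the same CUI.  FP32/INT8 argmax
disagreements concentrate on such pairs (where the FP32 margin is below
int8 resolution) and are CUI-neutral: both choices carry the correct
concept.

## Problem sizes

The shipped studies use 10 corpus/encoder replicates of 100 lexicon ×
100 ontology rows for the alignment experiment, 200 scored pairs, and
100 triplet groups at 0.2 dropout — sizes chosen so the whole suite and
the acceptance run complete in well under a minute each while keeping
per-row counts large enough for stable proportions.

## Known limitations

- The encoder is positionwise; phenomena requiring cross-token
  interaction (word order beyond the positional signal, contextual
  disambiguation) are out of reach by design.
- Quantization is simulated in NumPy with genuine integer accumulation
  but no hardware kernels; latency is not measured, and the
  serialized-size proxy stands in for it.
- Activation quantization is dynamic per-tensor only; static ranges
  and finer activation granularities are not modeled.
- The min–max calibration is fit per score vector; no learned
  correction is modeled.
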