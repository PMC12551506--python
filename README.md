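# ontoquant

Aligning a layman biomedical vocabulary with a large ontology string
table means encoding every term+explanation text and every ontology
surface string into a shared embedding space, then mapping each lexicon
entry to the ontology row that maximizes cosine similarity.  At
ontology scale this is expensive, and the standard remedy is
post-training quantization of the encoder to 8-bit weights and
activations (W8A8) — which only works if the quantized model keeps
producing the *same* argmax alignments as the full-precision one.

`ontoquant` is a self-contained, desk-scale implementation of that
whole pipeline, built so every number is checkable:

- **io_formats** — readers/writers for the pipe-delimited RRF ontology
  dialect (MRCONSO-style, trailing delimiter), lexicon TSVs, gold
  evaluation files, rated-alignment TSVs and run configs, plus the text
  normalizer and the CUI left-join used for semantic enrichment.
- **encoder** — a small deterministic text encoder (hash tokenizer,
  [CLS]/[SEP]/[PAD] layout, positionwise matmul→add→relu layers, mean
  pooling) with interchangeable FP32 and quantized execution paths.
- **quantcore** — simulated symmetric int8 arithmetic: per-tensor and
  per-channel schemes, exact integer-accumulation linear operators,
  calibration statistics, and smoothing-factor redistribution of
  activation outliers into the weights
  (`s_j = maxabs(X_j)^α / maxabs(W_j)^(1−α)`, default α = 0.5, applied
  as `X′ = X · diag(s)⁻¹`, `W′ = diag(s) · W`, which leaves `XW`
  unchanged).
- **aligner** — the dense cosine matrix `S_ij = ⟨e_i, e_j⟩ / (‖e_i‖‖e_j‖)`
  and the row-wise argmax mapping `j*_i = argmax_j S_ij`.
- **postprocess** — min–max score calibration onto the 0–5 annotation
  scale, complementarity merging of two models' rated alignments in
  descending rating order, and a constraint-filtered Pareto search over
  quantization configurations (quality = argmax agreement with FP32,
  cost = serialized weight bytes).
- **evaluation** — EDRM (`mean(1 − |h−r| / max(r−lo, hi−r))`), triplet
  mean average precision, Spearman rank correlation, and rating
  distributions.
- **fixtures** — seeded synthetic generators for all inputs (aligned
  lexicon/ontology corpora with planted ground truth, scored sentence
  pairs, grouped triplets), so nothing external or licensed is needed.

## Worked example

```python
from ontoquant import (Encoder, SmoothingConfig, SynthConfig, align_corpora,
                       gen_aligned_corpora, per_channel, quantize_encoder,
                       small_config)

corpus = gen_aligned_corpora(SynthConfig(n_concepts=50, noise_rate=0.1, seed=1))
encoder = Encoder(small_config(seed=101))

fp32 = align_corpora(corpus.lexicon, corpus.ontology, encoder, batch_size=10)
calibration = ([e.concat_text for e in corpus.lexicon]
               + [r.str_text for r in corpus.ontology])
int8 = quantize_encoder(encoder, calibration, per_channel(axis=1),
                        SmoothingConfig(alpha=0.5))
w8a8 = align_corpora(corpus.lexicon, corpus.ontology, int8, batch_size=10)

accuracy = sum(corpus.ontology[a.target_index].cui == corpus.truth[i]
               for i, a in enumerate(fp32)) / len(fp32)
agreement = sum(a.target_index == b.target_index
                for a, b in zip(fp32, w8a8)) / len(fp32)
ratio = int8.weight_payload_bytes() / encoder.weight_payload_bytes()
print(f"FP32 top-1 accuracy:      {accuracy:.3f}")
print(f"W8A8 argmax agreement:    {agreement:.3f}")
print(f"quantized weight payload: {ratio:.1%} of FP32")
```

prints

```
FP32 top-1 accuracy:      1.000
W8A8 argmax agreement:    1.000
quantized weight payload: 25.8% of FP32
```

i.e. on this corpus every lexicon row maps to its planted concept, the
int8 model reproduces every FP32 argmax decision, and the serialized
weight payload shrinks to about a quarter (int8 grids plus per-channel
scale and smoothing vectors).

The same pipeline is available from the shell via the `ontoquant`
console script (`synth`, `model init`/`model quantize`, `align`,
`merge`, `search`, `eval`); see `ontoquant --help`.

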