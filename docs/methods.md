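# Methods

This note records the model, the simulator, the training objective, the
decoders and the evaluation metrics implemented by `squeezecall`, together
with the numerical conventions and the design choices that were genuinely
open.

## The basecalling problem

A nanopore sequencer reports an electrical current trace ("squiggle") as a
DNA strand translocates the pore. The current level at any instant is
dominated by the k-mer resident in the pore; each k-mer position persists
for a variable number of samples (its dwell). Basecalling inverts this
process: from a raw current trace, infer the base sequence. The package
implements a Squeezeformer-encoder basecaller trained with connectionist
temporal classification (CTC) plus auxiliary losses, decoded by prefix beam
search.

## Squiggle simulator

The simulator replaces the resquiggling step used with real reads: it
produces reads whose signal-to-base alignment is known exactly, which is
what the frame-level KL objective needs.

- **Pore model.** One mean level per k-mer, drawn from a seeded standard
  normal and re-standardized to mean 0, sd 1 across the 4^k table (units are
  arbitrary pA-like; the med-MAD normalization removes scale anyway).
  Tables above k = 6 are rejected as a size guard.
- **Dwell model.** Integer dwells drawn uniformly from [dwell_min,
  dwell_max] samples per k-mer position. Uniform dwell keeps the zero-noise
  oracle exact (signal length is the sum of dwells; every sample is a table
  lookup). Real dwell distributions are heavier-tailed; nothing downstream
  depends on the dwell law's shape.
- **Noise.** Per-sample i.i.d. Gaussian with sd `noise_sd`. Real pore noise
  is autocorrelated and state-dependent; this simulator deliberately leaves
  out stalls, skips, adapter signal and modified bases, so passing tests
  demonstrate correctness of the method's machinery, not performance on
  real nanopore data.
- **Alignment labels.** `base_index[i]` is the index of the central base of
  the k-mer active at sample `i` (position + k//2; for even k the
  right-of-centre base — any fixed offset convention works, this one is
  constant everywhere).
- **Default desk profile:** k = 1, noise_sd 0.1, dwell 5–10. With k = 1 the
  four levels are direct base codes and a tiny model learns in minutes; a
  k = 5 table is available for realism. Two intrinsic error sources remain
  even at k = 1: (i) homopolymer run lengths are only constrained by total
  duration (dwell is 5–10, so duration overlaps between neighbouring run
  lengths — the classic homopolymer problem), and (ii) a random 4-entry
  level table can contain two levels closer than the noise, making those
  bases confusable until the network learns to average over the dwell.

All randomness flows through explicit integer seeds; no global state.

## Normalization and chunking

Signals are normalized per read with the med-MAD transform
`(x − median) / (1.4826·MAD)` (MAD = 0 falls back to dividing by 1), the
robust standard in basecalling pipelines. Normalizing per read rather than
per chunk keeps levels identical across chunk boundaries. Reads are then
cut into non-overlapping fixed-length chunks (3,600 samples by default).
A base belongs to the chunk containing the midpoint of its dwell, so every
base is labelled exactly once; the trailing partial chunk is dropped for
training and zero-padded (with its true length recorded) for inference.
At inference the per-chunk basecalls of one read are concatenated in order;
there is no overlap-merge because chunks do not overlap.

## Encoder

- **Convolution front-end:** three 1-D conv layers with kernel/padding/
  stride 5/1/1, 5/1/1, 19/10/1 and output channels 4, 16, model_width,
  each followed by LayerNorm and GELU. With all strides 1 the frame rate
  equals the sample rate and a 3,600-sample chunk yields 3,598 frames
  (the per-layer length rule `floor((L + 2p − k)/s) + 1`). The final
  stride is configurable for users who want aggressive downsampling.
- **Time-step masking (training only):** `round(mask_time_prob · T)` start
  frames are sampled without replacement; from each start,
  `mask_time_length` consecutive frames are replaced by a single learned
  vector (initialized uniform on [0, 1)) shared by all masked positions.
  Defaults 0.05 and 5. Overlapping spans only lower the masked fraction,
  never raise it above prob·span. Feature-dimension masking is not
  implemented.
- **Temporal U-Net of 2N Squeezeformer blocks:** blocks 1..N−1 at the full
  frame rate; a depthwise conv with kernel 3, stride 2, padding 1 pools to
  ceil(T/2) frames; blocks N..2N−1 run at half rate; nearest-neighbour
  repetition (truncated to T) plus a pointwise linear projection restores
  the rate, a residual connection adds the pre-pooling states, and the last
  block runs at full rate. Each block is the FMCF stack — feed-forward,
  multi-head self-attention, convolution module, feed-forward — with every
  sublayer residual under post-layer-norm and 0.5 macaron scaling on both
  feed-forwards. The block convolution module is pointwise→GLU→depthwise→
  LayerNorm→Swish→pointwise (LayerNorm rather than BatchNorm so evaluation
  needs no running statistics).
- **Head:** one affine layer to 5 logits (A, C, G, T, blank — blank always
  last) followed by log-softmax. Intermediate taps (default: block N) each
  own a separate head of the same shape.
- **Unstated hyperparameters** fixed as: 8 attention heads (tiny: 4),
  feed-forward expansion 4 (tiny: 2), dropout 0.1 (tiny: 0), block conv
  kernel 31 (tiny: 9). All overridable in `EncoderConfig`. Attention uses
  absolute positions: a fixed sinusoidal positional encoding is added to
  the frames entering the U-Net (no relative-position terms inside the
  attention). Without it the attention sublayers are blind to position
  except through the convolutions, which measurably slows discrimination
  of close current levels.
- **Presets:** `M` (N = 4, width 512), `L` (N = 5, width 512), `tiny`
  (N = 2, width 64). The tiny preset is the desk-scale configuration used
  throughout the tests: at ~0.4 M parameters, dropout and wide
  feed-forwards only slow convergence, so it disables dropout and halves
  the feed-forward expansion; time masking remains on.

The whole network, including backpropagation and Adam, runs on a small
reverse-mode autodiff engine over NumPy arrays written for this package
(`_autograd.py`); model arithmetic is float32, loss lattices float64.

## Objective

`Loss = γ·L_CTC + β·L_inter + (1 − γ − β)·L_KL`, defaults γ = 0.3,
β = 0.35.

- **L_CTC** is the negative log-likelihood of the label under the final
  head's per-frame categorical distribution, summed over all
  blank-augmented alignments with the usual collapse-repeats convention,
  computed by the forward recursion in log space (float64). Labels that
  cannot fit in T frames (each repeated pair needs a separating blank)
  raise a dedicated `InfeasibleLabelError` rather than returning a silent
  number; the trainer filters such chunks up front. The analytic gradient
  with respect to the input log-probabilities is
  `−Σ_{s: symbol(s)=k} exp(α_t(s) + β_t(s) − log P)`, verified against
  central finite differences at 1e-4 relative error. A batched kernel runs
  one lattice sweep for a whole batch (right-padding the state dimension);
  it is numerically identical to the per-item path.
- **L_inter** averages the same CTC loss over tapped intermediate blocks,
  each projected by its own head (weights not shared with the final head,
  the standard intermediate-CTC arrangement). Default tap set: block N
  only.
- **L_KL** is the mean over labelled frames of
  `KL(label_smooth(y_t) ‖ p_t)` with smoothing factor 0.1 (on-class 0.9,
  off-class 0.025 each for 5 classes). The direction is fixed as target
  first — the standard label-smoothing regularizer — and pinned by a
  worked numeric test case, since the two directions differ on asymmetric
  inputs. Frame labels come from the simulator's exact alignment: each
  encoder frame is mapped back through the conv stack to its central
  sample (per-layer affine rule `c_in = s·c_out + (k−1)/2 − p`) and takes
  the majority base among the samples in its receptive stride (a single
  sample at stride 1). Frames marked unknown (−1, e.g. in zero-padding)
  are skipped and the normalizer shrinks. The gap-free simulator never
  produces blank frame labels, which keeps the term well defined.

## Training

Adam (β1 0.9, β2 0.999, eps 1e-8) with the learning rate warmed linearly
to its peak (default 0.0005 over 1,000 updates) and decayed linearly to
zero at `total_steps` (a required setting — no canonical value exists).
Gradients are clipped at global norm 5, standard for CTC stability.
Chunks are shuffled each epoch; 5% (seeded) are held out for validation;
training aborts if the loss goes non-finite. Runs are single-process and
bit-reproducible given the seed on one machine. Validation quality is the
median match rate of greedy-decoded chunks against their labels.

## Decoding

- **Greedy:** per-frame argmax, collapse repeats, drop blanks.
- **Prefix beam search** (default width 5): per surviving prefix, separate
  log masses for paths ending in blank and in the last symbol; extending a
  prefix by its own last symbol is only allowed from the blank-ending mass
  (the collapse rule). All arithmetic is log-space logsumexp — probability
  space underflows at thousands of frames. Tie-breaking everywhere: higher
  total mass, then shorter prefix, then lexicographic; with sufficient
  width the beam equals the exhaustive enumeration oracle exactly, which
  the tests exercise instance by instance.
- **Exhaustive oracle** (`exhaustive_best`): enumerates every label string
  up to T ≤ 8 frames and scores it with the exact forward algorithm; used
  only for testing.
- **Per-base qualities:** for each emitted base, the CTC forward/backward
  occupancy of its state is maximized over frames; quality =
  −10·log10(1 − p), clipped to [1, 40]. A documented heuristic — the
  upstream method defines none.

## Evaluation metrics

Reads are aligned to references by a unit-cost global edit-distance DP with
deterministic traceback (prefer match/mismatch, then deletion, then
insertion); a semiglobal mode with free reference flanks exists for clipped
reads. Orientation is relative to the reference: an extra read base is an
insertion, a missing one a deletion. Deletion, insertion and mismatch
rates divide their counts by the alignment length; the error rate is their
sum; the identity rate is matches over the basecalled read length (the
aligned-columns denominator was considered and rejected — the read-length
reading matches the metric's plain definition). Identity ≥ 1 − error is
*not* an identity: the two use different denominators, and a test documents
the counterexample.

Homopolymer accuracy considers maximal single-base runs of a given length
in the reference only; a run counts as correct iff the read segment the
traceback aligns to it (including insertions strictly inside the run)
reproduces the run exactly. Heteropolymer accuracy does the same for
maximal perfect tandem repeats of a 2-base unit, lengths counted in bases;
no published definition of "heteropolymer" exists for this metric, so the
tandem-repeat reading is this package's documented operational choice.
The chunk match rate is matches over alignment length per chunk, with the
median across chunks (even counts average the middle two).

## Desk-scale problem sizes

The test and acceptance workloads are sized for a single CPU core:

- Oracle equivalence checks use 100 random posteriorgrams with T ≤ 6
  frames and labels up to 3 bases (exhaustive enumeration is exact there).
- The parameter-recovery experiment simulates 200 reads of 900 bases from
  a k = 1 pore model (noise 0.1, dwell 5–10), chunks them at 192 samples,
  and trains the tiny preset for 1,250 steps (batch 8, peak LR 2e-3,
  warmup 100) — roughly 1.4 epochs. The 192-sample chunk (~26 bases, 190
  frames) keeps the attention quadratic small while leaving ~7 frames per
  base for CTC; the hotter peak than the full-scale 5e-4 suits the small
  model and short schedule. Success is a validation median chunk match
  rate ≥ 0.90, with 2 of 3 seeds required because a random k = 1 level
  table occasionally draws two levels closer than the noise floor, which
  depresses accuracy toward the threshold; residual errors sit almost
  entirely in homopolymer run lengths (deletions/insertions, not
  mismatches), as expected from the duration-overlap argument above.

## Known limitations

- The simulator's i.i.d. Gaussian noise and uniform dwell understate the
  difficulty of real squiggles; results on simulation do not forecast real
  error rates.
- The per-frame categorical head is the only output model; no CRF
  transition parameterization or Viterbi/transition decoding.
- Single-device training only; the published multi-GPU batch semantics are
  reproduced through the aggregate batch-size setting.
- Quality scores are a heuristic, not calibrated probabilities.
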