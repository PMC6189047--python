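# Methods

## Problem and model

Given a set of DNA sequences labeled bound / not bound by a transcription
factor, the package learns a sequence classifier in three stages.

**Tokenization.** A sequence of length *L* over {A,C,G,T,N} is split into
*N* = ⌊(*L* − *k*)/*s*⌋ + 1 windows of length *k* whose starts are *s*
bases apart (0-based, half-open windows; trailing bases that cannot fill a
window are dropped). With the default 101-bp sequences, *k* = 5 and
*s* = 2, every sequence yields exactly 49 tokens. The vocabulary indexes
k-mers by the positive integers 1..V; index 0 is reserved for padding and
out-of-vocabulary tokens. The default vocabulary mode (`full`) enumerates
all 4^k k-mers lexicographically for *k* ≤ 8, so no k-mer can be
out-of-vocabulary at prediction time; `observed` mode (frequency-ordered)
exists for larger *k*. Any window containing a non-ACGT base (e.g. N) maps
to index 0 rather than being dropped, which keeps the token-count formula
exact — the padding/masking logic of the classifier depends on it.

**k-mer embedding.** Treating each tokenized sequence as a sentence, a
word2vec model (CBOW by default, skip-gram available) with negative
sampling learns one *d*-dimensional vector per k-mer. The trainer is a
native NumPy implementation of the classic recipe: unigram^0.75 noise
distribution, per-position shrunken context windows, learning rate decayed
linearly from 0.025 to 1e-4 over the token stream, 5 negatives, window 5,
5 epochs. Two deliberate deviations from common word2vec defaults:
`min_count` is fixed at 1 (dropping rare k-mers would create embedding
holes for valid sequences) and the default *d* is 50, the smallest value of
the supported sensitivity range {50, 100, 150, 200}, to keep desk-scale
runtime low; both are configurable. Training is single-threaded and fully
seeded, so identical inputs reproduce the matrix element-wise. Row 0 of the
embedding matrix (padding/OOV) is pinned at zero and receives no updates.

**Classifier.** The embedded token sequence is read by a bidirectional GRU.
Each direction applies the standard update-gate / reset-gate recurrence
(states are convex combinations of the previous state and a tanh candidate,
so states started in [−1, 1] stay there). The final states of the two
directions are merged — concatenate (default), sum, average or
element-wise multiplication — and a dense layer plus logistic sigmoid
produces P(bound). The head consumes the *final* merged state by default;
a `mean_pool` variant averaging the per-step merged outputs over unmasked
steps is provided, as the "fixed-length feature vector" reading is
genuinely open. One bidirectional layer is the default; the layer count is
configurable (stacked layers consume the per-step merged outputs of the
layer below). Initial hidden states are zero. Weights are initialized with
Glorot-uniform input transforms, orthogonal recurrent transforms and zero
biases, all seeded. No dropout or other regularization is applied by
default.

Forward and backward passes are hand-written NumPy: the forward pass caches
gate activations, and backpropagation-through-time is implemented directly
on the recurrence. Gradient correctness is verified against central finite
differences in the test suite, and the vectorized step is checked against
an independent straight-line scalar implementation (this also pins down the
gate-ordering convention: the reset gate multiplies the previous state
*before* the recurrent matrix — variants that apply it after the matmul
would fail that oracle). Masked (padding) steps pass the hidden state
through unchanged in both passes, which makes right-padded batches exactly
— not approximately — equivalent to unpadded ones.

**Training.** The loss is the negative Bernoulli log-likelihood with
probabilities clipped to [1e-7, 1 − 1e-7]; reported `loss()` sums over
instances, while mini-batch gradients use the mean (a scale choice that
interacts only with the learning rate). Optimizers are SGD (lr 0.01), Adam
(0.001), Adagrad (0.01) and RMSprop (0.001) — the framework-conventional
defaults, recorded in every report. Mini-batch size defaults to 200. The
epoch budget (default 20) and early stopping (patience 5 on validation
AUC, with best-epoch weight restoration) are this package's protocol: a
validation-driven stop is implied by the train/validate workflow but no
schedule is fixed by it. Training aborts with the offending epoch if the
loss becomes non-finite.

**Evaluation and experiments.** AUC (rank probability, ties 0.5) and APS
(recall-weighted mean precision) are computed on raw sigmoid scores via
scikit-learn, and are validated against exhaustive pair-counting and exact
precision-recall step-sum oracles in the tests. The default
hyper-parameter grid is the 12-cell cross of units {50, 80, 100} with the
four optimizers; the best cell is the validation-AUC argmax with ties
broken by higher APS, then fewer units. The embedding ablation trains the
three strategies (`no_init`, `init_no_train`, `init_train`) with otherwise
identical seeds and configuration. Sensitivity sweeps over *k* ∈ {4,5,6},
*s* ∈ {2,3,4,5} and *d* ∈ {50,100,150,200} rebuild the corpus and
re-train the embedding whenever *k* or *s* change.

## Synthetic data

Real datasets for this task are 101-bp windows centred on ChIP-seq peaks
with negatives matched for length, GC content and repeat fraction. The
generator emulates that construction: positives are i.i.d. background
(uniform by default) with one motif instance sampled column-wise from a
PWM and planted at a uniformly random offset; the default motif is the
8-bp CRE/AP-1-like consensus TGACGTCA at full strength (16 bits), standing
in for a strongly bound TF. Negatives come in two modes:

- `composition_matched` (default): i.i.d. draws from the empirical
  mononucleotide frequencies of the positive set, matching GC content in
  expectation (verified within ±0.02 at n = 500);
- `dinucleotide_shuffle`: an Eulerian-walk shuffle of a sampled positive
  that preserves dinucleotide counts exactly, the stand-in for
  repeat-fraction matching (no repeat annotation exists without external
  data).

Either way, a candidate containing a ≥(W−1)-length match to the motif
consensus is rejected and redrawn (consensus-string matching rather than a
PWM-score threshold — simpler and fully deterministic), with an error after
1000 attempts advising a weaker motif. One motif instance per positive, no
reverse-complement planting (the classifier has no reverse-complement
mechanism). Default dataset size is 1000 + 1000 sequences with an
0.8/0.1/0.1 stratified train/validation/test split — the split proportions
are a package decision, as is stratification by label (it prevents
degenerate single-class validation sets at small n).

What the generator does **not** emulate: positional uncertainty of the
motif relative to the peak centre, multiple/cooperative motif instances,
flanking-sequence and shape preferences, true repeat structure, and label
noise from imperfect peak calling. Passing the synthetic recovery tests
therefore shows the pipeline can learn a planted, high-information signal
at realistic sequence length and sample size — not that it attains any
particular accuracy on real ChIP-seq data.

## Reference experiment scales

The reference experiments (test suite and `scripts/acceptance.py`) use
2000 sequences (1600/200/200 split), units 50, Adam, k = 5, s = 2, d = 50,
batch 200, 10 epochs; under these conditions the test AUC reaches ≥ 0.95
(typically 1.0) and the null control (planting disabled) stays at chance
(AUC in [0.4, 0.6]). Grid and sweep smoke-tests run at 200 sequences and
2 epochs. These sizes are the package's chosen desk-scale defaults for a
single-CPU run.

## Numerical choices and edge cases

- Sigmoid is computed in the numerically stable split form; probabilities
  are clipped before logarithms (ε = 1e-7).
- The embedding matrix is stored tokens-as-rows, (V+1) × d, row 0 zero;
  the serialization pairs a JSON header with word2vec text format using
  `repr(float)` so round-trips are exact.
- `split_dataset` sizes are ⌊fraction·n⌋ for validation and test with the
  remainder to train; the per-class allocation uses largest-remainder
  apportionment (ties toward the larger class) with a repair step for
  tiny classes, keeping global sizes exact while stratifying.
- AUC requires both classes and APS at least one positive; both raise a
  dedicated error otherwise rather than returning a silent default.
- Orthogonal initialization fixes the QR sign so a seed determines the
  weights uniquely.
- `dinucleotide_shuffle` returns sequences of length < 3 unchanged.

## Known limitations

- Single CPU, dense NumPy: practical up to tens of thousands of sequences,
  not ENCODE-scale compendia.
- No reverse-complement weight sharing or attention; single-strand input.
- The word2vec trainer is deterministic because it is single-threaded;
  there is no parallel mode.
- `observed` vocabulary mode plus unseen test k-mers maps them to the
  zero vector (index 0), which the masking treats as real steps with null
  input — acceptable for rare events, but `full` mode avoids it entirely
  for k ≤ 8.
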