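# kegru

Transcription-factor (TF) binding site prediction from DNA sequence with
k-mer embeddings and a bidirectional gated recurrent unit (GRU) network.

TFs bind short, degenerate sequence elements, and classifiers trained on
ChIP-seq-derived positive/negative sequence sets learn those preferences
directly from sequence. This package treats a DNA sequence as a sentence of
overlapping k-mers, embeds each k-mer as a dense vector learned from
co-occurrence (word2vec), and classifies the embedded k-mer sequence with a
bidirectional GRU. It is aimed at regulatory-genomics practitioners who want
a transparent, dependency-light (pure NumPy) recurrent baseline whose every
component — tokenizer, embedding trainer, GRU cell, backpropagation,
optimizers — is inspectable and unit-tested, plus a synthetic-data generator
that emulates ChIP-seq-style datasets so the whole pipeline runs without
external downloads.

## The model

A sequence of length *L* is split into *N* = ⌊(*L* − *k*)/*s*⌋ + 1 k-mers
(length *k*, stride *s*), each mapped to a *d*-dimensional vector through an
embedding matrix pre-trained with word2vec on the k-mer corpus. A GRU
carries a hidden state *h<sub>t</sub>* across the sequence:

```
z_t = σ(W_z x_t + U_z h_{t−1} + b_z)          update gate
r_t = σ(W_r x_t + U_r h_{t−1} + b_r)          reset gate
m_t = tanh(W_h x_t + U_h (r_t ∗ h_{t−1}) + b_h)   candidate state
h_t = (1 − z_t) ∗ h_{t−1} + z_t ∗ m_t
```

A forward and a backward GRU read the sequence in opposite directions; their
final states are merged (concatenate / sum / average / multiplication) and a
dense layer with a logistic sigmoid yields *p* = P(bound). Training
minimizes the negative Bernoulli log-likelihood
−Σ<sub>i</sub> [*y<sub>i</sub>* log *p<sub>i</sub>* + (1 − *y<sub>i</sub>*) log(1 − *p<sub>i</sub>*)]
by mini-batch gradient descent (SGD, Adam, Adagrad or RMSprop). The
embedding layer supports three strategies: `no_init` (random, fine-tuned),
`init_no_train` (pre-trained, frozen) and `init_train` (pre-trained,
fine-tuned; the default). Models are scored by AUC and average precision
(APS).

## Worked example

```python
from kegru import (SyntheticSpec, TrainConfig, generate_dataset,
                   run_experiment, split_dataset)

# 1000 synthetic 101-bp sequences: half carry a planted TGACGTCA motif,
# half are GC-matched motif-free negatives.
spec = SyntheticSpec(n_pos=500, n_neg=500, seed=7)
dataset, truth = generate_dataset(spec)
dataset = split_dataset(dataset, (0.8, 0.1, 0.1), seed=8)

config = TrainConfig(units=50, optimizer="Adam", epochs=10,
                     embedding_strategy="init_train", k=5, s=2, d=50, seed=9)
model, metrics, log = run_experiment(dataset, config)

for entry in log:
    if "epoch" in entry:
        print(f"epoch {entry['epoch']:2d}  loss {entry['train_loss']:.4f}  "
              f"val AUC {entry['val_auc']:.4f}")
print(f"test AUC {metrics['test']['auc']:.4f}  test APS {metrics['test']['aps']:.4f}")
```

Output:

```
epoch  1  loss 0.7064  val AUC 0.6044
epoch  2  loss 0.6935  val AUC 0.6444
epoch  3  loss 0.6760  val AUC 0.6688
epoch  4  loss 0.6691  val AUC 0.7256
epoch  5  loss 0.6581  val AUC 0.7596
epoch  6  loss 0.6478  val AUC 0.7892
epoch  7  loss 0.6340  val AUC 0.7984
epoch  8  loss 0.6169  val AUC 0.8116
epoch  9  loss 0.5979  val AUC 0.8476
epoch 10  loss 0.5690  val AUC 0.8964
test AUC 0.8668  test APS 0.9008
```

The training loss falls and the validation AUC climbs as the network learns
to detect the planted motif; the held-out test AUC of 0.87 means a random
motif-bearing sequence outranks a random background sequence 87% of the
time at this training budget (doubling the data or epochs drives it to ~1.0).

The same pipeline is available as a CLI — `kegru simulate`, `tokenize`,
`embed`, `train`, `evaluate`, `grid` (the 12-cell units × optimizer search),
`ablate` (embedding strategies) and `sweep` (k/s/d sensitivity); see
`kegru --help`.

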