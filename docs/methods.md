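# Methods

## Label construction from window energy scans

The label source is a table of scored peptide windows: `(sequence_id,
window_start, window_length, reu)`, with REU the Rosetta energy of the
window against the partner chain (lower = more favourable). Processing:

1. **Artifact filter.** Windows with REU < −1000 are discarded as numerical
   artifacts. The filter is applied to individual window records, not whole
   chains, because the averaging step that follows is per-position and a
   single corrupt window would otherwise poison every position it covers.
2. **Length filter.** All windows of chains with length ≤ 50 or ≥ 1023 are
   discarded (kept range 51–1022, both bounds strict).
3. **Window → position averaging.** `E_i` = arithmetic mean of the REU of
   every window covering position `i`; `coverage_i` counts those windows.
   Positions covered by no window are *missing* (NaN energy, coverage 0) —
   never silently zero. Coverage satisfies the conservation law
   Σ_i coverage_i = Σ_records window_length, which the tests check exactly.
4. **Duplicate merging.** Chains with byte-identical residue strings are
   merged into one profile: at each position, the plain mean over members
   with a value there (coverage-unweighted — the member profiles are already
   per-position means, and weighting by coverage would double-count deep
   windows). The merged profile takes the lexicographically smallest member
   id and records all member ids.
5. **Binarization.** `y_i = 1` iff `E_i < −1` REU, strict. Missing positions
   get `y_i = 0` plus a mask flag; masked positions are excluded from the
   training loss and every metric. Each sequence carries a positive loss
   weight (default 1.0) for per-protein rebalancing.

## Homology-aware splitting

Sequences are clustered by connected components of the graph with an edge
wherever estimated pairwise identity ≥ 0.25. The built-in identity estimate
is shared-5-mer containment: |kmers(a) ∩ kmers(b)| / min(|kmers(a)|,
|kmers(b)|). It is alignment-free and errs permissive (containment ≥ true
identity for closely related pairs), which is the safe direction for leakage
prevention. Real clustering-tool output can be injected as a precomputed
`sequence_id → cluster` mapping, bypassing the estimator entirely.

Whole clusters are assigned to train/val/test. Clusters containing a
forced-test id (sequences earmarked for experimental follow-up) go to test
first; remaining clusters are taken largest-first and assigned to the split
whose occupied fraction is furthest below its target (defaults 0.77/0.10/0.13,
chosen to approximate a 26423/3487/3817-style partition). Ties in cluster
size are broken by a seeded permutation, so the assignment is deterministic
given the seed. If forced-test sequences alone exceed the test fraction, the
split proceeds with a warning rather than an error.

## Embedding backends

The classifier consumes one real vector per residue from a backend
implementing a shared contract: `embed(seq) → (n, dim)`, deterministic for
fixed parameters, with `set_trainable(k)` marking exactly the final `k`
blocks as fine-tunable (`k = 0` = frozen backend).

- **onehot** (default for training and tests): concatenated one-hot residue
  encodings over a symmetric context window of radius r = 7
  (dim = 21·15 = 315), boundary positions zero-padded. Parameter-free,
  linear-time, and sufficient to recover compositional motifs.
- **tinytransformer**: token embeddings + sinusoidal positions through
  `n_blocks` single-head attention + feed-forward blocks with residual
  connections and seeded random initialization. No layer norm — weights are
  initialized at scale 1/√dim, which keeps activations conditioned at the
  4-block default depth and keeps the hand-written backward pass simple.
  Gradients flow only through the last `k` blocks, mirroring partial
  fine-tuning of a pretrained language model; the backward pass is verified
  against central finite differences in the tests.
- **plugin:** `plugin:<module>:<factory>` loads any object satisfying the
  contract — the adapter slot for a real pretrained protein language model.
  Nothing in the core pipeline or tests requires it.

## Classifier and training

A four-weight-layer MLP (hidden sizes 256/128/64 by default, ReLU, sigmoid
output) is applied independently at each position. The loss per sequence is
the sequence weight times the *mean* masked binary cross entropy —
mean rather than sum so loss magnitude is length-independent and
mixed-length batches are stable. Probabilities are clamped to
[1e−7, 1 − 1e−7] inside the loss.

Optimization is minibatch Adam (rate 1e−3, β = 0.9/0.999), batches of 8
sequences, gradients averaged per batch. Backpropagation is hand-written
(the sigmoid-BCE identity `∂L/∂logit = w(p − y)/n_valid` feeds the head and,
when `k > 0`, continues into the backend's trainable blocks); analytic
gradients agree with central differences to 1e−4 relative in the tests.

Early stopping: after each epoch the validation loss is computed; training
stops when it has not improved for `patience` consecutive epochs (default 2)
or at `max_epochs`, and the best-validation-loss checkpoint is restored.
The recovery study below uses patience 3 / max 40 epochs, a schedule wide
enough that stopping is driven by the validation curve rather than the cap.
Everything is reproducible given the config seed; with `k = 0` the backend's
outputs are bit-identical before and after training.

## Guide-peptide prioritization

Given a predicted probability track `p_1..p_n` and peptide length `L`
(default 15, user-specified in practice):

- window score `s(i)` = mean of `p` over positions `i..i+L−1`, masked
  positions excluded; fully masked windows are missing.
- local maxima: `s(i)` strictly above both neighbours; a plateau of equal
  values strictly above both flanks yields its leftmost index; a boundary
  index qualifies if it exceeds its single neighbour (a constant profile thus
  yields index 1). Missing scores are never maxima and act as −∞ flanks.
- ranking by score descending, ties to the smaller start; by default a
  greedy pass drops any window overlapping an already-kept one
  (`allow_overlap` restores the permissive reading); at most `top_n`
  candidates are returned with contiguous ranks.
- for a target protein, candidates are computed per partner (partners found
  in the filtered PPI table) and pooled across partners by global score
  (per-partner mode is also exposed, since either reading is defensible).

Mean probability was chosen as the window score because it is invariant
across choices of `L`; the selection is verified against an independent
enumerate–filter–sort–greedy oracle on random curves.

## PPI evidence policies

`stringent` keeps all IMEx records, BioGRID records with low-throughput
(LTP) physical evidence, and PROPER records with p < 0.01; `lenient` keeps
IMEx, BioGRID LTP or HTP, and PROPER p < 0.05 (inequalities strict). The
stringent set is a subset of the lenient set for every input. Partner tables
are symmetric; self-interactions are tracked separately as homogeneous.
Coverage = 100 × (proteins with ≥ 1 heterogeneous partner) / proteome size.
Symbol matching is exact after uppercasing.

## Synthetic fixtures

The generator emulates the statistical structure the pipeline assumes, not
protein physics:

- sequences of 60–120 residues, uniform background composition;
- one planted motif of 8–12 residues per sequence, drawn with 90% of
  probability mass on the strongly hydrophobic subset {F, I, L, V}. The
  subset is deliberately small (background rate 4/20): it makes a planted
  run compositionally unambiguous, so the binding signal is carried by
  sequence alone and a context-window model can localize motif boundaries;
- true per-position energy = −2.0 REU at motif positions + N(0, 0.5) noise;
- labels obtained by the *builder's own* binarization of that energy, so
  generator and builder cannot drift apart;
- window records: each 10-mer window's REU is the mean of the true position
  energies it covers — the exact inverse of the builder's aggregation, so
  the builder recovers the planted effect exactly in the noiseless motif
  interior;
- the PPI generator plants one motif per partner (noiseless by default, so
  the interface is unambiguous) and mixes IMEx/BioGRID/PROPER evidence with
  p-values straddling both policy cutoffs.

What the fixtures do **not** emulate: realistic amino-acid composition and
phylogenetic correlation, structure-mediated (non-compositional) interface
signal, energy landscapes with long-range structure, multi-partner epistasis.
Passing the recovery tests shows the pipeline machinery is correct and that
a learnable sequence signal propagates end to end; it does not certify
performance on real proteins.

### What the recovery study can reach

At noise σ = 0.5 and effect −2, about Φ(−2) ≈ 2.3% of background positions
are spuriously labelled positive and the same fraction of motif positions
negative. These flipped labels bound the achievable held-out AUROC at ≈ 0.92
(the score of an oracle that knows the planted motifs exactly); the recovery
study's trained model reaches ≈ 0.905–0.93 across seeds, i.e. close to that
ceiling. The background label rate itself is checked against the Gaussian
tail prediction within three standard errors.

## Numerical and interface conventions

- All positions are 1-based inclusive everywhere (files, types, CLI).
- Score tracks are TSV with 6-significant-digit values; write∘read is a
  fixpoint at that precision. FASTA I/O uppercases residues and maps the
  nonstandard codes B, J, O, U, Z, * to X with a warning.
- AUROC uses the Mann–Whitney rank formulation with half credit for ties;
  Spearman uses average ranks; both refuse degenerate (single-class or
  constant) input rather than returning a conventional value. The Spearman
  against energies negates the energy axis so agreement is positive.
- Top-n energy summaries break score ties by position order.
- Metrics macro-average across sequences by default (per-sequence metrics,
  then mean, skipping sequences where a metric is undefined); a micro
  (global-pool) mode is exposed since either convention is defensible.
- One global seed is fanned out per stage by hashing the stage name
  (SHA-256, reduced below 2³¹), so adding a stage never perturbs another's
  randomness; pipeline reruns with the same config are byte-identical.
- Model checkpoints are single `.npz` files with the backend/head config and
  seed embedded as JSON.

## Known limitations

- The built-in identity estimator is a k-mer containment heuristic, not an
  aligner; for production splits, inject clustering output from a dedicated
  tool via the precomputed-clusters adapter.
- The tiny transformer is a contract-faithful stand-in at desk scale; its
  representations are not expected to transfer. Real embedding quality
  requires a pretrained backend through the plugin adapter.
- The cluster-split greedy assignment approximates the target fractions; with
  few large clusters the realized fractions can deviate substantially.
- Training is single-threaded dense numpy; it is sized for corpora of
  hundreds of sequences, not the tens of thousands a production run would use.
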