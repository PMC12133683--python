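# Methods

## Problem and model

The package predicts binary antibody–antigen interaction from the two
amino-acid sequences alone.  Each chain is represented twice: as a per-residue
embedding matrix (L × D) and as an embedding-fused CKSAAP tensor on the
20 × 20 ordered amino-acid-pair grid.  Two branch networks per chain — a
CNN–BiLSTM stack over the residue axis and recurrent criss-cross attention
over the pair grid — produce four fixed-width vectors that are concatenated
and classified by a ReLU MLP with a sigmoid output.  Antibody and antigen
branches never share parameters: the two chain types have different length
statistics and compositional structure.

### Encoders

* **One-hot** (default): L × 20 indicators in the fixed alphabet order
  `ACDEFGHIKLMNPQRSTVWY`; the mask/unknown residue `X` has an all-zero row.
* **External store**: per-residue matrices from a protein language model,
  read from an HDF5 file keyed by sequence id (one L × D float32 dataset per
  sequence, root attribute `dim`).  The library only consumes such stores;
  it never runs an embedding model itself.  Rows at `X` positions are zeroed
  so masking behaves identically across encoders.

### CKSAAP and the fusion rule

Classic CKSAAP counts, for each gap g = 0..k, ordered residue pairs
(seq[t], seq[t+g+1]) and normalizes each gap block by its number of valid
windows, so every non-empty block sums to 1.  The fused variant weights each
occurrence by the mean of the two endpoint embedding values per dimension,
giving a D × (k+1) × 20 × 20 tensor.  Two properties make this fusion rule
attractive and testable:

* with a constant all-ones embedding it reduces *exactly* to the classic
  counts (asserted to 1e-10 in the tests), and
* it is linear in the embedding.

Windows touching `X` are excluded from numerator **and** denominator.  This
is what makes CDR masking meaningful: occluding a region deletes its pair
evidence instead of diluting the remaining frequencies.  Normalizing fused
cells by the valid-window count (rather than leaving raw sums) keeps the
feature scale length-independent, which matters when antibody and antigen
lengths differ.

### CNN–BiLSTM branch

Linear projection to `projection_dim`, then `n` units of valid 1-D
convolution (kernel m), non-overlapping max-pooling (width w), and a BiLSTM
whose output is added to a (linearly projected) residual of its input.
Output length per unit is `floor((L − m + 1)/w)`; inputs shorter than the
stack's minimum length raise an error.  The final representation is the
masked mean over surviving positions — mean pooling is length-robust, which
valid convolution alone is not.  Padded batches carry a length mask; LSTM
hidden and cell states are multiplied by the mask at every step, so padding
never leaks across the sequence in either direction (appending pad rows is a
no-op, asserted in the tests).

Defaults: m = 3, w = 2, two units, the published depth for this
architecture.  The kernel width, pooling geometry and hidden width are
conventional choices; the architecture depth `n = 2` and the CKSAAP bound
`k = 3` follow the published tuning of this model family.

### Criss-cross attention branch

The fused tensor's embedding and gap axes are flattened into C = D·(k+1)
channels over the 20 × 20 grid (the grid side is the amino-acid alphabet
size).  An optional learned 1×1 reduction to `pre_channels` precedes
attention to bound memory when D is large (e.g. language-model embeddings
with D = 1280).  Each pass projects the grid with three 1×1 convolutions to
queries/keys (reduced channels C′ = max(1, C/8)) and values (full width),
computes, for every position u, dot-product affinities against the 2n−1
positions sharing u's row or column — u itself counted once — and softmaxes
them (max-subtracted for stability) into a probability fiber; aggregation
sums the attended values and adds the residual input.  Two recurrences with
shared projection parameters propagate information between any two grid
cells; a finite-difference probe in the test suite verifies the full
receptive field.  The self-position convention (2n−1 members, counted once)
is the standard criss-cross design; the alternative reading that counts the
self position twice changes nothing qualitatively but breaks the
probability-fiber dimension.

### Training

Binary cross-entropy on logits (numerically stable formulation), Adam.  The
full-scale defaults are 80 epochs, learning rate 5e-4, batch size 128.  The
desk-scale studies (below) use 15 epochs, 2e-3, batch 32 — sized so a
complete train/evaluate cycle on 1000 pairs takes about two minutes on one
CPU while still converging on the planted rule.  There is no early stopping;
the final-epoch model is returned.  All parameter initialization and batch
shuffling derive from explicit seeds; training is bit-reproducible on CPU.

### Metrics

ACC, precision, recall, specificity and F1 from thresholded confusion counts
(threshold 0.5, configurable); MCC with the standard formula
`(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`; ROC AUC and AUPR from
the raw scores.  A published variant of the MCC formula that reuses the F1
numerator (2·TP) is treated as a typographical slip: it is not the Matthews
coefficient and can leave the coefficient's range, so the standard form is
used.  Zero denominators yield 0 (logged).  Multi-seed comparisons use a
two-sided Welch t-test (the unequal-variance form is the safe default when
only "Student's t-test" is specified); two constant equal groups give p = 1,
constant unequal groups p = 0.

## Synthetic benchmark

The generator emulates the *shape* of real AAI benchmarks — paired
sequences, binary labels, CDR/epitope annotations — with an exactly
re-checkable ground truth:

* backgrounds i.i.d. uniform over the 20 residues (ab and ag length 60);
* complementarity is the reverse-alphabet letter bijection, so binding means
  "the CDR motif is the letterwise complement of the epitope motif";
* one 6-mer epitope motif per dataset; intended positives (half the pairs)
  carry it in the antigen's epitope window and its complement in exactly one
  CDR window chosen with probability proportional to the importance weights
  (defaults 0.2, 0.5, 1.0 for CDR1..3);
* intended negatives may carry either motif half alone (decoys: 35%
  antigen-side, 35% antibody-side), so neither chain is informative alone
  and a model must learn the conjunction;
* the label is recomputed from the sequences (weighted per-CDR
  complementarity matches, thresholded at half the smallest positive
  weight) and flipped with probability ε = 0.05.

What this does *not* emulate: immunoglobulin germline structure, somatic
hypermutation, realistic length variation, physicochemical binding scores,
or the redundancy structure of curated benchmarks.  Passing the synthetic
studies therefore demonstrates that the architecture, features, training
loop and sensitivity analysis work as specified — not that the model
reaches any particular accuracy on real antibody data.

## Study conditions

All end-to-end checks use 1000 training pairs, 300 held-out pairs, and the
small model (one-hot encoder, k = 1, one CNN-BiLSTM unit, projection 32,
hidden 16, attention pre-reduction to 16 channels, MLP 64→16), trained for
15 epochs.  Under these conditions:

* **Learnability** — held-out accuracy ≥ 0.9 despite 5% label noise.
* **CDR sensitivity** — masking biases satisfy
  b(CDR1) ≤ b(CDR2) ≤ b(CDR3), mirroring the planted importances, in at
  least 4 of 5 seeds; masking all CDRs hurts most.
* **Label-shuffle null** — training on permuted labels yields held-out AUC
  within [0.4, 0.6]: the pipeline cannot manufacture signal.

One master seed fans out to named substreams (generator / model / shuffle)
via hashed seed sequences, so multi-seed protocols are scriptable and every
artifact is reproducible from its manifest.

## Numerical and design notes

* The compute core is a small numpy reverse-mode autodiff engine (float64);
  every primitive's gradient is checked against central finite differences.
  Softmax uses max subtraction; binary cross-entropy is computed from logits
  with the log1p(exp(−|z|)) form.
* Max-pool ties split gradient equally among maximal entries.
* The redundancy filter scores global (Needleman–Wunsch) alignments with
  match +1, mismatch 0, linear gap −1 and defines identity as matches over
  alignment columns; a test pair is dropped only when *both* chains reach
  the cutoff against a training pair *and* the labels agree.  Published
  survivor counts for this kind of filter are sensitive to the identity
  definition, which is rarely stated; this choice is the conservative
  standard.
* Region coordinates are 0-based half-open everywhere; regions on one
  sequence must not overlap.
* Nonstandard residues (B, Z, U, O, J, `*`) canonicalize to `X`, unifying
  unknowns with the masking token.

## Known limitations

* CPU-only and desk-scale: the full published-scale configuration (k = 3,
  two units, width-1280 embeddings, 80 epochs on ~25k pairs) is expressible
  but impractical in this implementation; reproducing external benchmark
  tables additionally requires the corresponding curated datasets and
  pretrained embedding models, which are not bundled.
* The CDR-removal retraining experiment is supported through
  `remove_regions` + refitting, but the acceptance studies exercise the
  masking analysis only.
* Whether masked positions should be re-embedded by the language model or
  zeroed in-place is undecidable from sequence alone; the store-based
  encoder zeroes them.
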