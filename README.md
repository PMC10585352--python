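# peptidecrf

Bioactive peptides (hormones, neuropeptides, antimicrobial peptides) are cut
out of longer precursor proteins by proteases. Predicting which parts of a
precursor are released — and whether a released segment is a functional
peptide or a discarded propeptide — is a span-labeling problem: most residues
are background, and the interesting annotations are short contiguous
segments of 5–50 residues whose termini are determined by local cleavage
signals such as dibasic KR/RR sites.

`peptidecrf` implements a length-constrained linear-chain conditional random
field (CRF) for this problem, for computational biologists who want a
transparent, trainable, CPU-only span labeler:

* a **constrained state space** with one background state plus one state per
  within-span position for each class (101 states for two classes and spans
  up to 50 residues), whose transition mask structurally enforces the
  5–50-residue length bounds and forbids direct peptide↔propeptide
  transitions;
* **class-tied emissions**: a neural network produces three logits per
  position, ψ(None), ψ(Peptide), ψ(Propeptide), shared among all states of
  the same class;
* exact inference: forward log-partition, Viterbi decoding, and
  forward–backward posteriors, all in NumPy with analytic gradients, so the
  emission network and the transition weights φ train end to end by
  minimising the CRF negative log-likelihood
  `−log P(y|h) = log Z(h) − Σ_t [ψ_t(y_t) + φ(y_{t−1}, y_t)]`;
* pluggable emission front-ends: one-hot encoding over the 33-token ESM
  tokenizer vocabulary, or precomputed per-residue protein-language-model
  embeddings loaded from an HDF5 container;
* span-level evaluation with tolerance windows and overlap-group collapsing,
  dataset-curation filters, flanking-motif k-means clustering with
  stratified fold assignment, nested-cross-validation ensembling, and a
  synthetic precursor generator with planted cleavage motifs.

## Worked example

Simulate a proteome of 120 synthetic precursors with planted flank motifs
(KR…RR around peptides, GG…LL around propeptides), train, predict, evaluate:

```bash
peptidecrf simulate --n-records 120 --seed 42 --outdir demo/data
# proteins  peptides  propeptides  mean_annotations_per_protein
#      120       112          105                          1.81

peptidecrf train --fasta demo/data/sequences.fasta \
    --annotations demo/data/annotations.tsv \
    --epochs 12 --conv-width 32 --lstm-hidden 32 --seed 0 --outdir demo/model
# best epoch 10: validation mean F1 (tolerance 3) = 0.8109

peptidecrf predict --fasta demo/data/sequences.fasta \
    --model demo/model/model.npz --marginals --outdir demo/pred
# wrote 234 predicted spans for 120 sequences

peptidecrf evaluate --predictions demo/pred/predictions.tsv \
    --truth demo/data/annotations.tsv --outdir demo/eval
#      class  tolerance  precision_mean  recall_mean  f1_mean
#    Peptide          0        0.709402     0.741071 0.724891
#    Peptide          3        0.863248     0.901786 0.882096
# Propeptide          3        0.918182     0.961905 0.939535
#        all          3        0.889868     0.930876 0.909910
```

The training line reports the early-stopping metric: the mean of peptide and
propeptide span-level F1 on a held-out validation split, where a predicted
span counts as correct only if both termini fall within 3 residues of a true
span's termini. The evaluation table shows how precision/recall grow as the
tolerance window widens from exact boundaries (0) to ±3 residues. (This demo
evaluates on the training proteome to illustrate the mechanics; the test
suite's parameter-recovery experiment uses a disjoint validation split.)

Predictions are TSV spans in 1-based inclusive coordinates, e.g.
`SYN00000  8  32  Propeptide`; `--marginals` additionally writes per-position
class posteriors obtained by forward–backward with the within-span states
merged per class. Passing several `--model` flags ensembles checkpoints the
nested-CV way: emissions and transition weights are averaged for decoding,
per-model marginals are averaged for the posterior output.

The same functionality is available as a library; see the docstrings in
`peptidecrf.crf`, `peptidecrf.state_space` and `peptidecrf.evaluation`, and
`docs/methods.md` for the model description and design choices.

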