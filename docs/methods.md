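# Methods

## Model

`peptidecrf` labels each residue of a precursor protein with one of three
classes — None (background), Peptide, Propeptide — under the hard constraint
that every contiguous span of a non-background class has length between
`min_len` (default 5) and `max_len` (default 50) residues. The constraint is
encoded structurally rather than heuristically: the label space of the
linear-chain CRF contains one background state plus, for each span class, one
state per within-span position `1..max_len`. With two classes and
`max_len = 50` this gives 101 states.

Allowed transitions are exactly:

* `None → None` and `None → (c, 1)` for each class `c`;
* continuation `(c, p) → (c, p+1)` for `p < max_len`;
* span exit `(c, p) → None` for `p ≥ min_len`;
* tandem re-entry `(c, p) → (c, 1)` for `p ≥ min_len` (same class only).

Everything else — in particular any direct step between the Peptide and
Propeptide branches, and any exit before `min_len` — carries an additive
`−inf` mask and is never learned. Sequences may start at `None` or `(c, 1)`
and may end at `None` or at `(c, p ≥ min_len)`: terminal spans are
biologically real (e.g. peptides at the mature protein's N terminus after
signal-peptide removal). Both the tandem-re-entry and the boundary-span
rules are config switches (`allow_same_class_adjacency`,
`allow_boundary_spans`), since a case can be made either way; the defaults
are the permissive ones because tandem repeats of identical peptides occur
in real precursors.

A path `y` is scored as `Σ_t ψ_t(class(y_t)) + Σ_t φ(y_{t−1}, y_t)`. The
emission score ψ is computed per class, not per state — all 50 states of a
branch share one logit — because the extra states exist only to count span
length, not to represent distinct biology. φ is a learned weight per allowed
transition; initial/final constraints are hard masks with no learned
boundary weights, which keeps the loss in the plain CRF form

    −log P(y|h) = log Z(h) − score(y).

Inference is exact: the forward recursion computes `log Z`, Viterbi the best
path, forward–backward the per-position state posteriors, which are summed
within each class branch to give the reported three-class marginals. The NLL
gradient is the classic expected-minus-observed sufficient statistics from
forward–backward, so no autodiff framework is required.

### Numerics

Forward–backward runs in scaled probability space (per-step renormalization,
the standard HMM rescaling), with per-position emission shifts
`exp(ψ_t − max_k ψ_t(k))`. If any normalizer degenerates (emission ranges
beyond ~700 nats, overflowing transition weights), the code transparently
falls back to a log-space log-sum-exp recursion that tolerates `−inf`
masks. Viterbi is max-plus with ties broken toward the lowest state index at
every backtracking step, making decoded output deterministic; one visible
consequence is that when all segmentations tie exactly (e.g. uniform
emissions, zero transitions), decoding yields tandem minimum-length spans
rather than one maximal span. Marginal rows sum to 1 within 1e-6 without
renormalization; the oracle tests compare all three dynamic programs against
explicit path enumeration at 1e-8.

## Emission models

Front-ends produce a `T × D` feature matrix per sequence:

* **one-hot** (D = 33): indicator rows over the ESM tokenizer vocabulary,
  pinned in this package so results do not depend on the language model
  being installed. No BOS/EOS rows; row *t* is residue *t*. Non-standard
  residues X/U/B/Z/O have dedicated tokens, anything else maps to `<unk>`.
* **precomputed**: per-residue embeddings (e.g. width 1280 from a protein
  language model) loaded from an HDF5 container keyed by sequence id. The
  package never runs a language model itself.

The emission network is CNN–BiLSTM–CNN: a width-preserving convolution
(kernel 3, ReLU, default width 64) over the feature dimension, a
bidirectional LSTM (default 64 units per direction), and a second kernel-3
convolution projecting to the 3 class logits. These widths are this
package's defaults, exposed in config; there is no canonical setting and
they matter mainly for capacity/runtime trade-offs. A purely position-wise
linear head (`LinearEmissionModel`) is also provided; note it cannot see
flanking context and therefore cannot learn cleavage signals that lie
outside the span — it is a baseline and test vehicle, not the recommended
model. All layers are NumPy with hand-derived backward passes, verified by
finite differences to relative error < 1e-4.

## Training

Adam (lr 1e-3, default), batch size one sequence (variable length, no
padding), gradient-norm clipping at 5. Default 50 epochs with early stopping
on the validation mean of peptide-F1 and propeptide-F1 at tolerance window 3
(patience 5); the best checkpoint is restored. Transition weights start at
0, network weights at small random values under a configurable seed, so runs
are reproducible single-threaded.

Precursors with overlapping span annotations cannot be represented by a
single state path, so each epoch draws a maximal non-overlapping subset:
annotations are shuffled uniformly and accepted greedily unless they clash
with an accepted one. Non-conflicting annotations are therefore always kept,
and each member of a conflicting pair is used in about half the epochs. The
per-record rng is seeded from (global seed, epoch, id hash): reproducible,
yet labels vary across epochs as intended. The alternative reading — keep
only one annotation per protein per epoch — would discard conflict-free
information for no stated reason, so the maximal-subset reading was chosen.

### Ensembling

Nested 5-fold cross-validation trains 5 × 4 = 20 models (each outer test
fold paired with each remaining fold as inner validation). For prediction,
the 20 emission matrices are averaged and decoded with the element-wise mean
of the 20 transition-weight matrices — meaningful because every CRF weight
has a fixed interpretable role. Posterior marginals are instead the
arithmetic mean of the 20 per-model forward–backward outputs, *not* the
marginals of the averaged model; the decoded path and the marginals can
therefore legitimately disagree.

## Data preparation

Curation filters mirror the training-data selection rules: (i) Propeptide
annotations whose evidence tags are the PROSITE ProRules PRU00477/PRU01070
(sorting signals misfiled as propeptides) are removed; (ii) precursors whose
Peptide annotation covers the full sequence, or the full mature protein
after a Signal/Transit annotation starting at position 1, are discarded
(such "peptides" are not released products); (iii) Peptide/Propeptide spans
outside 5–50 residues are dropped and records left without any in-range
span are discarded. The length filter runs last since it owns the
at-least-one-annotation rule; the other two commute.

For fold balancing, the two residues on each side of every span (boundary
positions padded with `*`) are embedded per residue and concatenated to a
4-vector motif descriptor, k-means clustered (default k = 50, k-means++,
10 restarts, tol 1e-4), and records — tagged by the majority cluster of
their spans, ties to the lowest cluster id — are dealt round-robin over
folds within each cluster. The default per-residue embedding is the
BLOSUM62 substitution-score row of the residue: biochemistry-aware,
deterministic, and dependency-free; any token→vector table (e.g. language-
model derived) can be injected instead. True homology-aware partitioning is
out of scope; externally produced record→fold files are accepted through
`read_partition_file`, and the cluster-stratified assigner is the
self-contained fallback.

## Synthetic data

The generator emulates the data model the method assumes: background
sequence (uniform over the 20 standard residues by default; a
natural-frequency table ships as an alternative) carrying 0–4 non-
overlapping spans whose flanks hold class-specific cleavage motifs. Defaults,
chosen once as the standard study conditions: 400 records of 100–160
residues; span count probabilities (0.10, 0.30, 0.30, 0.20, 0.10) for 0–4;
span lengths uniform on 5–30 (most real peptide products are short);
peptide/propeptide ratio 0.5; peptide flank motifs KR before and RR after
the span, mimicking prohormone-convertase dibasic sites, and GG/LL for
propeptides so the classes are separable; inter-span gap ≥ 4 so the
2-residue flank motifs never collide; `motif_fidelity` = 1.0, i.e. every
flank residue is planted. Span placement is uniform given the gaps, by
sampling slack cut-points; an infeasible record configuration errors after
bounded retries.

What the generator does *not* emulate: signal/transit peptides, overlapping
annotations, tissue-specific protease repertoires, compositional differences
between span interiors and background, and any sequence homology structure.
Passing the parameter-recovery test therefore shows that the architecture
can learn local flanking cleavage signals end to end through the CRF — not
that it reaches any particular accuracy on real proteomes, where signals are
weaker, noisier and confounded.

With `motif_fidelity = 1.0` the boundaries are fully determined by local
context and a one-hot CNN–BiLSTM–CNN model reaches validation mean F1
(tolerance 3) ≥ 0.8 on 300 training / 100 validation records; with
`motif_fidelity = 0` the labels are independent of the sequence and the same
training run stays below 0.2 — the model cannot invent absent structure.
Both runs finish in minutes on one CPU at these problem sizes.

## Evaluation

Predicted spans are compared to truth at span level. A prediction is a true
positive if both termini lie within the tolerance window (in residues) of a
true span's termini. Overlapping true spans are collapsed into connected
components that count once and are satisfied by matching any member.
Matching is greedy one-to-one in prediction order, ties to the
earliest-starting unmatched group; surplus predictions on an already-matched
group are false positives. On random instances with ≤ 8 spans the greedy
count is tested against an exhaustive optimal-assignment oracle (no
discrepancies observed at these sizes; the test would flag any). Precision,
recall and F1 use the 0-when-undefined convention. Cross-class hits count as
FP + FN in per-class mode; a pooled "all" mode sums counts before taking
ratios. `segments_from_probabilities` thresholds per-residue probabilities
(inclusive ≥, default 0.5) into segments so per-residue predictors can be
scored under the identical span protocol. Replicate summaries report means
and population standard deviations over models.

## Known limitations

* One label per position: overlapping peptides cannot be predicted jointly;
  training resolves them by resampling, evaluation by group-collapsing.
* The CRF transition weights are position-independent; all locality beyond
  span length must come from the emission network's receptive field.
* Training is O(T · S²)-ish per sequence in pure NumPy — comfortable for
  hundreds of precursors on one CPU, not tuned for proteome-scale training.
* The stratified fold assigner balances motif clusters but does not control
  sequence homology between folds; use an external homology partitioner for
  honest generalization estimates on real data.
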