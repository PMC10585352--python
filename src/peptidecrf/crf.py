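"""Linear-chain CRF with class-tied emissions over a constrained state space.

The CRF scores a state path y for a length-T sequence as

    score(y) = sum_t psi_t(class(y_t)) + sum_t phi(y_{t-1}, y_t)

where psi is the T x K class-level emission matrix (shared by all states of
one class) and phi the learned transition weights over allowed transitions.
Forbidden transitions, initial states and final states are hard additive
-inf masks, never learned. The normalizer log Z is computed with the
forward algorithm in log space; decoding uses Viterbi (max-plus) with
deterministic lowest-index tie-breaking; per-position class posteriors come
from forward-backward with the within-class states merged.

Everything here is NumPy; the NLL gradient with respect to emissions and
transitions is the classic expected-minus-observed sufficient-statistics
form obtained from forward-backward.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from . import evaluation, labeling
from .emissions import (
    ConvLstmConvEmissionModel,
    EmissionModel,
    EmbeddingMatrix,
    LinearEmissionModel,
    OneHotFeaturizer,
    PrecomputedFeaturizer,
)
from .seqio import ProteinRecord
from .state_space import (
    StateSpace,
    build_state_space,
    final_mask,
    initial_mask,
    transition_mask,
)

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class CrfParameters:
    """Learned transition weights over one state space."""

    transition_weights: np.ndarray  # (S, S), meaningful only where allowed
    space: StateSpace

    def __post_init__(self) -> None:
        S = self.space.n_states
        if self.transition_weights.shape != (S, S):
            raise ValueError(
                f"transition weight shape {self.transition_weights.shape} != ({S}, {S})"
            )

    @classmethod
    def zeros(cls, space: StateSpace) -> "CrfParameters":
        return cls(np.zeros((space.n_states, space.n_states)), space)

    def masked(self) -> np.ndarray:
        return self.transition_weights + transition_mask(self.space)


@dataclass
class PathDecoding:
    """Viterbi result: state path, merged class labels, and derived spans."""

    state_path: np.ndarray  # (T,) state indices
    class_labels: np.ndarray  # (T,) class indices (0 = None)
    spans: list[tuple[int, int, str]]  # internal 0-based half-open
    score: float


@dataclass
class MarginalProfile:
    """Per-position class posteriors (T x K rows on the simplex)."""

    class_posteriors: np.ndarray


def expand_emissions(e: np.ndarray, space: StateSpace) -> np.ndarray:
    """Tile class-level emissions onto states: column s = column class(s)."""
    e = np.asarray(e, dtype=np.float64)
    if e.ndim != 2 or e.shape[1] != space.n_classes:
        raise ValueError(
            f"emission matrix shape {e.shape} incompatible with "
            f"{space.n_classes} classes"
        )
    return e[:, space.class_of_state]


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    """Log-sum-exp that tolerates all--inf slices without warnings."""
    m = np.max(a, axis=axis, keepdims=True)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.sum(np.exp(a - m_safe), axis=axis)) + np.squeeze(m_safe, axis=axis)
    return np.where(np.isfinite(np.squeeze(m, axis=axis)), out, -np.inf)


def _forward(states: np.ndarray, trans: np.ndarray, init: np.ndarray, fin: np.ndarray):
    T = states.shape[0]
    alpha = np.empty_like(states)
    alpha[0] = states[0] + init
    for t in range(1, T):
        alpha[t] = _logsumexp(alpha[t - 1][:, None] + trans, axis=0) + states[t]
    log_z = float(_logsumexp((alpha[T - 1] + fin)[None, :], axis=1)[0])
    return alpha, log_z


def _backward(states: np.ndarray, trans: np.ndarray, fin: np.ndarray) -> np.ndarray:
    T = states.shape[0]
    beta = np.empty_like(states)
    beta[T - 1] = fin
    for t in range(T - 2, -1, -1):
        beta[t] = _logsumexp(trans + (states[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


# Scaled (probability-space) forward-backward: the classic rescaling trick.
# Exact up to floating point for moderate score ranges and much faster than
# per-step log-sum-exp; callers fall back to the log-space recursions above
# whenever a normalizer degenerates (extreme logits or overflowing weights).


def _scaled_forward(E: np.ndarray, A: np.ndarray, init01: np.ndarray, fin01: np.ndarray):
    T, S = E.shape
    alpha = np.empty((T, S))
    logc = np.empty(T)
    a = E[0] * init01
    for t in range(T):
        if t:
            a = (alpha[t - 1] @ A) * E[t]
        s = a.sum()
        if not np.isfinite(s) or s <= 0.0:
            return None
        alpha[t] = a / s
        logc[t] = np.log(s)
    f = float(alpha[T - 1] @ fin01)
    if f <= 0.0:
        return None
    return alpha, float(logc.sum()) + np.log(f)


def _scaled_backward(E: np.ndarray, A: np.ndarray, fin01: np.ndarray):
    T, S = E.shape
    beta = np.empty((T, S))
    beta[T - 1] = fin01
    for t in range(T - 2, -1, -1):
        b = A @ (E[t + 1] * beta[t + 1])
        s = b.sum()
        if not np.isfinite(s) or s <= 0.0:
            return None
        beta[t] = b / s
    return beta


def _scaled_quantities(states: np.ndarray, params: CrfParameters):
    """(log Z, per-position state posteriors, expected edge counts) or None.

    ``states`` is the T x S tied score matrix. Expected transition counts
    are returned as a vector over the allowed-edge list (row-major order of
    ``np.nonzero(allowed_transition)``).
    """
    space = params.space
    with np.errstate(over="ignore"):
        A = np.where(
            space.allowed_transition, np.exp(params.transition_weights), 0.0
        )
    if not np.isfinite(A).all():
        return None
    m = states.max(axis=1)
    E = np.exp(states - m[:, None])
    init01 = space.allowed_initial.astype(float)
    fin01 = space.allowed_final.astype(float)
    fwd = _scaled_forward(E, A, init01, fin01)
    if fwd is None:
        return None
    alpha, log_z_scaled = fwd
    log_z = log_z_scaled + float(m.sum())
    beta = _scaled_backward(E, A, fin01)
    if beta is None:
        return None
    gamma = alpha * beta
    denom = gamma.sum(axis=1, keepdims=True)
    if (denom <= 0.0).any():
        return None
    gamma /= denom

    I, J = np.nonzero(space.allowed_transition)
    T = states.shape[0]
    if T > 1:
        xi = alpha[:-1][:, I] * A[I, J] * (E[1:] * beta[1:])[:, J]
        tot = xi.sum(axis=1, keepdims=True)
        if (tot <= 0.0).any():
            return None
        edge_counts = (xi / tot).sum(axis=0)
    else:
        edge_counts = np.zeros(len(I))
    return log_z, gamma, edge_counts


def _collapse_classes(state_matrix: np.ndarray, space: StateSpace) -> np.ndarray:
    """Sum state columns within each class (states are laid out in class blocks)."""
    idx = [0] + [1 + c * space.max_len for c in range(len(space.span_classes))]
    return np.add.reduceat(state_matrix, idx, axis=1)


def forward_log_partition(e: np.ndarray, params: CrfParameters) -> float:
    """log Z: log-sum-exp of path scores over all mask-valid paths."""
    space = params.space
    states = expand_emissions(e, space)
    if states.shape[0] < 1:
        raise ValueError("sequence length must be >= 1")
    with np.errstate(over="ignore"):
        A = np.where(space.allowed_transition, np.exp(params.transition_weights), 0.0)
    if np.isfinite(A).all():
        m = states.max(axis=1)
        fwd = _scaled_forward(
            np.exp(states - m[:, None]), A,
            space.allowed_initial.astype(float), space.allowed_final.astype(float),
        )
        if fwd is not None:
            return fwd[1] + float(m.sum())
    _, log_z = _forward(
        states, params.masked(), initial_mask(space), final_mask(space)
    )
    return log_z


def _check_valid_path(y: np.ndarray, space: StateSpace) -> None:
    if not space.allowed_initial[y[0]]:
        raise ValueError(f"label path starts in disallowed state {y[0]}")
    if not space.allowed_final[y[-1]]:
        raise ValueError(f"label path ends in disallowed state {y[-1]}")
    bad = np.nonzero(~space.allowed_transition[y[:-1], y[1:]])[0]
    if bad.size:
        t = int(bad[0])
        raise ValueError(
            f"label path violates transition mask at position {t}: "
            f"{y[t]} -> {y[t + 1]}"
        )


def path_score(e: np.ndarray, params: CrfParameters, y: np.ndarray) -> float:
    """Score of one valid path: tied emissions plus transition weights."""
    space = params.space
    y = np.asarray(y, dtype=np.int64)
    _check_valid_path(y, space)
    states = expand_emissions(e, space)
    s = float(states[np.arange(len(y)), y].sum())
    s += float(params.transition_weights[y[:-1], y[1:]].sum())
    return s


def nll_loss(e: np.ndarray, params: CrfParameters, y: np.ndarray) -> float:
    """Negative log-likelihood of a label path: log Z - score(y). Always >= 0."""
    return forward_log_partition(e, params) - path_score(e, params, y)


def nll_loss_and_gradients(
    e: np.ndarray, params: CrfParameters, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """NLL plus its gradients w.r.t. class emissions and transition weights.

    Gradients are expected minus observed sufficient statistics:
    d/d psi[t, k] = P(class k at t) - [class(y_t) = k];
    d/d phi[i, j] = E[#(i -> j)] - #(i -> j in y), zero where forbidden.
    """
    space = params.space
    y = np.asarray(y, dtype=np.int64)
    _check_valid_path(y, space)
    states = expand_emissions(e, space)
    T = states.shape[0]
    K = space.n_classes

    scaled = _scaled_quantities(states, params)
    if scaled is not None:
        log_z, state_post, edge_counts = scaled
        d_trans = np.zeros_like(params.transition_weights)
        d_trans[space.allowed_transition] = edge_counts
    else:
        trans = params.masked()
        init, fin = initial_mask(space), final_mask(space)
        alpha, log_z = _forward(states, trans, init, fin)
        beta = _backward(states, trans, fin)
        state_post = np.exp(alpha + beta - log_z)  # (T, S)
        d_trans = np.zeros_like(params.transition_weights)
        for t in range(T - 1):
            xi = alpha[t][:, None] + trans + (states[t + 1] + beta[t + 1])[None, :] - log_z
            d_trans += np.exp(np.where(np.isneginf(xi), -np.inf, xi))
        d_trans[~space.allowed_transition] = 0.0

    d_e = _collapse_classes(state_post, space)
    d_e[np.arange(T), space.class_of_state[y]] -= 1.0
    np.add.at(d_trans, (y[:-1], y[1:]), -1.0)
    d_trans[~space.allowed_transition] = 0.0

    loss = log_z - (
        float(states[np.arange(T), y].sum())
        + float(params.transition_weights[y[:-1], y[1:]].sum())
    )
    return loss, d_e, d_trans


def viterbi_decode(e: np.ndarray, params: CrfParameters) -> PathDecoding:
    """Highest-scoring valid path; ties broken toward the lowest state index."""
    space = params.space
    states = expand_emissions(e, space)
    if states.shape[0] < 1:
        raise ValueError("sequence length must be >= 1")
    trans = params.masked()
    T, S = states.shape
    delta = states[0] + initial_mask(space)
    back = np.zeros((T, S), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + trans
        back[t] = np.argmax(cand, axis=0)  # first max = lowest prev index
        delta = cand[back[t], np.arange(S)] + states[t]
    delta = delta + final_mask(space)
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(np.argmax(delta))
    score = float(delta[path[T - 1]])
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return PathDecoding(
        state_path=path,
        class_labels=space.class_of_state[path],
        spans=_spans_from_state_path(path, space),
        score=score,
    )


def _spans_from_state_path(
    path: np.ndarray, space: StateSpace
) -> list[tuple[int, int, str]]:
    """Cut spans at state-position resets: each (c, 1) state opens a span."""
    spans: list[tuple[int, int, str]] = []
    cos, pos = space.class_of_state, space.position_of_state
    names = space.class_names
    T = len(path)
    t = 0
    while t < T:
        s = int(path[t])
        if cos[s] > 0 and pos[s] == 1:
            end = t
            while (
                end + 1 < T
                and cos[path[end + 1]] == cos[s]
                and pos[path[end + 1]] == pos[path[end]] + 1
            ):
                end += 1
            spans.append((t, end + 1, names[cos[s]]))
            t = end + 1
        else:
            t += 1
    return spans


def posterior_marginals(e: np.ndarray, params: CrfParameters) -> MarginalProfile:
    """Forward-backward class posteriors with span-position states merged."""
    space = params.space
    states = expand_emissions(e, space)
    if states.shape[0] < 1:
        raise ValueError("sequence length must be >= 1")
    scaled = _scaled_quantities(states, params)
    if scaled is not None:
        return MarginalProfile(_collapse_classes(scaled[1], space))
    trans = params.masked()
    alpha, log_z = _forward(states, trans, initial_mask(space), final_mask(space))
    beta = _backward(states, trans, final_mask(space))
    state_post = np.exp(alpha + beta - log_z)
    return MarginalProfile(_collapse_classes(state_post, space))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the reference configuration: 50 epochs with early
    stopping on the mean of peptide and propeptide span-level F1 at a
    3-residue tolerance window, Adam with learning rate 1e-3, batch size
    of one sequence (no padding), and per-epoch resampling of overlapping
    annotations.
    """

    epochs: int = 50
    learning_rate: float = 1e-3
    patience: int = 5
    tolerance: int = 3
    seed: int = 0
    resample_overlapping: bool = True
    grad_clip: float = 5.0


@dataclass
class TrainHistory:
    train_nll: list[float] = field(default_factory=list)
    val_mean_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = -1.0
    stopped_epoch: int = -1


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


@dataclass
class PeptideCrfModel:
    """A trained emission model + CRF bundle with its featurizer."""

    space: StateSpace
    emission_model: EmissionModel
    crf_params: CrfParameters
    featurizer: Callable[[ProteinRecord], EmbeddingMatrix]
    train_config: Optional[TrainConfig] = None
    history: Optional[TrainHistory] = None

    def emission_matrix(self, record: ProteinRecord) -> np.ndarray:
        scores, _ = self.emission_model.forward(self.featurizer(record))
        return scores

    def predict(self, record: ProteinRecord) -> tuple[PathDecoding, MarginalProfile]:
        e = self.emission_matrix(record)
        return viterbi_decode(e, self.crf_params), posterior_marginals(e, self.crf_params)


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _validation_mean_f1(
    model: PeptideCrfModel, records: Sequence[ProteinRecord], tolerance: int
) -> float:
    """Mean of peptide and propeptide span F1 at the given tolerance."""
    per_class_counts = {
        c: evaluation.EvaluationCounts(0, 0, 0, tolerance, c)
        for c in model.space.span_classes
    }
    for rec in records:
        decoding = viterbi_decode(model.emission_matrix(rec), model.crf_params)
        pred = [(s + 1, e, c) for s, e, c in decoding.spans]
        truth = [
            (a.start, a.end, a.span_class)
            for a in rec.annotations_of_class(*model.space.span_classes)
            if model.space.min_len <= a.length <= model.space.max_len
        ]
        for cls in model.space.span_classes:
            p = [(s, e) for s, e, c in pred if c == cls]
            groups = evaluation.collapse_overlap_groups(
                [(s, e) for s, e, c in truth if c == cls]
            )
            counts = evaluation.match_spans(p, groups, tolerance)
            acc = per_class_counts[cls]
            acc.tp += counts.tp
            acc.fp += counts.fp
            acc.fn += counts.fn
    f1s = [
        evaluation.precision_recall_f1(per_class_counts[c]).f1
        for c in model.space.span_classes
    ]
    return float(np.mean(f1s))


def train_crf(
    train_records: Sequence[ProteinRecord],
    val_records: Sequence[ProteinRecord],
    emission_model: EmissionModel,
    featurizer: Callable[[ProteinRecord], EmbeddingMatrix],
    space: StateSpace,
    config: TrainConfig = TrainConfig(),
) -> PeptideCrfModel:
    """Jointly train emission-model and transition parameters by NLL descent.

    One gradient step per sequence (variable length, no padding). After each
    epoch the mean peptide/propeptide F1 on the validation split decides
    early stopping; the best checkpoint is kept. Overlapping annotations are
    re-resolved each epoch with an rng seeded per (epoch, record id), so
    runs are reproducible while labels vary across epochs.
    """
    if not train_records:
        raise ValueError("training set is empty")
    if config.epochs < 1:
        raise ValueError("epochs must be >= 1")
    train_ids = {r.id for r in train_records}
    overlap = train_ids & {r.id for r in val_records}
    if overlap:
        raise ValueError(f"train/validation splits share record ids: {sorted(overlap)[:5]}")

    crf_params = CrfParameters.zeros(space)
    params: dict[str, np.ndarray] = {f"em.{k}": v for k, v in emission_model.params.items()}
    params["trans"] = crf_params.transition_weights
    opt = _Adam(params, config.learning_rate)
    history = TrainHistory()
    model = PeptideCrfModel(space, emission_model, crf_params, featurizer, config, history)

    emb_cache = {rec.id: featurizer(rec) for rec in train_records}
    best_snapshot = None
    epochs_since_best = 0
    order_rng = np.random.default_rng(config.seed)

    for epoch in range(config.epochs):
        order = order_rng.permutation(len(train_records))
        epoch_nll = 0.0
        for idx in order:
            rec = train_records[idx]
            y = labeling.epoch_labels(rec, space, epoch, config.seed, config.resample_overlapping)
            emb = emb_cache[rec.id]
            scores, cache = emission_model.forward(emb)
            loss, d_e, d_trans = nll_loss_and_gradients(scores, crf_params, y)
            epoch_nll += loss
            grads = {f"em.{k}": g for k, g in emission_model.backward(cache, d_e).items()}
            grads["trans"] = d_trans
            if config.grad_clip:
                _clip_grads(grads, config.grad_clip)
            if config.learning_rate > 0:
                opt.step(params, grads)
                crf_params.transition_weights[~space.allowed_transition] = 0.0
        mean_nll = epoch_nll / len(train_records)
        history.train_nll.append(mean_nll)

        val_f1 = (
            _validation_mean_f1(model, val_records, config.tolerance)
            if val_records
            else -mean_nll
        )
        history.val_mean_f1.append(val_f1 if val_records else float("nan"))
        logger.info(
            "epoch %d: mean train NLL %.4f, val mean F1(tol=%d) %.4f",
            epoch, mean_nll, config.tolerance, val_f1,
        )
        if val_f1 > history.best_val_f1:
            history.best_val_f1 = val_f1
            history.best_epoch = epoch
            best_snapshot = (
                copy.deepcopy(emission_model.params),
                crf_params.transition_weights.copy(),
            )
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                history.stopped_epoch = epoch
                break
    if history.stopped_epoch < 0:
        history.stopped_epoch = len(history.train_nll) - 1

    if best_snapshot is not None:
        em_params, trans = best_snapshot
        for k in emission_model.params:
            emission_model.params[k][...] = em_params[k]
        crf_params.transition_weights[...] = trans
    return model


# ---------------------------------------------------------------------------
# Ensembling
# ---------------------------------------------------------------------------


def _same_space(a: StateSpace, b: StateSpace) -> bool:
    return (
        a.min_len == b.min_len
        and a.max_len == b.max_len
        and a.span_classes == b.span_classes
        and np.array_equal(a.allowed_transition, b.allowed_transition)
        and np.array_equal(a.allowed_initial, b.allowed_initial)
        and np.array_equal(a.allowed_final, b.allowed_final)
    )


def ensemble_predict(
    models: Sequence[PeptideCrfModel], record: ProteinRecord
) -> tuple[PathDecoding, MarginalProfile]:
    """Combine an ensemble the way the nested-CV predictor does.

    Decoding: Viterbi on the element-wise mean of the models' emission
    matrices with the element-wise mean of their transition weights.
    Marginals: arithmetic mean of the per-model forward-backward posteriors
    (not the marginals of the averaged model); the two outputs may disagree.
    """
    if not models:
        raise ValueError("ensemble needs at least one model")
    space = models[0].space
    for m in models[1:]:
        if not _same_space(m.space, space):
            raise ValueError("ensemble members use different state spaces")
    emissions = [m.emission_matrix(record) for m in models]
    mean_e = np.mean(emissions, axis=0)
    mean_trans = np.mean([m.crf_params.transition_weights for m in models], axis=0)
    mean_params = CrfParameters(mean_trans, space)
    decoding = viterbi_decode(mean_e, mean_params)
    per_model = [
        posterior_marginals(e, m.crf_params).class_posteriors
        for e, m in zip(emissions, models)
    ]
    return decoding, MarginalProfile(np.mean(per_model, axis=0))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_model(model: PeptideCrfModel, path: str | Path) -> None:
    """Serialize state-space config, emission weights and transitions (npz)."""
    em = model.emission_model
    if isinstance(em, ConvLstmConvEmissionModel):
        em_kind = "conv-lstm-conv"
        em_hyper = {
            "conv_width": em.conv_width,
            "kernel_size": em.kernel_size,
            "lstm_hidden": em.lstm_hidden,
            "n_classes": em.n_classes,
        }
        input_width = int(em.params["conv1_W"].shape[1])
    elif isinstance(em, LinearEmissionModel):
        em_kind = "linear"
        em_hyper = {"n_classes": int(em.params["b"].shape[0])}
        input_width = int(em.params["W"].shape[0])
    else:
        raise TypeError(f"cannot serialize emission model {type(em).__name__}")
    feat_name = getattr(model.featurizer, "name", "one-hot")
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "space": {
            "min_len": model.space.min_len,
            "max_len": model.space.max_len,
            "span_classes": list(model.space.span_classes),
        },
        "emission_model": {"kind": em_kind, "input_width": input_width, **em_hyper},
        "featurizer": feat_name,
        "train_config": asdict(model.train_config) if model.train_config else None,
    }
    arrays = {f"em.{k}": v for k, v in em.params.items()}
    arrays["trans"] = model.crf_params.transition_weights
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(
    path: str | Path, featurizer: Optional[Callable] = None
) -> PeptideCrfModel:
    """Load a checkpoint; supply a featurizer for precomputed embeddings."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
        space = build_state_space(
            meta["space"]["min_len"],
            meta["space"]["max_len"],
            meta["space"]["span_classes"],
        )
        em_meta = meta["emission_model"]
        if em_meta["kind"] == "conv-lstm-conv":
            em = ConvLstmConvEmissionModel(
                em_meta["input_width"],
                conv_width=em_meta["conv_width"],
                kernel_size=em_meta["kernel_size"],
                lstm_hidden=em_meta["lstm_hidden"],
                n_classes=em_meta["n_classes"],
            )
        elif em_meta["kind"] == "linear":
            em = LinearEmissionModel(em_meta["input_width"], em_meta["n_classes"])
        else:
            raise ValueError(f"unknown emission model kind {em_meta['kind']!r}")
        for k in em.params:
            em.params[k] = np.array(data[f"em.{k}"])
        trans = np.array(data["trans"])
    if featurizer is None:
        if meta["featurizer"] != "one-hot":
            raise ValueError(
                f"checkpoint uses featurizer {meta['featurizer']!r}; pass one explicitly"
            )
        featurizer = OneHotFeaturizer()
    cfg = TrainConfig(**meta["train_config"]) if meta.get("train_config") else None
    return PeptideCrfModel(space, em, CrfParameters(trans, space), featurizer, cfg)
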