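"""Per-position feature extraction and emission scoring.

Front-ends turn a protein sequence into a T x D embedding matrix (one-hot
over the ESM tokenizer vocabulary, or precomputed language-model vectors
loaded from an HDF5 container). Emission models map that matrix to a
T x K matrix of class logits (K = 3: None, Peptide, Propeptide) which the
CRF ties across all states of the same class.

All models are plain NumPy with analytic backward passes so the whole
pipeline trains end to end without a deep-learning framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

import h5py
import numpy as np

#: The 33-token vocabulary of the ESM protein language model tokenizer,
#: in its published order: special tokens, amino acids by frequency, rare
#: residue codes, then gap/null/mask tokens. Pinned here so one-hot models
#: are reproducible without the language model installed.
ESM_VOCAB: tuple[str, ...] = (
    "<cls>", "<pad>", "<eos>", "<unk>",
    "L", "A", "G", "V", "S", "E", "R", "T", "I", "D", "P", "K",
    "Q", "N", "F", "Y", "M", "H", "W", "C",
    "X", "B", "U", "Z", "O",
    ".", "-", "<null_1>", "<mask>",
)

UNKNOWN_TOKEN = "<unk>"

_ESM_INDEX = {tok: i for i, tok in enumerate(ESM_VOCAB)}


@dataclass
class EmbeddingMatrix:
    """Per-residue feature vectors for one sequence (T x D)."""

    vectors: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("embedding matrix must be 2-dimensional (T x D)")

    @property
    def length(self) -> int:
        return self.vectors.shape[0]

    @property
    def width(self) -> int:
        return self.vectors.shape[1]


def one_hot_encode(
    sequence: str, vocab: tuple[str, ...] = ESM_VOCAB
) -> EmbeddingMatrix:
    """One-hot encode a sequence over the fixed token vocabulary.

    Residues absent from the vocabulary map to the unknown token. No
    special BOS/EOS rows are added: row ``t`` corresponds 1:1 to residue
    ``t`` of the amino-acid string.
    """
    index = _ESM_INDEX if vocab is ESM_VOCAB else {t: i for i, t in enumerate(vocab)}
    unk = index[UNKNOWN_TOKEN] if UNKNOWN_TOKEN in index else 0
    T, D = len(sequence), len(vocab)
    mat = np.zeros((T, D), dtype=np.float64)
    for t, aa in enumerate(sequence.upper()):
        mat[t, index.get(aa, unk)] = 1.0
    return EmbeddingMatrix(mat, source_tag="one-hot")


def save_embeddings(path: str | Path, arrays: Mapping[str, np.ndarray]) -> None:
    """Write per-sequence T x D float arrays to an HDF5 container."""
    with h5py.File(path, "w") as fh:
        for rid, arr in arrays.items():
            fh.create_dataset(rid, data=np.asarray(arr, dtype=np.float64))


def load_embeddings(path: str | Path, ids: Iterable[str]) -> dict[str, EmbeddingMatrix]:
    """Load precomputed per-residue embeddings for the requested ids.

    Raises ``KeyError`` naming any missing id and ``ValueError`` if the
    stored arrays do not share one embedding width.
    """
    out: dict[str, EmbeddingMatrix] = {}
    with h5py.File(path, "r") as fh:
        missing = [rid for rid in ids if rid not in fh]
        if missing:
            raise KeyError(f"embedding container {path} is missing ids: {missing}")
        width: Optional[int] = None
        for rid in ids:
            arr = np.asarray(fh[rid], dtype=np.float64)
            if arr.ndim != 2:
                raise ValueError(f"entry {rid!r} is not a 2-D array")
            if width is None:
                width = arr.shape[1]
            elif arr.shape[1] != width:
                raise ValueError(
                    f"entry {rid!r} has width {arr.shape[1]}, expected {width}"
                )
            out[rid] = EmbeddingMatrix(arr, source_tag=f"precomputed:{path}")
    return out


# ---------------------------------------------------------------------------
# Emission models
# ---------------------------------------------------------------------------


class EmissionModel:
    """Interface: parameters, forward to T x K logits, analytic backward."""

    params: dict[str, np.ndarray]

    def forward(self, emb: EmbeddingMatrix) -> tuple[np.ndarray, object]:
        raise NotImplementedError

    def backward(self, cache: object, d_scores: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def copy(self) -> "EmissionModel":
        import copy

        return copy.deepcopy(self)


class LinearEmissionModel(EmissionModel):
    """Position-wise linear map from features to class logits.

    Sees a single residue's features at a time, so it cannot exploit
    flanking context; useful as the simplest trainable head and in tests.
    """

    def __init__(self, input_width: int, n_classes: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(input_width)
        self.params = {
            "W": rng.normal(0.0, scale, size=(input_width, n_classes)),
            "b": np.zeros(n_classes),
        }

    def forward(self, emb: EmbeddingMatrix):
        X = emb.vectors
        return X @ self.params["W"] + self.params["b"], X

    def backward(self, cache, d_scores):
        X = cache
        return {"W": X.T @ d_scores, "b": d_scores.sum(axis=0)}


def _conv1d_same(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Width-preserving 1-D convolution over positions.

    X: (T, Din); W: (k, Din, Dout); zero padding of (k-1)//2 on each side.
    Returns (Y, Xpad) with Y (T, Dout).
    """
    k = W.shape[0]
    off = (k - 1) // 2
    T = X.shape[0]
    Xpad = np.zeros((T + k - 1, X.shape[1]))
    Xpad[off : off + T] = X
    Y = np.zeros((T, W.shape[2]))
    for j in range(k):
        Y += Xpad[j : j + T] @ W[j]
    return Y + b, Xpad


def _conv1d_same_backward(
    dY: np.ndarray, Xpad: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = W.shape[0]
    off = (k - 1) // 2
    T = dY.shape[0]
    dW = np.empty_like(W)
    dXpad = np.zeros_like(Xpad)
    for j in range(k):
        dW[j] = Xpad[j : j + T].T @ dY
        dXpad[j : j + T] += dY @ W[j].T
    db = dY.sum(axis=0)
    dX = dXpad[off : off + T]
    return dX, dW, db


def _lstm_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Unidirectional LSTM. X: (T, Din); returns hidden states (T, H) + cache.

    Gate layout along the 4H axis is (input, forget, output, cell-candidate)
    so the three sigmoid gates form one contiguous block. The input
    projection X @ Wx is hoisted out of the time loop; only the recurrent
    term is sequential.
    """
    T = X.shape[0]
    H = Wh.shape[0]
    Xproj = X @ Wx + b  # (T, 4H)
    gates = np.empty((T, 4 * H))
    C = np.empty((T, H))
    Hs = np.empty((T, H))
    h_prev = np.zeros(H)
    c_prev = np.zeros(H)
    for t in range(T):
        a = Xproj[t] + h_prev @ Wh
        a[: 3 * H] = _sigmoid(a[: 3 * H])
        a[3 * H :] = np.tanh(a[3 * H :])
        i, f, o, g = a[:H], a[H : 2 * H], a[2 * H : 3 * H], a[3 * H :]
        c_prev = f * c_prev + i * g
        h_prev = o * np.tanh(c_prev)
        gates[t] = a
        C[t] = c_prev
        Hs[t] = h_prev
    return Hs, (X, gates, C, Hs)


def _lstm_backward(dH_out: np.ndarray, cache, Wx: np.ndarray, Wh: np.ndarray):
    X, gates, C, Hs = cache
    T, H = Hs.shape
    dA = np.empty((T, 4 * H))
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    for t in range(T - 1, -1, -1):
        i, f, o, g = (
            gates[t, :H],
            gates[t, H : 2 * H],
            gates[t, 2 * H : 3 * H],
            gates[t, 3 * H :],
        )
        c_prev = C[t - 1] if t > 0 else 0.0
        tanh_c = np.tanh(C[t])
        dh = dH_out[t] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c**2)
        da = dA[t]
        da[:H] = dc * g * i * (1 - i)
        da[H : 2 * H] = dc * c_prev * f * (1 - f)
        da[2 * H : 3 * H] = do * o * (1 - o)
        da[3 * H :] = dc * i * (1 - g**2)
        dh_next = da @ Wh.T
        dc_next = dc * f
    Hprev = np.vstack([np.zeros((1, H)), Hs[:-1]])
    dWx = X.T @ dA
    dWh = Hprev.T @ dA
    db = dA.sum(axis=0)
    dX = dA @ Wx.T
    return dX, dWx, dWh, db


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class ConvLstmConvEmissionModel(EmissionModel):
    """CNN-BiLSTM-CNN emission network.

    Architecture: (i) a width-preserving convolution block (kernel 3, ReLU)
    over the embedding dimension, (ii) a bidirectional LSTM over positions,
    (iii) a convolution block projecting to the K class logits. Layer
    widths are configurable; defaults are conv width 64 and 64 recurrent
    units per direction.
    """

    def __init__(
        self,
        input_width: int,
        conv_width: int = 64,
        kernel_size: int = 3,
        lstm_hidden: int = 64,
        n_classes: int = 3,
        seed: int = 0,
    ):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd to preserve length")
        self.conv_width = conv_width
        self.kernel_size = kernel_size
        self.lstm_hidden = lstm_hidden
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)

        def glorot(*shape, fan_in):
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

        H = lstm_hidden
        k = kernel_size
        self.params = {
            "conv1_W": glorot(k, input_width, conv_width, fan_in=k * input_width),
            "conv1_b": np.zeros(conv_width),
            "lstm_f_Wx": glorot(conv_width, 4 * H, fan_in=conv_width),
            "lstm_f_Wh": glorot(H, 4 * H, fan_in=H),
            "lstm_f_b": _forget_bias(H),
            "lstm_b_Wx": glorot(conv_width, 4 * H, fan_in=conv_width),
            "lstm_b_Wh": glorot(H, 4 * H, fan_in=H),
            "lstm_b_b": _forget_bias(H),
            "conv2_W": glorot(k, 2 * H, n_classes, fan_in=k * 2 * H),
            "conv2_b": np.zeros(n_classes),
        }

    def forward(self, emb: EmbeddingMatrix):
        p = self.params
        X = emb.vectors
        Z1, Xpad = _conv1d_same(X, p["conv1_W"], p["conv1_b"])
        A1 = np.maximum(Z1, 0.0)
        Hf, cache_f = _lstm_forward(A1, p["lstm_f_Wx"], p["lstm_f_Wh"], p["lstm_f_b"])
        Hb_rev, cache_b = _lstm_forward(
            A1[::-1], p["lstm_b_Wx"], p["lstm_b_Wh"], p["lstm_b_b"]
        )
        Hcat = np.concatenate([Hf, Hb_rev[::-1]], axis=1)
        scores, Hpad = _conv1d_same(Hcat, p["conv2_W"], p["conv2_b"])
        return scores, (Xpad, Z1, cache_f, cache_b, Hpad)

    def backward(self, cache, d_scores):
        p = self.params
        Xpad, Z1, cache_f, cache_b, Hpad = cache
        H = self.lstm_hidden
        dHcat, dconv2_W, dconv2_b = _conv1d_same_backward(d_scores, Hpad, p["conv2_W"])
        dHf = dHcat[:, :H]
        dHb = dHcat[:, H:][::-1]
        dA1_f, dWx_f, dWh_f, db_f = _lstm_backward(
            dHf, cache_f, p["lstm_f_Wx"], p["lstm_f_Wh"]
        )
        dA1_b_rev, dWx_b, dWh_b, db_b = _lstm_backward(
            dHb, cache_b, p["lstm_b_Wx"], p["lstm_b_Wh"]
        )
        dA1 = dA1_f + dA1_b_rev[::-1]
        dZ1 = dA1 * (Z1 > 0)
        _, dconv1_W, dconv1_b = _conv1d_same_backward(dZ1, Xpad, p["conv1_W"])
        return {
            "conv1_W": dconv1_W,
            "conv1_b": dconv1_b,
            "lstm_f_Wx": dWx_f,
            "lstm_f_Wh": dWh_f,
            "lstm_f_b": db_f,
            "lstm_b_Wx": dWx_b,
            "lstm_b_Wh": dWh_b,
            "lstm_b_b": db_b,
            "conv2_W": dconv2_W,
            "conv2_b": dconv2_b,
        }


def _forget_bias(H: int) -> np.ndarray:
    # forget gate initialized open; stabilizes early BPTT
    b = np.zeros(4 * H)
    b[H : 2 * H] = 1.0
    return b


def emission_network_forward(emb: EmbeddingMatrix, model: ConvLstmConvEmissionModel) -> np.ndarray:
    """Functional wrapper: run the emission network, return T x K logits."""
    scores, _ = model.forward(emb)
    return scores


# ---------------------------------------------------------------------------
# Featurizers: record -> EmbeddingMatrix front-ends
# ---------------------------------------------------------------------------


class OneHotFeaturizer:
    """Encode each record's sequence as one-hot rows over the 33-token vocab."""

    name = "one-hot"
    width = len(ESM_VOCAB)

    def __call__(self, record) -> EmbeddingMatrix:
        return one_hot_encode(record.sequence)


class PrecomputedFeaturizer:
    """Serve precomputed embeddings keyed by record id."""

    name = "precomputed"

    def __init__(self, embeddings: Mapping[str, EmbeddingMatrix]):
        self.embeddings = dict(embeddings)
        widths = {e.width for e in self.embeddings.values()}
        if len(widths) > 1:
            raise ValueError(f"inconsistent embedding widths: {sorted(widths)}")
        self.width = widths.pop() if widths else 0

    def __call__(self, record) -> EmbeddingMatrix:
        try:
            emb = self.embeddings[record.id]
        except KeyError:
            raise KeyError(f"no precomputed embedding for record {record.id!r}")
        if emb.length != len(record.sequence):
            raise ValueError(
                f"embedding length {emb.length} != sequence length "
                f"{len(record.sequence)} for record {record.id!r}"
            )
        return emb
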