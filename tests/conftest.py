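"""Shared fixtures and the brute-force path-enumeration oracle.

The oracle scores every mask-valid state path explicitly from the raw
mask arrays and class map, independently of the dynamic programs it
checks. It is only feasible for tiny instances (T <= 8, few states).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from peptidecrf.state_space import StateSpace, build_state_space


def enumerate_valid_paths(space: StateSpace, T: int) -> list[tuple[int, ...]]:
    """All state paths respecting initial/transition/final masks."""
    paths = []
    starts = np.nonzero(space.allowed_initial)[0]
    finals = set(np.nonzero(space.allowed_final)[0].tolist())

    def extend(prefix):
        if len(prefix) == T:
            if prefix[-1] in finals:
                paths.append(tuple(prefix))
            return
        for nxt in np.nonzero(space.allowed_transition[prefix[-1]])[0]:
            extend(prefix + [int(nxt)])

    for s in starts:
        extend([int(s)])
    return paths


def oracle_path_score(e: np.ndarray, trans_weights: np.ndarray, space: StateSpace,
                      path: tuple[int, ...]) -> float:
    score = sum(e[t, space.class_of_state[s]] for t, s in enumerate(path))
    score += sum(trans_weights[path[t], path[t + 1]] for t in range(len(path) - 1))
    return float(score)


def oracle_log_partition(e, trans_weights, space) -> float:
    paths = enumerate_valid_paths(space, e.shape[0])
    scores = [oracle_path_score(e, trans_weights, space, p) for p in paths]
    m = max(scores)
    return m + math.log(sum(math.exp(s - m) for s in scores))


def oracle_best(e, trans_weights, space):
    """(best score, all argmax paths) by enumeration."""
    paths = enumerate_valid_paths(space, e.shape[0])
    scores = [oracle_path_score(e, trans_weights, space, p) for p in paths]
    best = max(scores)
    argmax = [p for p, s in zip(paths, scores) if abs(s - best) < 1e-9]
    return best, argmax


def oracle_class_marginals(e, trans_weights, space) -> np.ndarray:
    """Exact per-position class posteriors by enumeration."""
    T = e.shape[0]
    paths = enumerate_valid_paths(space, T)
    scores = np.array([oracle_path_score(e, trans_weights, space, p) for p in paths])
    w = np.exp(scores - scores.max())
    w /= w.sum()
    K = space.n_classes
    out = np.zeros((T, K))
    for p, wi in zip(paths, w):
        for t, s in enumerate(p):
            out[t, space.class_of_state[s]] += wi
    return out


@pytest.fixture(scope="session")
def paper_space() -> StateSpace:
    return build_state_space(5, 50, ["Peptide", "Propeptide"])


@pytest.fixture
def tiny_space() -> StateSpace:
    """Small space (min 2, max 3, one class) where enumeration is cheap."""
    return build_state_space(2, 3, ["Peptide"])


@pytest.fixture
def two_class_tiny_space() -> StateSpace:
    return build_state_space(2, 4, ["Peptide", "Propeptide"])
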