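"""Constrained state-space layout for length-bounded span labeling.

The label grammar has one background state ("None") plus, for every span
class, one state per within-span position 1..max_len. Transitions are
restricted so that every decoded span has length in [min_len, max_len] and
no path ever steps directly between states of different span classes.
For two span classes and max_len = 50 this yields 101 states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NONE_CLASS = "None"
NEG_INF = -np.inf


@dataclass(frozen=True)
class StateSpace:
    """State layout and allowed-transition structure.

    State 0 is the background ("None") state. State ``1 + c*max_len + (p-1)``
    is position ``p`` (1-based within the span) of span class ``c`` (0-based
    index into ``span_classes``).
    """

    min_len: int
    max_len: int
    span_classes: tuple[str, ...]
    n_states: int
    class_of_state: np.ndarray  # (S,) int: 0 = None, 1 + class index otherwise
    position_of_state: np.ndarray  # (S,) int: 0 for None, else 1..max_len
    allowed_transition: np.ndarray  # (S, S) bool
    allowed_initial: np.ndarray  # (S,) bool
    allowed_final: np.ndarray  # (S,) bool

    @property
    def n_classes(self) -> int:
        """Number of emission classes (background + span classes)."""
        return 1 + len(self.span_classes)

    @property
    def class_names(self) -> tuple[str, ...]:
        return (NONE_CLASS,) + self.span_classes

    def state_index(self, span_class: str, position: int) -> int:
        if span_class == NONE_CLASS:
            return 0
        c = self.span_classes.index(span_class)
        if not 1 <= position <= self.max_len:
            raise ValueError(f"position {position} outside 1..{self.max_len}")
        return 1 + c * self.max_len + (position - 1)


def build_state_space(
    min_len: int,
    max_len: int,
    span_classes: list[str] | tuple[str, ...],
    allow_same_class_adjacency: bool = True,
    allow_boundary_spans: bool = True,
) -> StateSpace:
    """Construct the constrained state space.

    Allowed transitions:

    * ``None -> None`` and ``None -> (c, 1)`` for every class ``c``;
    * within-span continuation ``(c, p) -> (c, p+1)`` for ``p < max_len``;
    * span exit ``(c, p) -> None`` for ``p >= min_len``;
    * tandem same-class spans ``(c, p) -> (c, 1)`` for ``p >= min_len``
      (disabled by ``allow_same_class_adjacency=False``).

    Cross-class adjacency is never allowed. With ``allow_boundary_spans``
    (default) a sequence may start at ``(c, 1)`` and end at any ``(c, p)``
    with ``p >= min_len``; otherwise spans must be flanked by background.
    """
    if min_len < 1 or min_len > max_len:
        raise ValueError(f"need 1 <= min_len <= max_len, got ({min_len}, {max_len})")
    span_classes = tuple(span_classes)
    if not span_classes:
        raise ValueError("at least one span class is required")
    if NONE_CLASS in span_classes:
        raise ValueError(f"{NONE_CLASS!r} is reserved for the background state")

    n_classes = len(span_classes)
    n_states = 1 + n_classes * max_len
    class_of_state = np.zeros(n_states, dtype=np.int64)
    position_of_state = np.zeros(n_states, dtype=np.int64)
    for c in range(n_classes):
        for p in range(1, max_len + 1):
            s = 1 + c * max_len + (p - 1)
            class_of_state[s] = c + 1
            position_of_state[s] = p

    allowed = np.zeros((n_states, n_states), dtype=bool)
    allowed[0, 0] = True
    for c in range(n_classes):
        first = 1 + c * max_len
        allowed[0, first] = True
        for p in range(1, max_len + 1):
            s = first + (p - 1)
            if p < max_len:
                allowed[s, s + 1] = True
            if p >= min_len:
                allowed[s, 0] = True
                if allow_same_class_adjacency:
                    allowed[s, first] = True

    initial = np.zeros(n_states, dtype=bool)
    final = np.zeros(n_states, dtype=bool)
    initial[0] = True
    final[0] = True
    if allow_boundary_spans:
        for c in range(n_classes):
            first = 1 + c * max_len
            initial[first] = True
            final[first + min_len - 1 : first + max_len] = True

    cos = class_of_state
    return StateSpace(
        min_len=min_len,
        max_len=max_len,
        span_classes=span_classes,
        n_states=n_states,
        class_of_state=cos,
        position_of_state=position_of_state,
        allowed_transition=allowed,
        allowed_initial=initial,
        allowed_final=final,
    )


def transition_mask(space: StateSpace) -> np.ndarray:
    """Additive mask: 0 on allowed transitions, -inf on forbidden ones."""
    mask = np.where(space.allowed_transition, 0.0, NEG_INF)
    return mask


def initial_mask(space: StateSpace) -> np.ndarray:
    return np.where(space.allowed_initial, 0.0, NEG_INF)


def final_mask(space: StateSpace) -> np.ndarray:
    return np.where(space.allowed_final, 0.0, NEG_INF)
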