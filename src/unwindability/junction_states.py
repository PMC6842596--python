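"""Per-frame junction states and base-pair opening/closing events.

Base-pair opening at an ss/ds junction is a stepwise process: one of the
two bases unpairs and unstacks first ("flips out"), leaving a
dangling-base intermediate, before the partner unstacks and completes
the opening.  This module turns trajectory distance channels into a
discrete state per frame for every base pair,

    CLOSED -> FLIP5 (5'-terminus base out, 3'-dangling intermediate)
           -> FLIP3 (3'-terminus base out, 5'-dangling intermediate)
           -> OPEN,

and segments the state series into opening/closing events labeled by
their pathway and nearest-neighbor (NN) sequence context.

Three distance channels are monitored per junction position k:
pairing (WC donor-acceptor atoms of pair k), 5'-stacking (base-ring
centroids of chain-1 residues k and k+1) and 3'-stacking (chain-2
partner and its inward neighbor).  A channel counts as disrupted when
its smoothed value exceeds the native value by a threshold offset, with
hysteresis to suppress chatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .helix_builder import NativeStructure

__all__ = [
    "StateThresholds",
    "JunctionStateSeries",
    "OpeningEvent",
    "CLOSED",
    "FLIP5",
    "FLIP3",
    "OPEN",
    "pairing_distance",
    "stacking_distance",
    "smooth",
    "compute_channels",
    "assign_states",
    "extract_events",
]

CLOSED, FLIP5, FLIP3, OPEN = 0, 1, 2, 3
STATE_NAMES = {CLOSED: "CLOSED", FLIP5: "FLIP5", FLIP3: "FLIP3", OPEN: "OPEN"}


def pairing_distance(frame: np.ndarray, structure: NativeStructure, pair: int) -> float:
    """WC donor-acceptor (purine N1 - pyrimidine N3) distance of a pair, A."""
    i, j = structure.wc_atom_indices(pair)
    return float(np.linalg.norm(np.asarray(frame)[i] - np.asarray(frame)[j]))


def stacking_distance(
    frame: np.ndarray,
    structure: NativeStructure,
    base_i: Tuple[str, int],
    base_j: Tuple[str, int],
) -> float:
    """Distance between two base-ring centroids, A."""
    if base_i == base_j:
        raise ValueError("stacking distance of a base with itself")
    ci = structure.base_centroid(*base_i, coords=np.asarray(frame))
    cj = structure.base_centroid(*base_j, coords=np.asarray(frame))
    return float(np.linalg.norm(ci - cj))


def smooth(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the boundaries so
    the output has the same length as the input."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    if window == 1 or len(x) == 0:
        return x.copy()
    half = window // 2
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (window - 1 - half), n - 1)
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def compute_channels(frames: np.ndarray, structure: NativeStructure) -> Dict[str, np.ndarray]:
    """Raw distance channels of a frame stack.

    Returns 'pairing' (n_frames, N), 'stack5' and 'stack3'
    (n_frames, N-1); identical to what the engine records on the fly.
    """
    F = np.asarray(frames)
    n = structure.n_pairs
    wc = np.array([structure.wc_atom_indices(k) for k in range(1, n + 1)])
    pairing = np.linalg.norm(F[:, wc[:, 0], :] - F[:, wc[:, 1], :], axis=2)

    def centroids(chain: str, resi: int) -> np.ndarray:
        idx = structure.base_atom_indices(chain, resi)
        return F[:, idx, :].mean(axis=1)

    cenA = {k: centroids("A", k) for k in range(1, n + 1)}
    cenB = {k: centroids("B", k) for k in range(1, n + 1)}
    s5 = np.stack([np.linalg.norm(cenA[k] - cenA[k + 1], axis=1) for k in range(1, n)], axis=1)
    s3 = np.stack([np.linalg.norm(cenB[n + 1 - k] - cenB[n - k], axis=1) for k in range(1, n)], axis=1)
    return {"pairing": pairing, "stack5": s5, "stack3": s3}


@dataclass(frozen=True)
class StateThresholds:
    """Disruption thresholds relative to the native channel values (A).

    A channel becomes disrupted when its smoothed value exceeds
    native + offset, and recovers below native + offset - hysteresis.
    The stacking offset is larger than the pairing offset because the
    pulling force stretches the junction stack geometry even while the
    pair is closed.  A base counts as flipped out only when it is both
    unpaired and unstacked (require_unpaired), matching the stepwise
    opening mechanism.
    """

    pairing_offset: float = 2.5
    stack_offset: float = 3.0
    hysteresis: float = 0.5
    require_unpaired: bool = True

    def __post_init__(self) -> None:
        if self.pairing_offset <= 0 or self.stack_offset <= 0:
            raise ValueError("offsets must be positive")
        if not (0 <= self.hysteresis < min(self.pairing_offset, self.stack_offset)):
            raise ValueError("need 0 <= hysteresis < offset")


@dataclass
class JunctionStateSeries:
    """Discrete junction description of every saved frame."""

    pair_states: np.ndarray  # (n_frames, n_pairs) int8
    junction: np.ndarray  # (n_frames,) first non-OPEN pair, n_pairs+1 if none
    states: np.ndarray  # (n_frames,) state of the junction pair (OPEN if past end)
    contexts: List[Optional[str]]  # NN context per pair position (None for the last)
    window: int
    thresholds: StateThresholds
    channels_smoothed: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.junction)

    @property
    def n_pairs(self) -> int:
        return self.pair_states.shape[1]

    def occupancy(self) -> Dict[str, float]:
        vals, counts = np.unique(self.states, return_counts=True)
        return {STATE_NAMES[int(v)]: c / len(self.states) for v, c in zip(vals, counts)}


def _hysteresis_flags(x: np.ndarray, on: float, off: float) -> np.ndarray:
    """Boolean series: True once x exceeds `on`, back False below `off`."""
    flags = np.empty(len(x), dtype=bool)
    state = False
    for i, v in enumerate(x):
        if state:
            if v < off:
                state = False
        else:
            if v > on:
                state = True
        flags[i] = state
    return flags


def assign_states(
    channels: Dict[str, np.ndarray],
    structure: NativeStructure,
    thresholds: StateThresholds | None = None,
    window: int = 300,
) -> JunctionStateSeries:
    """Classify every base pair of every frame from its distance channels.

    CLOSED: pairing and both stacking channels native-like; FLIP5/FLIP3:
    exactly one base's stacking channel disrupted (5'-terminus base for
    FLIP5, which leaves a 3'-dangling intermediate); OPEN: both
    disrupted.  The junction is the first pair, counting from the pulled
    end, that is not OPEN.
    """
    if thresholds is None:
        thresholds = StateThresholds()
    pairing = np.asarray(channels["pairing"], dtype=float)
    s5 = np.asarray(channels["stack5"], dtype=float)
    s3 = np.asarray(channels["stack3"], dtype=float)
    n_frames, n_pairs = pairing.shape
    if s5.shape[1] != n_pairs - 1:
        raise ValueError("stacking channels must cover n_pairs - 1 junction positions")

    native = compute_channels(structure.coords[None, :, :], structure)

    def flags(raw: np.ndarray, nat: np.ndarray, offset: float) -> np.ndarray:
        out = np.empty(raw.shape, dtype=bool)
        for k in range(raw.shape[1]):
            sm = smooth(raw[:, k], window)
            on = nat[0, k] + offset
            off = on - thresholds.hysteresis
            out[:, k] = _hysteresis_flags(sm, on, off)
        return out

    pair_broken = flags(pairing, native["pairing"], thresholds.pairing_offset)
    f5 = flags(s5, native["stack5"], thresholds.stack_offset)
    f3 = flags(s3, native["stack3"], thresholds.stack_offset)

    pair_states = np.empty((n_frames, n_pairs), dtype=np.int8)
    for k in range(n_pairs):
        if k < n_pairs - 1:
            b5, b3 = f5[:, k], f3[:, k]
        else:
            # the innermost pair has no inward stacking channels; treat its
            # pairing as the only criterion
            b5 = pair_broken[:, k]
            b3 = pair_broken[:, k]
        if thresholds.require_unpaired:
            b5 = b5 & pair_broken[:, k]
            b3 = b3 & pair_broken[:, k]
        st = np.full(n_frames, CLOSED, dtype=np.int8)
        st[b5 & ~b3] = FLIP5
        st[~b5 & b3] = FLIP3
        st[b5 & b3] = OPEN
        pair_states[:, k] = st

    not_open = pair_states != OPEN
    junction = np.where(not_open.any(axis=1), not_open.argmax(axis=1) + 1, n_pairs + 1)
    states = np.where(
        junction <= n_pairs,
        pair_states[np.arange(n_frames), np.minimum(junction, n_pairs) - 1],
        OPEN,
    ).astype(np.int8)

    contexts: List[Optional[str]] = [
        structure.nn_context(k) if k < n_pairs else None for k in range(1, n_pairs + 1)
    ]
    smoothed = {
        "pairing": np.stack([smooth(pairing[:, k], window) for k in range(n_pairs)], axis=1),
        "stack5": np.stack([smooth(s5[:, k], window) for k in range(n_pairs - 1)], axis=1),
        "stack3": np.stack([smooth(s3[:, k], window) for k in range(n_pairs - 1)], axis=1),
    }
    return JunctionStateSeries(
        pair_states=pair_states,
        junction=junction,
        states=states,
        contexts=contexts,
        window=window,
        thresholds=thresholds,
        channels_smoothed=smoothed,
    )


@dataclass(frozen=True)
class OpeningEvent:
    direction: str  # 'opening' | 'closing'
    pathway: str  # 'via_FLIP5' | 'via_FLIP3' | 'direct'
    context: Optional[str]
    pair: int  # 1-based pair index
    start: int  # frame of the last terminal state before the transit
    end: int  # frame of the first opposite terminal state

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("event must span at least one frame")


def _debounce(states: np.ndarray, min_dwell: int) -> np.ndarray:
    """Merge dwells shorter than min_dwell into the preceding state."""
    if min_dwell <= 1:
        return states
    out = states.copy()
    cur = out[0]
    i = 0
    n = len(out)
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if j - i < min_dwell and i > 0:
            out[i:j] = cur
        else:
            cur = out[i]
        i = j
    return out


def extract_events(
    series: JunctionStateSeries,
    min_dwell: int | None = None,
    junction_only: bool = True,
) -> List[OpeningEvent]:
    """Segment each pair's state series into opening/closing events.

    An event is a CLOSED -> OPEN transit (or the reverse); the pathway
    is the intermediate with the longest dwell during the transit, or
    'direct' on an exact tie.  Excursions that return to the starting
    terminal state are discarded.  Dwells shorter than `min_dwell`
    frames (default: one smoothing window) are merged away first.

    With junction_only (default), an event is kept only when the pair
    was the junction pair of the pulled-side ss/ds boundary at its
    closed terminus, so far-end fraying and interior-bubble excursions -
    whose NN context orientation would differ - are excluded.
    """
    if min_dwell is None:
        min_dwell = series.window
    events: List[OpeningEvent] = []
    for k in range(1, series.n_pairs + 1):
        st = _debounce(series.pair_states[:, k - 1].copy(), min_dwell)
        ctx = series.contexts[k - 1]
        last_terminal = None  # (state, frame)
        dwell5 = dwell3 = 0
        for i, s in enumerate(st):
            if s == FLIP5:
                dwell5 += 1
                continue
            if s == FLIP3:
                dwell3 += 1
                continue
            # s is terminal (CLOSED or OPEN)
            if last_terminal is not None and s != last_terminal[0]:
                if dwell5 > dwell3:
                    path = "via_FLIP5"
                elif dwell3 > dwell5:
                    path = "via_FLIP3"
                else:
                    path = "direct"
                direction = "opening" if s == OPEN else "closing"
                closed_end = last_terminal[1] if direction == "opening" else i
                if not junction_only or series.junction[closed_end] == k:
                    events.append(OpeningEvent(direction, path, ctx, k, last_terminal[1], i))
            last_terminal = (s, i)
            dwell5 = dwell3 = 0
    events.sort(key=lambda e: e.end)
    return events
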