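"""Pseudorandom trial-sequence generation for grasp-and-lift sessions.

A session interleaves light and heavy target objects with occasional
medium-weight dummy objects.  A trial is *analyzable* only when both it and
its predecessor are light/heavy targets, so its previous-weight /
current-weight order pair (LL, HL, LH, HH) is defined.  The generator
produces sequences in which every order pair occurs exactly
``n_reps_per_cell`` times for each of the three stimulation conditions
(dynamic, static, none), and dummy trials are never first, last, or
adjacent to one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd


class ObjectKind(str, Enum):
    LIGHT = "light"
    HEAVY = "heavy"
    MEDIUM = "medium"  # dummy weight
    PRACTICE = "practice"


class TmsCondition(str, Enum):
    DYNAMIC = "dynamic"
    STATIC = "static"
    NONE = "none"


class OrderPair(str, Enum):
    LL = "LL"
    HL = "HL"
    LH = "LH"
    HH = "HH"
    UNDEFINED = "undefined"


#: order pair label keyed by (previous object, current object)
_PAIR_CODE = {
    (ObjectKind.LIGHT, ObjectKind.LIGHT): OrderPair.LL,
    (ObjectKind.HEAVY, ObjectKind.LIGHT): OrderPair.HL,
    (ObjectKind.LIGHT, ObjectKind.HEAVY): OrderPair.LH,
    (ObjectKind.HEAVY, ObjectKind.HEAVY): OrderPair.HH,
}

ANALYZABLE_PAIRS = (OrderPair.LL, OrderPair.HL, OrderPair.LH, OrderPair.HH)
CONDITIONS = (TmsCondition.DYNAMIC, TmsCondition.STATIC, TmsCondition.NONE)


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial of a session."""

    index: int  # 1-based position in the session
    object: ObjectKind
    tms_condition: TmsCondition
    order_pair: OrderPair
    analyzable: bool

    def __post_init__(self) -> None:
        defined = self.order_pair is not OrderPair.UNDEFINED
        if self.analyzable != defined:
            raise ValueError("analyzable must be true iff order pair is defined")


@dataclass
class SessionDesign:
    """An ordered trial sequence plus the parameters that generated it."""

    trials: list[TrialSpec]
    seed: int
    n_reps_per_cell: int = 10

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_analyzable(self) -> int:
        return sum(t.analyzable for t in self.trials)

    @property
    def n_dummies(self) -> int:
        return sum(t.object is ObjectKind.MEDIUM for t in self.trials)

    def cell_counts(self) -> dict[tuple[OrderPair, TmsCondition], int]:
        counts: dict[tuple[OrderPair, TmsCondition], int] = {
            (p, c): 0 for p in ANALYZABLE_PAIRS for c in CONDITIONS
        }
        for t in self.trials:
            if t.analyzable:
                counts[(t.order_pair, t.tms_condition)] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "object": [t.object.value for t in self.trials],
                "tms_condition": [t.tms_condition.value for t in self.trials],
                "order_pair": [t.order_pair.value for t in self.trials],
                "analyzable": [t.analyzable for t in self.trials],
            }
        )


def label_order_pairs(objects: list[ObjectKind | str]) -> list[OrderPair]:
    """Label each trial with its (previous, current) order pair.

    The first trial, dummy/practice trials, and trials following a dummy or
    practice object all get :attr:`OrderPair.UNDEFINED`.
    """
    if len(objects) == 0:
        raise ValueError("object list must be non-empty")
    objs = [ObjectKind(o) for o in objects]
    labels = [OrderPair.UNDEFINED]
    for prev, cur in zip(objs[:-1], objs[1:]):
        labels.append(_PAIR_CODE.get((prev, cur), OrderPair.UNDEFINED))
    return labels


def default_dummy_count(n_reps_per_cell: int) -> int:
    """Dummy-trial count scaled from the reference design (14 at 10 reps)."""
    return max(1, round(1.4 * n_reps_per_cell))


def _walk_feasible(state: ObjectKind, counts: dict[str, int]) -> bool:
    # Remaining transition counts admit a completing walk from `state`.
    cross = counts["LH"] - counts["HL"]
    if state is ObjectKind.LIGHT:
        return cross in (0, 1) and (counts["HH"] == 0 or counts["LH"] > 0)
    return cross in (-1, 0) and (counts["LL"] == 0 or counts["HL"] > 0)


def _sample_walk(
    counts: dict[str, int], rng: np.random.Generator
) -> list[ObjectKind] | None:
    """Sample a light/heavy walk realizing exact transition counts.

    Transitions are drawn proportionally to their remaining counts, with a
    one-step feasibility lookahead; for a two-state walk this never dead-ends
    once a feasible start state exists.
    """
    counts = dict(counts)
    cross = counts["LH"] - counts["HL"]
    if abs(cross) > 1:
        return None
    if cross == 1:
        state = ObjectKind.LIGHT
    elif cross == -1:
        state = ObjectKind.HEAVY
    else:
        choices = [
            s
            for s in (ObjectKind.LIGHT, ObjectKind.HEAVY)
            if _walk_feasible(s, counts)
        ]
        if not choices:
            return None
        state = choices[rng.integers(len(choices))]

    out = {ObjectKind.LIGHT: ("LL", "LH"), ObjectKind.HEAVY: ("HL", "HH")}
    dest = {"LL": ObjectKind.LIGHT, "LH": ObjectKind.HEAVY,
            "HL": ObjectKind.LIGHT, "HH": ObjectKind.HEAVY}
    walk = [state]
    n_left = sum(counts.values())
    for _ in range(n_left):
        candidates = []
        weights = []
        for trans in out[state]:
            if counts[trans] == 0:
                continue
            counts[trans] -= 1
            if _walk_feasible(dest[trans], counts):
                candidates.append(trans)
                weights.append(counts[trans] + 1)
            counts[trans] += 1
        if not candidates:
            return None
        w = np.asarray(weights, dtype=float)
        trans = candidates[rng.choice(len(candidates), p=w / w.sum())]
        counts[trans] -= 1
        state = dest[trans]
        walk.append(state)
    return walk


def generate_session(
    seed: int,
    n_reps_per_cell: int = 10,
    include_practice: bool = False,
    n_dummies: int | None = None,
    max_retries: int = 10_000,
) -> SessionDesign:
    """Generate one pseudorandom session satisfying the design constraints.

    Parameters
    ----------
    seed
        Seed for the sequence generator; identical seeds give identical
        sessions.
    n_reps_per_cell
        Analyzable repetitions per (order pair x stimulation condition)
        cell.  The reference design uses 10, giving 120 analyzable trials,
        14 dummies and 149 trials in total.
    include_practice
        Prepend five practice trials, two of which carry stimulation (one
        dynamic, one static).  Practice trials are never analyzable.
    n_dummies
        Override the dummy-trial count (defaults to the 10%-of-session rule
        scaled from the reference design).
    max_retries
        Cap on constrained rejection-sampling attempts.
    """
    if n_reps_per_cell < 1:
        raise ValueError("n_reps_per_cell must be >= 1")
    r = n_reps_per_cell
    d = default_dummy_count(r) if n_dummies is None else n_dummies
    if d < 1:
        raise ValueError("at least one dummy trial is required")
    rng = np.random.default_rng(seed)

    walk = None
    for _ in range(max_retries):
        extra = rng.multinomial(d, [0.25] * 4)
        counts = {
            "LL": 3 * r + int(extra[0]),
            "HL": 3 * r + int(extra[1]),
            "LH": 3 * r + int(extra[2]),
            "HH": 3 * r + int(extra[3]),
        }
        walk = _sample_walk(counts, rng)
        if walk is not None:
            break
    if walk is None:
        raise RuntimeError(
            f"no valid sequence found in {max_retries} attempts "
            f"(n_reps_per_cell={r}, n_dummies={d})"
        )

    # Cut the walk's surplus transitions by inserting a dummy into the
    # matching gaps: for each pair type, exactly the `extra` transitions
    # beyond the required 3r are cut.  Distinct interior gaps guarantee no
    # dummy is first, last, or adjacent to another dummy.
    pair_of_gap: dict[str, list[int]] = {"LL": [], "HL": [], "LH": [], "HH": []}
    code = {
        (ObjectKind.LIGHT, ObjectKind.LIGHT): "LL",
        (ObjectKind.HEAVY, ObjectKind.LIGHT): "HL",
        (ObjectKind.LIGHT, ObjectKind.HEAVY): "LH",
        (ObjectKind.HEAVY, ObjectKind.HEAVY): "HH",
    }
    for i in range(1, len(walk)):
        pair_of_gap[code[(walk[i - 1], walk[i])]].append(i)
    gap_set: set[int] = set()
    for ptype, n_cut in zip(("LL", "HL", "LH", "HH"), extra):
        chosen = rng.choice(pair_of_gap[ptype], size=int(n_cut), replace=False)
        gap_set.update(int(g) for g in chosen)
    objects: list[ObjectKind] = []
    for i, obj in enumerate(walk):
        if i in gap_set:
            objects.append(ObjectKind.MEDIUM)
        objects.append(obj)

    if include_practice:
        objects = [ObjectKind.PRACTICE] * 5 + objects
    pairs = label_order_pairs(objects)

    # Assign stimulation conditions: exactly r per condition within each
    # order pair among analyzable trials; random elsewhere.
    queues: dict[OrderPair, list[TmsCondition]] = {}
    for pair in ANALYZABLE_PAIRS:
        n_pair = sum(p is pair for p in pairs)
        if n_pair != 3 * r:
            raise RuntimeError("internal error: order-pair count mismatch")
        seq = list(CONDITIONS) * r
        rng.shuffle(seq)  # type: ignore[arg-type]
        queues[pair] = seq

    conditions: list[TmsCondition] = []
    for obj, pair in zip(objects, pairs):
        if pair is not OrderPair.UNDEFINED:
            conditions.append(queues[pair].pop())
        else:
            conditions.append(CONDITIONS[rng.integers(3)])

    if include_practice:
        # exactly one dynamic and one static stimulation among practice
        practice_conds = [
            TmsCondition.DYNAMIC,
            TmsCondition.STATIC,
            TmsCondition.NONE,
            TmsCondition.NONE,
            TmsCondition.NONE,
        ]
        rng.shuffle(practice_conds)  # type: ignore[arg-type]
        conditions[:5] = practice_conds

    trials = [
        TrialSpec(
            index=i + 1,
            object=obj,
            tms_condition=cond,
            order_pair=pair,
            analyzable=pair is not OrderPair.UNDEFINED,
        )
        for i, (obj, cond, pair) in enumerate(zip(objects, conditions, pairs))
    ]
    return SessionDesign(trials=trials, seed=seed, n_reps_per_cell=r)
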