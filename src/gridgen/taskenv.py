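"""Grid-world navigation task designs, trial generation, and environment dynamics.

The tasks are 6x6 grid worlds in which an agent must reach one of several
labeled goal squares. Each trial belongs to a *context* (cued by color) that
fixes (a) which goal is rewarded and (b) the "mapping" — which keyboard keys
produce which cardinal movement. Three experiment designs manipulate the
statistical relationship between mappings and rewarded goals across contexts,
quantified by the normalized mutual information (NMI) between the two.

Coordinate convention: cells are ``(col, row)`` with origin ``(0, 0)`` at the
north-west corner; ``E`` increments ``col`` and ``S`` increments ``row``.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

GRID_SIZE = 6

#: Cardinal movements available for planning.
MOVES = ("N", "S", "E", "W")

#: Observable outcomes of a keypress: a cardinal movement or no movement at
#: all (keys of the inactive hand do nothing).
KEY_OUTCOMES = ("N", "S", "E", "W", "NONE")

#: The eight response keys, left hand then right hand.
KEYS = ("a", "s", "d", "f", "j", "k", "l", ";")
LEFT_KEYS = KEYS[:4]
RIGHT_KEYS = KEYS[4:]

#: The two admissible left-to-right orderings of movements over one hand's keys.
MAPPING_PATTERNS = {
    "WNSE": ("W", "N", "S", "E"),
    "NWES": ("N", "W", "E", "S"),
}

_DELTAS = {"N": (0, -1), "S": (0, 1), "E": (1, 0), "W": (-1, 0), "NONE": (0, 0)}


class DesignError(ValueError):
    """Raised for invalid design requests or unbalanceable sequences."""


@dataclass(frozen=True)
class KeyMapping:
    """A deterministic assignment of the 8 keys to movements.

    Exactly the four keys of one hand map bijectively onto {N, S, E, W}
    following one of the two admissible left-to-right patterns; the other
    hand's keys produce no movement.
    """

    mapping_id: str
    hand: str  # "left" | "right"
    pattern: str  # key of MAPPING_PATTERNS

    @property
    def assignment(self) -> dict[str, str]:
        active = LEFT_KEYS if self.hand == "left" else RIGHT_KEYS
        inactive = RIGHT_KEYS if self.hand == "left" else LEFT_KEYS
        out = dict(zip(active, MAPPING_PATTERNS[self.pattern]))
        out.update({k: "NONE" for k in inactive})
        return out

    def __post_init__(self):
        if self.hand not in ("left", "right"):
            raise DesignError(f"unknown hand {self.hand!r}")
        if self.pattern not in MAPPING_PATTERNS:
            raise DesignError(f"unknown mapping pattern {self.pattern!r}")


@dataclass(frozen=True)
class ContextSpec:
    """One context: a mapping, a single rewarded goal, and its trial count."""

    context_id: int
    mapping_id: str
    rewarded_goal: str
    phase: str  # "training" | "test"
    n_trials: int


@dataclass
class GridWorld:
    """A 6x6 grid instance: wall edges and labeled goal cells."""

    width: int = GRID_SIZE
    height: int = GRID_SIZE
    walls: frozenset = frozenset()  # frozenset of frozenset({cell, cell}) pairs
    goal_cells: dict = field(default_factory=dict)  # label -> (col, row)

    def __post_init__(self):
        if (self.width, self.height) != (GRID_SIZE, GRID_SIZE):
            raise DesignError("grid worlds are exactly 6x6")
        cells = list(self.goal_cells.values())
        if len(set(cells)) != len(cells):
            raise DesignError("goal cells must be pairwise distinct")
        for edge in self.walls:
            a, b = tuple(edge)
            if not (_in_bounds(a) and _in_bounds(b)) or not _adjacent(a, b):
                raise DesignError(f"wall {a}-{b} does not join adjacent in-bounds cells")


@dataclass(frozen=True)
class TrialSpec:
    """One trial's grid instance with its context and start cell."""

    trial_index: int
    context_id: int
    grid: GridWorld
    start_cell: tuple
    phase: str


@dataclass
class ExperimentDesign:
    """Full specification of one experiment's contexts and trial counts."""

    experiment: str  # "1_repeat" | "1_switch" | "2" | "3"
    goal_labels: tuple
    mappings: dict  # mapping_id -> KeyMapping
    training_contexts: list
    test_contexts: list

    @property
    def n_train_trials(self) -> int:
        return sum(c.n_trials for c in self.training_contexts)

    @property
    def n_test_trials(self) -> int:
        return sum(c.n_trials for c in self.test_contexts)

    @property
    def contexts(self) -> list:
        return self.training_contexts + self.test_contexts

    def context(self, context_id: int) -> ContextSpec:
        for c in self.contexts:
            if c.context_id == context_id:
                return c
        raise KeyError(f"no context {context_id} in design")

    def test_context_id(self, ordinal: int) -> int:
        """Context id of the ``ordinal``-th (1-based) test context."""
        return self.test_contexts[ordinal - 1].context_id

    def to_json(self) -> str:
        doc = {
            "experiment": self.experiment,
            "goal_labels": list(self.goal_labels),
            "mappings": {
                mid: {"hand": m.hand, "pattern": m.pattern}
                for mid, m in self.mappings.items()
            },
            "contexts": [
                {
                    "context_id": c.context_id,
                    "mapping_id": c.mapping_id,
                    "rewarded_goal": c.rewarded_goal,
                    "phase": c.phase,
                    "n_trials": c.n_trials,
                }
                for c in self.contexts
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentDesign":
        doc = json.loads(text)
        mappings = {
            mid: KeyMapping(mid, spec["hand"], spec["pattern"])
            for mid, spec in doc["mappings"].items()
        }
        ctxs = [
            ContextSpec(c["context_id"], c["mapping_id"], c["rewarded_goal"],
                        c["phase"], c["n_trials"])
            for c in doc["contexts"]
        ]
        return cls(
            experiment=doc["experiment"],
            goal_labels=tuple(doc["goal_labels"]),
            mappings=mappings,
            training_contexts=[c for c in ctxs if c.phase == "training"],
            test_contexts=[c for c in ctxs if c.phase == "test"],
        )


def _in_bounds(cell) -> bool:
    col, row = cell
    return 0 <= col < GRID_SIZE and 0 <= row < GRID_SIZE


def _adjacent(a, b) -> bool:
    return abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1


# ---------------------------------------------------------------------------
# Experiment designs
# ---------------------------------------------------------------------------

# Default mapping pair: one per hand, different left-to-right pattern, so that
# knowledge of one mapping cannot be transferred to the other by symmetry.
_MAP_HIGH = KeyMapping("m_high", "left", "WNSE")
_MAP_LOW = KeyMapping("m_low", "right", "NWES")

# Training trial allocations. Totals per mapping are equal and totals per
# rewarded goal are equal in every design (the balance constraint).
_EXP1_TRAIN = [("m_high", "A", 8), ("m_high", "A", 8), ("m_low", "B", 16)]
_EXP2_TRAIN = [
    ("m_low", "A", 14), ("m_low", "B", 14), ("m_low", "C", 28),
    ("m_high", "A", 7), ("m_high", "A", 7), ("m_high", "B", 14),
    ("m_high", "D", 28),
]
_EXP3_TRAIN = [
    ("m_low", "A", 20), ("m_low", "C", 40),
    ("m_high", "A", 10), ("m_high", "A", 10), ("m_high", "B", 40),
]

# Test contexts in the order of the published context numbering (test 1..n).
_EXP1_TEST = {
    "repeat": [("m_high", "A", 4), ("m_high", "A", 4), ("m_low", "B", 8)],
    "switch": [("m_low", "A", 4), ("m_low", "A", 4), ("m_high", "B", 8)],
}
_EXP2_TEST = [("m_low", "A", 6), ("m_low", "B", 6), ("m_high", "C", 6),
              ("m_high", "D", 6)]
_EXP3_TEST = [("m_low", "A", 10), ("m_high", "B", 10), ("m_high", "C", 5),
              ("m_low", "C", 5)]

# Displayed goal squares per experiment. Experiment 1 trains and tests only
# goals A and B ("no reward for choosing the other goal"), so chance is 1/2;
# experiments 2 and 3 display four and three labeled goals respectively.
_GOALS = {1: ("A", "B"), 2: ("A", "B", "C", "D"), 3: ("A", "B", "C")}


def build_design(experiment: int, variant: str | None = None) -> ExperimentDesign:
    """Construct one of the three built-in experiment designs.

    Parameters
    ----------
    experiment : {1, 2, 3}
    variant : {"repeat", "switch"}, optional
        Required for experiment 1 (the between-subjects test manipulation);
        must be omitted for experiments 2 and 3.
    """
    if experiment not in (1, 2, 3):
        raise DesignError(f"unknown experiment {experiment!r}")
    if experiment == 1:
        if variant not in ("repeat", "switch"):
            raise DesignError("experiment 1 requires variant 'repeat' or 'switch'")
        train, test = _EXP1_TRAIN, _EXP1_TEST[variant]
        name = f"1_{variant}"
    else:
        if variant is not None:
            raise DesignError("variant is only valid for experiment 1")
        train = _EXP2_TRAIN if experiment == 2 else _EXP3_TRAIN
        test = _EXP2_TEST if experiment == 2 else _EXP3_TEST
        name = str(experiment)

    ctxs = []
    for i, (mid, goal, n) in enumerate(train):
        ctxs.append(ContextSpec(i, mid, goal, "training", n))
    for j, (mid, goal, n) in enumerate(test):
        ctxs.append(ContextSpec(len(train) + j, mid, goal, "test", n))

    design = ExperimentDesign(
        experiment=name,
        goal_labels=_GOALS[experiment],
        mappings={"m_high": _MAP_HIGH, "m_low": _MAP_LOW},
        training_contexts=[c for c in ctxs if c.phase == "training"],
        test_contexts=[c for c in ctxs if c.phase == "test"],
    )
    _check_balance(design)
    return design


def _check_balance(design: ExperimentDesign) -> None:
    per_map, per_goal = {}, {}
    for c in design.training_contexts:
        per_map[c.mapping_id] = per_map.get(c.mapping_id, 0) + c.n_trials
        per_goal[c.rewarded_goal] = per_goal.get(c.rewarded_goal, 0) + c.n_trials
    if len(set(per_map.values())) != 1 or len(set(per_goal.values())) != 1:
        raise DesignError(
            f"unbalanced training allocation: per-mapping {per_map}, per-goal {per_goal}")


# ---------------------------------------------------------------------------
# Context-order generation
# ---------------------------------------------------------------------------

#: Context-switch hazard rates for the first and second half of training.
TRAIN_HAZARDS = (0.25, 0.08)


def generate_context_order(design: ExperimentDesign, phase: str, seed) -> list:
    """Emit the sequence of context ids for one phase.

    Training orders are built half-by-half: each context contributes half of
    its trials to each half (plus/minus one when the count is odd), and within
    each half the order is arranged so that the context-switch rate between
    adjacent trials matches the phase hazard (25% in the first half, 8% in the
    second). Test orders are unconstrained random permutations.
    """
    rng = np.random.default_rng(seed)
    if phase == "test":
        ids = np.repeat(
            [c.context_id for c in design.test_contexts],
            [c.n_trials for c in design.test_contexts],
        )
        return list(rng.permutation(ids))
    if phase != "training":
        raise DesignError(f"unknown phase {phase!r}")

    counts = {c.context_id: c.n_trials for c in design.training_contexts}
    total = sum(counts.values())
    if total % 2:
        raise DesignError("training total must be even for half-balance")
    halves = _split_halves(counts, rng)
    order = []
    for half_counts, hazard in zip(halves, TRAIN_HAZARDS):
        order.extend(_sequence_with_hazard(half_counts, hazard, rng))
    return order


def _split_halves(counts: dict, rng) -> tuple[dict, dict]:
    first = {c: n // 2 for c, n in counts.items()}
    odd = [c for c, n in counts.items() if n % 2]
    # Odd counts are topped up alternately so the two halves stay equal in
    # total; an odd number of odd contexts cannot be balanced.
    if len(odd) % 2:
        raise DesignError(f"contexts {odd} cannot be split into balanced halves")
    odd = list(rng.permutation(odd))
    for i, c in enumerate(odd):
        if i % 2 == 0:
            first[c] += 1
    second = {c: counts[c] - first[c] for c in counts}
    return first, second


def _sequence_with_hazard(counts: dict, hazard: float, rng, max_tries: int = 200):
    """Arrange a multiset of context ids with a target adjacent-switch rate.

    The number of switches is drawn Binomial(n-1, hazard), clamped to the
    feasible range, and realized by composing each context's trials into runs
    and arranging the runs so no two adjacent runs share a context.
    """
    ids = [c for c, n in counts.items() if n > 0]
    n = sum(counts.values())
    if n == 0:
        return []
    if len(ids) == 1:
        return [ids[0]] * n
    k = len(ids)
    n_switch = int(rng.binomial(n - 1, hazard))
    n_switch = max(k - 1, min(n_switch, n - 1))

    for _ in range(max_tries):
        runs = _draw_runs(counts, ids, n_switch + 1, rng)
        if runs is None:
            continue
        seq = _arrange_runs(runs, rng)
        if seq is not None:
            return seq
    raise DesignError(f"could not realize hazard {hazard} for counts {counts}")


def _draw_runs(counts, ids, n_runs, rng):
    """Split each context's count into runs; total runs must equal n_runs."""
    cap = (n_runs + 1) // 2  # arrangement feasibility: no context may exceed this
    runs_per = {c: 1 for c in ids}
    for _ in range(n_runs - len(ids)):
        eligible = [c for c in ids if runs_per[c] < min(counts[c], cap)]
        if not eligible:
            return None
        weights = np.array([counts[c] - runs_per[c] for c in eligible], float)
        runs_per[rng.choice(eligible, p=weights / weights.sum())] += 1
    runs = []
    for c in ids:
        r = runs_per[c]
        # random composition of counts[c] into r positive parts
        cuts = np.sort(rng.choice(np.arange(1, counts[c]), size=r - 1, replace=False))
        parts = np.diff(np.concatenate(([0], cuts, [counts[c]])))
        runs.extend((c, int(p)) for p in parts)
    return runs


def _arrange_runs(runs, rng, tries: int = 60):
    for _ in range(tries):
        perm = [runs[i] for i in rng.permutation(len(runs))]
        if all(perm[i][0] != perm[i + 1][0] for i in range(len(perm) - 1)):
            return [c for c, p in perm for _ in range(p)]
    return None


# ---------------------------------------------------------------------------
# Trial generation and dynamics
# ---------------------------------------------------------------------------

#: Fraction of trials that receive barrier walls, and how many wall edges.
BARRIER_PROB = 1 / 3
N_BARRIER_EDGES = 4

_ALL_CELLS = [(c, r) for r in range(GRID_SIZE) for c in range(GRID_SIZE)]
_ALL_EDGES = [
    frozenset({(c, r), (c + dc, r + dr)})
    for (c, r) in _ALL_CELLS
    for dc, dr in ((1, 0), (0, 1))
    if _in_bounds((c + dc, r + dr))
]


def generate_trial(design: ExperimentDesign, context_id: int, rng,
                   trial_index: int = 0) -> TrialSpec:
    """Generate one trial: random goal placements, start cell, and barriers.

    Goal and start locations are re-randomized on every trial; on a random
    subset of trials a few interior walls are placed, resampled until every
    goal remains reachable from the start.
    """
    spec = design.context(context_id)
    while True:
        cells = [
            _ALL_CELLS[i]
            for i in rng.choice(len(_ALL_CELLS), size=len(design.goal_labels) + 1,
                                replace=False)
        ]
        goal_cells = dict(zip(design.goal_labels, cells[:-1]))
        start = cells[-1]
        if rng.random() < BARRIER_PROB:
            walls = frozenset(
                _ALL_EDGES[i]
                for i in rng.choice(len(_ALL_EDGES), size=N_BARRIER_EDGES,
                                    replace=False)
            )
        else:
            walls = frozenset()
        grid = GridWorld(walls=walls, goal_cells=goal_cells)
        if not walls or all(_reachable(grid, start, g) for g in goal_cells.values()):
            return TrialSpec(trial_index, context_id, grid, start, spec.phase)


def _reachable(grid: GridWorld, start, target) -> bool:
    seen, queue = {start}, deque([start])
    while queue:
        cell = queue.popleft()
        if cell == target:
            return True
        for move in MOVES:
            nxt, blocked = _step(grid, cell, move)
            if not blocked and nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return False


def _step(grid: GridWorld, cell, movement):
    if movement == "NONE":
        return cell, False
    dc, dr = _DELTAS[movement]
    nxt = (cell[0] + dc, cell[1] + dr)
    if not _in_bounds(nxt) or frozenset({cell, nxt}) in grid.walls:
        return cell, True
    return nxt, False


def transition(trial: TrialSpec, cell, movement):
    """Deterministic grid dynamics: ``(next_cell, blocked)``.

    A movement off the grid or across a wall edge leaves the cell unchanged
    with ``blocked=True``; ``NONE`` leaves it unchanged without blocking.
    """
    if not _in_bounds(cell):
        raise ValueError(f"cell {cell} out of bounds")
    if movement not in KEY_OUTCOMES:
        raise ValueError(f"unknown movement {movement!r}")
    return _step(trial.grid, cell, movement)


# ---------------------------------------------------------------------------
# Design-level statistics
# ---------------------------------------------------------------------------


def write_trial_log(trials, path) -> None:
    """Write generated trials as CSV (wall list serialized as a JSON string)."""
    import csv

    trials = list(trials)
    if not trials:
        raise ValueError("no trials to write")
    labels = sorted({g for t in trials for g in t.grid.goal_cells})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial", "context", "phase", "start_col", "start_row"]
                   + [f"goal_{g}_col" for g in labels]
                   + [f"goal_{g}_row" for g in labels] + ["walls"])
        for t in trials:
            cells = t.grid.goal_cells
            w.writerow(
                [t.trial_index, t.context_id, t.phase, t.start_cell[0],
                 t.start_cell[1]]
                + [cells[g][0] for g in labels] + [cells[g][1] for g in labels]
                + [json.dumps(sorted(sorted(map(list, e)) for e in t.grid.walls))])


def nmi(design: ExperimentDesign) -> float:
    """Normalized mutual information between mapping and goal over training.

    Each distinct training context counts once (context popularity, not trial
    frequency): ``I(G; M) / H(G)``. Raises if the goal entropy is zero.
    """
    ctxs = design.training_contexts
    if len(ctxs) < 2:
        raise DesignError("NMI requires at least two training contexts")
    pairs = [(c.mapping_id, c.rewarded_goal) for c in ctxs]
    n = len(pairs)
    maps = sorted({m for m, g in pairs})
    goals = sorted({g for m, g in pairs})
    joint = np.zeros((len(maps), len(goals)))
    for m, g in pairs:
        joint[maps.index(m), goals.index(g)] += 1
    joint /= n
    p_g = joint.sum(axis=0)
    p_m = joint.sum(axis=1)
    h_g = _entropy(p_g)
    if h_g == 0:
        raise DesignError("goal entropy is zero; NMI undefined")
    h_g_given_m = sum(
        p_m[i] * _entropy(joint[i] / p_m[i]) for i in range(len(maps)) if p_m[i] > 0
    )
    return float((h_g - h_g_given_m) / h_g)


def _entropy(p) -> float:
    p = np.asarray(p, float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())
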