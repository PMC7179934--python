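"""Tabular value-iteration planning on 6x6 grid instances.

Movement in the grids is deterministic, so the Bellman backup reduces to a
lookup of each action's successor state. Goal cells are absorbing: their value
is held at zero and their reward is collected on entry, so the action value of
stepping onto the only rewarded goal is exactly its goal value.
"""

from __future__ import annotations

import numpy as np

from .taskenv import GRID_SIZE, MOVES, TrialSpec, _in_bounds

N_STATES = GRID_SIZE * GRID_SIZE

_DELTAS = {"N": (0, -1), "S": (0, 1), "E": (1, 0), "W": (-1, 0)}


def cell_index(cell) -> int:
    return cell[1] * GRID_SIZE + cell[0]


def _base_successor_table() -> np.ndarray:
    ns = np.empty((len(MOVES), N_STATES), dtype=np.int64)
    for a, move in enumerate(MOVES):
        dc, dr = _DELTAS[move]
        for s in range(N_STATES):
            col, row = s % GRID_SIZE, s // GRID_SIZE
            nxt = (col + dc, row + dr)
            ns[a, s] = s if not _in_bounds(nxt) else cell_index(nxt)
    return ns


_BASE_NS = _base_successor_table()
_BASE_NS.setflags(write=False)


def successor_table(grid) -> np.ndarray:
    """``(4, 36)`` array of successor state indices under each movement.

    The wall-free table is precomputed; walls only patch the affected edges.
    """
    if not grid.walls:
        return _BASE_NS
    ns = _BASE_NS.copy()
    for edge in grid.walls:
        a_cell, b_cell = tuple(edge)
        for src, dst in ((a_cell, b_cell), (b_cell, a_cell)):
            dc, dr = dst[0] - src[0], dst[1] - src[1]
            move = {(0, -1): "N", (0, 1): "S", (1, 0): "E", (-1, 0): "W"}[(dc, dr)]
            ns[MOVES.index(move), cell_index(src)] = cell_index(src)
    return ns


def _value_iteration_np(ns, reward, terminal, gamma, tol, max_iter):
    v = np.zeros(N_STATES)
    for _ in range(max_iter):
        q = reward[ns] + gamma * v[ns]
        v_new = q.max(axis=0)
        v_new[terminal] = 0.0
        delta = np.abs(v_new - v).max()
        v = v_new
        if delta < tol:
            break
    return reward[ns] + gamma * v[ns]


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=True)
    def _value_iteration_nb(ns, reward, terminal, gamma, tol, max_iter):  # pragma: no cover
        n_a, n_s = ns.shape
        v = np.zeros(n_s)
        v_new = np.zeros(n_s)
        for _ in range(max_iter):
            delta = 0.0
            for s in range(n_s):
                if terminal[s]:
                    v_new[s] = 0.0
                else:
                    best = -1e300
                    for a in range(n_a):
                        sp = ns[a, s]
                        val = reward[sp] + gamma * v[sp]
                        if val > best:
                            best = val
                    v_new[s] = best
                d = abs(v_new[s] - v[s])
                if d > delta:
                    delta = d
            v, v_new = v_new, v
            if delta < tol:
                break
        q = np.empty((n_a, n_s))
        for a in range(n_a):
            for s in range(n_s):
                sp = ns[a, s]
                q[a, s] = reward[sp] + gamma * v[sp]
        return q

    _value_iteration = _value_iteration_nb
except Exception:  # pragma: no cover
    _value_iteration = _value_iteration_np


def plan_value_iteration(trial: TrialSpec, goal_values, gamma: float = 0.8,
                         tol: float = 1e-6, max_iter: int = 500,
                         discount_q: bool = True) -> np.ndarray:
    """Solve for movement values ``Q[(a, s)]`` on one trial's grid.

    Parameters
    ----------
    goal_values : mapping from goal label to value
        The agent's current value (or reward-belief probability) for each
        labeled goal square; goal squares are absorbing.
    discount_q : bool
        If True (default) the successor value is discounted in the final
        action-value readout as well as in the fixed-point iteration. The
        undiscounted readout variant is available for comparison.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0, 1)")
    ns = successor_table(trial.grid)
    reward = np.zeros(N_STATES)
    terminal = np.zeros(N_STATES, dtype=np.bool_)
    for label, cell in trial.grid.goal_cells.items():
        reward[cell_index(cell)] = goal_values[label]
        terminal[cell_index(cell)] = True
    q = _value_iteration(ns, reward, terminal, gamma, tol, max_iter)
    if not discount_q:
        # literal undiscounted readout: Q = R(s') + V(s')
        v = np.where(terminal, 0.0, q.max(axis=0))
        q = reward[ns] + v[ns]
    return q
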