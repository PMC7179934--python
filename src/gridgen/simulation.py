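"""Generative simulation of full subjects and the batch resampling protocol.

Each simulated subject draws its parameters from the population distributions,
experiences a freshly randomized instantiation of the task (context order,
goal/start placements, barriers), and is run generatively through training and
test. Cluster inference continues through the test phase, so novel test
contexts influence subsequent generalization.

The batch protocol resamples the cohort of simulations into sample-size-matched
batches (matching the human cohort sizes) on which contrast distributions are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import taskenv
from .agents import GAMMA, AgentParams, make_agent

#: Hard cap on keypresses within one trial; far above optimal path lengths.
TRIAL_KEYPRESS_CAP = 100

#: Human cohort sizes per experiment condition, used as batch sizes.
HUMAN_N = {"1_repeat": 80, "1_switch": 49, "2": 114, "3": 115}

#: Default cohort/batch protocol.
N_SIMS_FULL = 2500
N_BATCHES = 200

RECORD_COLUMNS = [
    "sim_id", "model", "trial", "context", "phase", "test_index", "chosen_goal",
    "reward", "n_keypresses", "first_context_visit", "capped",
]


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def sample_params(model: str, rng) -> AgentParams:
    """Draw one subject's parameters from the population distributions.

    log(alpha) ~ N(-0.5, 1); log(beta) ~ N(2, 0.5); eta, omega, zeta, epsilon
    are inverse-logit transforms of N(-1, 1) draws; gamma is fixed at 0.8. The
    flat agent receives an infinite concentration.
    """
    alpha = np.inf if model == "flat" else float(np.exp(rng.normal(-0.5, 1.0)))
    return AgentParams(
        model=model,
        alpha=alpha,
        beta=float(np.exp(rng.normal(2.0, 0.5))),
        gamma=GAMMA,
        eta=float(_inv_logit(rng.normal(-1.0, 1.0))),
        omega=float(_inv_logit(rng.normal(-1.0, 1.0))),
        zeta=float(_inv_logit(rng.normal(-1.0, 1.0))),
        epsilon=float(_inv_logit(rng.normal(-1.0, 1.0))),
        meta_prior=tuple(rng.uniform(0.0, 1.0, size=2)),
    )


@dataclass
class SimulationRecord:
    """One completed trial of one simulated subject."""

    sim_id: int
    model: str
    trial: int
    context: int
    phase: str
    test_index: int  # 1-based ordinal among test contexts; 0 for training
    chosen_goal: str | None
    reward: int
    n_keypresses: int
    first_context_visit: bool
    capped: bool


def run_subject(design: taskenv.ExperimentDesign, params: AgentParams,
                seed) -> list[SimulationRecord]:
    """Run one simulated subject through training then test.

    Trials end on entry into any goal square (binary reward by match with the
    context's rewarded goal). A trial that exhausts the keypress cap without
    entering a goal is scored unrewarded with no goal outcome observed.
    """
    rng = np.random.default_rng(seed)
    agent = make_agent(params, design, rng)
    order = generate_full_order(design, rng)
    test_ord = {c.context_id: i + 1 for i, c in enumerate(design.test_contexts)}
    true_assign = {
        c.context_id: design.mappings[c.mapping_id].assignment
        for c in design.contexts
    }
    seen: set[int] = set()
    records = []
    for t, ctx in enumerate(order):
        spec = design.context(ctx)
        trial = taskenv.generate_trial(design, ctx, rng, trial_index=t)
        first = ctx not in seen
        seen.add(ctx)
        agent.begin_trial(ctx, trial)
        cell = trial.start_cell
        cell_to_goal = {c: g for g, c in trial.grid.goal_cells.items()}
        chosen, presses, capped = None, 0, False
        while presses < TRIAL_KEYPRESS_CAP:
            _, key = agent.act(cell)
            presses += 1
            true_move = true_assign[ctx][key]
            nxt, blocked = taskenv.transition(trial, cell, true_move)
            # fully supervised attempted movement, even when blocked
            agent.observe_mapping(key, true_move)
            cell = nxt
            if cell in cell_to_goal:
                chosen = cell_to_goal[cell]
                break
        else:
            capped = True
        reward = int(chosen == spec.rewarded_goal) if chosen is not None else 0
        agent.observe_goal(chosen, reward)
        records.append(SimulationRecord(
            sim_id=-1, model=params.model, trial=t, context=ctx, phase=spec.phase,
            test_index=test_ord.get(ctx, 0), chosen_goal=chosen, reward=reward,
            n_keypresses=presses, first_context_visit=first, capped=capped))
    return records


def generate_full_order(design: taskenv.ExperimentDesign, rng) -> list[int]:
    """Training order (hazard-constrained) followed by a random test order."""
    train = taskenv.generate_context_order(design, "training", rng)
    test = taskenv.generate_context_order(design, "test", rng)
    return list(train) + list(test)


@dataclass
class BatchSet:
    """Index sets of sims forming sample-size-matched batches."""

    batches: list  # list of integer arrays of sim_ids
    batch_size: int


def run_cohort(design: taskenv.ExperimentDesign, model: str,
               n_sims: int = N_SIMS_FULL, n_batches: int = N_BATCHES,
               batch_size: int | None = None, master_seed=0,
               ) -> tuple[pd.DataFrame, BatchSet]:
    """Simulate ``n_sims`` independent subjects and draw the batch sets.

    Every subject gets independent parameter draws and an independent task
    instantiation. Batches are drawn without replacement within a batch and
    independently (with replacement) across batches. Fully reproducible from
    ``master_seed``.
    """
    if batch_size is None:
        batch_size = HUMAN_N[design.experiment]
    if batch_size > n_sims:
        raise ValueError("batch_size may not exceed n_sims")
    ss = np.random.SeedSequence(master_seed)
    param_seed, batch_seed, *sim_seeds = ss.spawn(n_sims + 2)
    param_rng = np.random.default_rng(param_seed)
    rows = []
    for i in range(n_sims):
        params = sample_params(model, param_rng)
        for rec in run_subject(design, params, sim_seeds[i]):
            rec.sim_id = i
            rows.append(rec)
    records = pd.DataFrame([r.__dict__ for r in rows], columns=RECORD_COLUMNS)
    batch_rng = np.random.default_rng(batch_seed)
    batches = [
        batch_rng.choice(n_sims, size=batch_size, replace=False)
        for _ in range(n_batches)
    ]
    return records, BatchSet(batches=batches, batch_size=batch_size)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_batches(batchset: BatchSet, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump({"batch_size": batchset.batch_size,
                   "batches": [b.tolist() for b in batchset.batches]}, fh)
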