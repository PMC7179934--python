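"""Six reinforcement-learning agents for the context-cued navigation tasks.

Three generalizing agents cluster contexts with a Chinese-restaurant-process
(CRP) prior so that learned structure can be reused in novel contexts:

* ``joint`` — each context joins a single cluster holding both its key→movement
  mapping function and its rewarded-goal belief; mapping evidence therefore
  constrains goal generalization.
* ``independent`` — each context is clustered twice, once for mappings and once
  for goals, so either function can be reused without the other.
* ``meta`` — maintains both strategies and, on each trial, samples which one to
  act on with probability proportional to its accumulated reward-prediction
  evidence times a random prior (an approximation to Bayesian model averaging).

Three non-generalizing controls learn each context from scratch: a ``flat``
agent (the CRP limit of infinite concentration — one cluster per context), a
delta-rule Q-learner, and a Kalman-filter upper-confidence-bound explorer.

All agents share the same planner (value iteration over the trial's grid) and
the same softmax action selection over cardinal movements, followed by sampling
a keypress from the learned inverse mapping.

Cluster statistics are sufficient statistics summed over member contexts, so
reassigning a context automatically removes its evidence from its old cluster.
Context popularity counts each distinct context once, however many trials it
has been experienced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .taskenv import KEY_OUTCOMES, KEYS, MOVES
from . import planner

N_KEYS = len(KEYS)
N_OUTCOMES = len(KEY_OUTCOMES)
_KEY_IDX = {k: i for i, k in enumerate(KEYS)}
_OUT_IDX = {o: i for i, o in enumerate(KEY_OUTCOMES)}
_MOVE_IDX = {m: i for i, m in enumerate(MOVES)}

#: Symmetric pseudo-count added to every (key, outcome) cell so that mapping
#: estimates are defined before any observation (uniform for an empty cluster).
MAPPING_PSEUDO_COUNT = 0.01

#: Floor on a strategy's reward-prediction probability, keeping log evidence
#: finite when a strategy assigned zero probability to the observed outcome.
META_EVIDENCE_FLOOR = 0.01

GAMMA = 0.8  # discount, fixed for all agents

MODELS = ("joint", "independent", "meta", "flat", "qlearn", "ucb")


@dataclass
class AgentParams:
    """Free parameters of one simulated subject."""

    model: str
    alpha: float = 1.0  # CRP concentration (np.inf for the flat agent)
    beta: float = 5.0  # softmax inverse temperature
    gamma: float = GAMMA
    eta: float = 0.1  # Q-learner learning rate
    omega: float = 0.25  # UCB exploration weight
    zeta: float = 0.25  # Kalman diffusion noise
    epsilon: float = 0.25  # Kalman irreducible noise
    meta_prior: tuple = (0.5, 0.5)  # (independent, joint) strategy priors
    likelihood: str = "predictive"  # cluster likelihood form; or "plugin"

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0 or not 0 <= self.eta <= 1 or not 0 <= self.gamma < 1:
            raise ValueError("parameter out of range")


# ---------------------------------------------------------------------------
# CRP prior and cluster posteriors
# ---------------------------------------------------------------------------


def crp_prior(membership_counts, alpha: float) -> np.ndarray:
    """Chinese-restaurant-process prior over existing clusters plus one new.

    Existing cluster k receives ``N_k / (N + alpha)``; a new cluster receives
    ``alpha / (N + alpha)``. ``alpha=inf`` yields the flat-agent limit where a
    new cluster is certain.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    counts = np.asarray(membership_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("membership counts must be non-negative")
    out = np.empty(len(counts) + 1)
    if math.isinf(alpha):
        out[:-1] = 0.0
        out[-1] = 1.0
        return out
    denom = counts.sum() + alpha
    out[:-1] = counts / denom
    out[-1] = alpha / denom
    return out


@dataclass
class ContextStats:
    """Per-context observation history as sufficient statistics.

    ``goal_seq`` keeps the chronological (goal index, reward) outcomes so the
    sequential predictive likelihood can replay them in order.
    """

    n_goals: int
    map_counts: np.ndarray = None  # (8 keys, 5 outcomes)
    goal_pos: np.ndarray = None  # rewarded observations per goal
    goal_neg: np.ndarray = None  # unrewarded observations per goal
    goal_seq: list = None

    def __post_init__(self):
        if self.map_counts is None:
            self.map_counts = np.zeros((N_KEYS, N_OUTCOMES))
        if self.goal_pos is None:
            self.goal_pos = np.zeros(self.n_goals)
            self.goal_neg = np.zeros(self.n_goals)
        if self.goal_seq is None:
            self.goal_seq = []


def goal_belief(goal_pos, goal_neg) -> np.ndarray:
    """Maximum-likelihood rewarded-goal belief from outcome counts.

    A single consistently rewarded goal gives a point mass; unrewarded goals
    are eliminated with the rest uniform. Contradictory evidence (possible only
    transiently, before reassignment heals the cluster) falls back to uniform
    over the non-eliminated goals, or over all goals if none remain.
    """
    pos = goal_pos > 0
    ok = goal_neg == 0
    n = len(goal_pos)
    if pos.sum() == 1 and ok[np.argmax(pos)]:
        out = np.zeros(n)
        out[np.argmax(pos)] = 1.0
        return out
    mask = ok if ok.any() else np.ones(n, dtype=bool)
    return mask / mask.sum()


def mapping_estimate(map_counts, pseudo: float = MAPPING_PSEUDO_COUNT):
    """Smoothed mapping estimates ``(phi(outcome|key), phi(key|movement))``.

    ``phi(outcome|key)`` rows are normalized over the five outcomes (the four
    cardinal movements plus NONE); ``phi(key|movement)`` columns are normalized
    over the eight keys for each cardinal movement.
    """
    c = map_counts + pseudo
    phi_out = c / c.sum(axis=1, keepdims=True)
    phi_key = c[:, : len(MOVES)] / c[:, : len(MOVES)].sum(axis=0, keepdims=True)
    return phi_out, phi_key


def _mapping_loglik_plugin(obs_counts, cluster_counts) -> float:
    """Context history evaluated against the cluster's current (smoothed) ML
    mapping estimate."""
    phi_out, _ = mapping_estimate(cluster_counts)
    return float((obs_counts * np.log(phi_out)).sum())


def _mapping_marginal_py(obs, clus, pseudo):
    ll = 0.0
    for a in range(obs.shape[0]):
        row_obs = obs[a].sum()
        if row_obs == 0:
            continue
        row_a = 0.0
        for o in range(obs.shape[1]):
            x = clus[a, o] + pseudo
            row_a += x
            if obs[a, o] > 0:
                ll += math.lgamma(x + obs[a, o]) - math.lgamma(x)
        ll -= math.lgamma(row_a + row_obs) - math.lgamma(row_a)
    return ll


try:
    from numba import njit as _njit

    _mapping_marginal = _njit(cache=True)(_mapping_marginal_py)
except Exception:  # pragma: no cover
    _mapping_marginal = _mapping_marginal_py


def _mapping_loglik_predictive(obs_counts, cluster_counts,
                               pseudo: float = MAPPING_PSEUDO_COUNT) -> float:
    """Posterior-predictive (Dirichlet-multinomial marginal) likelihood.

    Equals the product of one-step-ahead predictive probabilities of the
    context's own (key, outcome) events given the cluster's other data: early
    events are judged against the cluster's estimates, later events also
    against the context's own accumulating counts. Unlike the plugin form it
    does not charge a fresh cluster the uniform rate for every observation.
    """
    return float(_mapping_marginal(obs_counts, cluster_counts, pseudo))


def _goal_loglik(goal_seq, cluster_pos, cluster_neg, sequential: bool) -> float:
    """Likelihood of the context's goal outcomes under a cluster.

    ``sequential=True`` replays the outcomes in order, updating a scratch copy
    of the cluster's evidence with the context's own outcomes (the predictive
    form); otherwise every outcome is judged against the cluster's current
    belief (the plugin form).
    """
    if not goal_seq:
        return 0.0
    pos = [float(v) for v in cluster_pos]
    neg = [float(v) for v in cluster_neg]
    n = len(pos)
    # Under the eliminative belief, a repeated (goal, reward) outcome has
    # probability exactly 1 after its first occurrence (a rewarded goal
    # becomes a point mass; an unrewarded goal is eliminated), and every
    # contradictory sequence hits a zero at the first conflicting event — so
    # the sequential product over the history equals the product over first
    # occurrences. The shortcut is invalid only in fallback belief states
    # (two rewarded goals in play, or every goal eliminated), which are
    # replayed in full; both are degenerate and terminate almost immediately.
    pos_goals = {i for i in range(n) if pos[i] > 0}
    pos_goals |= {g for g, r in goal_seq if r}
    all_eliminated_possible = all(
        neg[i] > 0 or any(g == i and r == 0 for g, r in goal_seq)
        for i in range(n))
    if sequential and len(pos_goals) < 2 and not all_eliminated_possible:
        events = []
        seen = set()
        for ev in goal_seq:
            if ev not in seen:
                seen.add(ev)
                events.append(ev)
    else:
        events = goal_seq
    ll = 0.0
    for g, r in events:
        # belief value at goal g only (same rule as goal_belief)
        pos_idx = [i for i in range(n) if pos[i] > 0]
        if len(pos_idx) == 1 and neg[pos_idx[0]] == 0:
            bg = 1.0 if g == pos_idx[0] else 0.0
        else:
            ok = [i for i in range(n) if neg[i] == 0]
            if ok:
                bg = (1.0 / len(ok)) if g in ok else 0.0
            else:
                bg = 1.0 / n
        p = bg if r else 1.0 - bg
        if p <= 0.0:
            return -np.inf
        ll += math.log(p)
        if sequential:
            if r:
                pos[g] += 1
            else:
                neg[g] += 1
    return ll


class ClusterModel:
    """One CRP clustering over contexts with a configurable likelihood mode.

    ``mode`` selects which observations enter the likelihood: ``"joint"`` uses
    both mapping and goal outcomes, ``"mapping_only"`` / ``"reward_only"`` are
    the two halves used by the independent agent. The flat agent is the
    ``alpha=inf`` limit. Context statistics live in a shared dict so multiple
    clusterings (independent, meta) can view the same observation history.
    """

    def __init__(self, stats: dict, alpha: float, mode: str, n_goals: int,
                 rng=None, likelihood: str = "predictive"):
        if mode not in ("joint", "mapping_only", "reward_only"):
            raise ValueError(f"unknown mode {mode!r}")
        if likelihood not in ("predictive", "plugin"):
            raise ValueError(f"unknown likelihood form {likelihood!r}")
        self.stats = stats
        self.alpha = alpha
        self.mode = mode
        self.n_goals = n_goals
        self.rng = rng
        self.likelihood = likelihood
        self.assignments: dict[int, int] = {}  # context -> cluster id
        self._next_id = 0
        # goal-outcome likelihoods are constant within a trial (goal evidence
        # arrives only at trial end); cache them until the next invalidation
        self._goal_ll_cache: dict = {}
        # leave-one-out cluster sums are stable for a whole trial: only the
        # queried context's stats and assignment can change mid-trial, and
        # they are excluded from these sums by construction
        self._loo_cache: dict = {}

    # -- cluster views ----------------------------------------------------
    def members(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for ctx, k in self.assignments.items():
            out.setdefault(k, []).append(ctx)
        return out

    def _cluster_sums(self, ctxs, exclude):
        mc = np.zeros((N_KEYS, N_OUTCOMES))
        gp = np.zeros(self.n_goals)
        gn = np.zeros(self.n_goals)
        for c in ctxs:
            if c == exclude:
                continue
            st = self.stats[c]
            mc += st.map_counts
            gp += st.goal_pos
            gn += st.goal_neg
        return mc, gp, gn

    def posterior(self, context: int):
        """Leave-self-out posterior over existing clusters plus a new one.

        Returns ``(cluster_ids + [new_id], probabilities)``. The queried
        context's own observations form the likelihood data; its current
        assignment (if any) is removed from both prior counts and cluster
        statistics before evaluation.
        """
        st = self.stats.get(context, ContextStats(self.n_goals))
        member = self.members()
        # drop the queried context and any cluster it would leave empty
        ids = []
        for k in sorted(member):
            ctxs = [c for c in member[k] if c != context]
            if ctxs:
                ids.append((k, ctxs))
        counts = np.array([len(ctxs) for _, ctxs in ids], dtype=float)
        prior = crp_prior(counts, self.alpha)
        loglik = np.zeros(len(ids) + 1)
        fresh = ContextStats(self.n_goals)
        for i, (k, ctxs) in enumerate(ids):
            loo_key = (context, k)
            sums = self._loo_cache.get(loo_key)
            if sums is None:
                sums = self._cluster_sums(ctxs, context)
                self._loo_cache[loo_key] = sums
            mc, gp, gn = sums
            loglik[i] = self._loglik(st, mc, gp, gn, cache_key=(context, k))
        loglik[-1] = self._loglik(st, fresh.map_counts, fresh.goal_pos,
                                  fresh.goal_neg, cache_key=(context, None))
        with np.errstate(divide="ignore"):
            logp = np.log(prior) + loglik
        if np.all(np.isinf(logp)):
            logp = np.zeros_like(logp)  # degenerate; fall back to uniform
        logp -= logp.max()
        p = np.exp(logp)
        p /= p.sum()
        new_id = self._next_id
        while new_id in member:
            new_id += 1
        return [k for k, _ in ids] + [new_id], p

    def _loglik(self, st: ContextStats, mc, gp, gn, cache_key=None) -> float:
        ll = 0.0
        if self.mode in ("joint", "mapping_only"):
            if self.likelihood == "predictive":
                ll += _mapping_loglik_predictive(st.map_counts, mc)
            else:
                ll += _mapping_loglik_plugin(st.map_counts, mc)
        if self.mode in ("joint", "reward_only"):
            if cache_key is not None and cache_key in self._goal_ll_cache:
                ll += self._goal_ll_cache[cache_key]
            else:
                g = _goal_loglik(st.goal_seq, gp, gn,
                                 sequential=self.likelihood == "predictive")
                if cache_key is not None:
                    self._goal_ll_cache[cache_key] = g
                ll += g
        return ll

    def clear_trial_cache(self) -> None:
        """Invalidate all per-trial caches (call at trial boundaries, when
        other contexts' data or assignments may have changed)."""
        self._goal_ll_cache.clear()
        self._loo_cache.clear()

    def clear_goal_cache(self) -> None:
        """Invalidate cached goal likelihoods only (the queried context's own
        goal evidence changed; other contexts' sums remain valid)."""
        self._goal_ll_cache.clear()

    def assign_map(self, context: int) -> int:
        """(Re)assign the context to its maximum-a-posteriori cluster.

        Exact posterior ties break toward the oldest (lowest-index) cluster,
        which also prefers an existing cluster over a new one; the rule is
        deterministic given the agent's history.
        """
        ids, p = self.posterior(context)
        k = ids[int(np.argmax(p))]
        self.assignments[context] = k
        self._next_id = max(self._next_id, k + 1)
        return k

    def cluster_of(self, context: int):
        return self.assignments.get(context)

    def cluster_stats(self, k: int):
        ctxs = [c for c, kk in self.assignments.items() if kk == k]
        return self._cluster_sums(ctxs, exclude=None)

    def goal_belief_of(self, k) -> np.ndarray:
        """Goal belief of cluster ``k`` only (skips mapping estimates)."""
        gp = np.zeros(self.n_goals)
        gn = np.zeros(self.n_goals)
        for c, kk in self.assignments.items():
            if kk == k:
                st = self.stats[c]
                gp += st.goal_pos
                gn += st.goal_neg
        return goal_belief(gp, gn)

    def predict_functions(self, k):
        """Mapping estimates and goal belief for cluster ``k`` (None = empty)."""
        if k is None or k not in self.assignments.values():
            fresh = ContextStats(self.n_goals)
            phi_out, phi_key = mapping_estimate(fresh.map_counts)
            return phi_out, phi_key, goal_belief(fresh.goal_pos, fresh.goal_neg)
        mc, gp, gn = self.cluster_stats(k)
        phi_out, phi_key = mapping_estimate(mc)
        return phi_out, phi_key, goal_belief(gp, gn)


# ---------------------------------------------------------------------------
# Incremental value learners (non-generalizing reward models)
# ---------------------------------------------------------------------------


def q_learning_update(value: float, reward: float, eta: float) -> float:
    """Delta rule: ``R <- R + eta * (r - R)``."""
    if not 0 <= eta <= 1:
        raise ValueError("eta must lie in [0, 1]")
    return value + eta * (reward - value)


def kalman_ucb_update(mu: float, sigma2: float, reward: float, zeta: float,
                      epsilon: float, omega: float, gain_from_variance: bool = False):
    """One Kalman-filter update of a goal's reward estimate plus its UCB value.

    The default gain ``G = (mu + zeta) / (mu + zeta + epsilon)`` follows the
    mean-based form used by the published agent; the conventional
    variance-based gain is available behind ``gain_from_variance``. The gain is
    clamped to [0, 1]. Returns ``(mu, sigma2, exploration_value)`` where the
    exploration value is ``mu + omega * sigma2``.
    """
    base = sigma2 if gain_from_variance else mu
    denom = base + zeta + epsilon
    gain = 1.0 if denom == 0 else (base + zeta) / denom
    gain = min(1.0, max(0.0, gain))
    mu = mu + gain * (reward - mu)
    sigma2 = (1.0 - gain) * (sigma2 + zeta)
    return mu, sigma2, mu + omega * sigma2


# ---------------------------------------------------------------------------
# Meta arbitration
# ---------------------------------------------------------------------------


@dataclass
class MetaState:
    """Accumulated per-strategy log reward-prediction evidence and priors."""

    prior: np.ndarray  # per-strategy prior Pr(m), drawn uniform(0, 1)
    log_evidence: np.ndarray = None

    def __post_init__(self):
        if self.log_evidence is None:
            self.log_evidence = np.zeros(len(self.prior))

    def weights(self) -> np.ndarray:
        logw = self.log_evidence + np.log(self.prior)
        logw -= logw.max()
        w = np.exp(logw)
        return w / w.sum()


def meta_arbitrate(state: MetaState, reward_pred_prob, rng):
    """Accumulate log evidence and sample the strategy to act with.

    ``reward_pred_prob`` holds each strategy's probability of the observed
    reward outcome on the last trial (already floored by the caller); weights
    are ``w_m ∝ exp(Σ log Pr(r_t|m)) Pr(m)``.
    """
    p = np.asarray(reward_pred_prob, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("reward prediction probabilities must lie in (0, 1]")
    state.log_evidence = state.log_evidence + np.log(p)
    w = state.weights()
    return state, int(rng.choice(len(w), p=w))


# ---------------------------------------------------------------------------
# Action selection
# ---------------------------------------------------------------------------


def softmax_movement(q_column, beta: float, rng) -> int:
    """Sample a cardinal-movement index from ``Pr(A) ∝ exp(beta * Q)``."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    z = beta * np.asarray(q_column, dtype=float)
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(len(p), p=p))


def select_action(q, cell, beta, phi_key, rng):
    """Sample ``(movement, keypress)`` at ``cell`` from the softmax policy.

    ``q`` is the planner's ``(4, 36)`` table; the keypress is drawn from the
    inverse mapping estimate ``phi(key | movement)`` for the chosen movement.
    """
    s = cell[1] * 6 + cell[0]
    # inline softmax over the 4 cardinal movements (hot path)
    q0, q1, q2, q3 = q[0, s], q[1, s], q[2, s], q[3, s]
    m = max(q0, q1, q2, q3)
    w = (math.exp(beta * (q0 - m)), math.exp(beta * (q1 - m)),
         math.exp(beta * (q2 - m)), math.exp(beta * (q3 - m)))
    u = rng.random() * (w[0] + w[1] + w[2] + w[3])
    a = 0
    acc = w[0]
    while u > acc and a < 3:
        a += 1
        acc += w[a]
    col = phi_key[:, a]
    u = rng.random() * col.sum()
    key = 0
    acc = col[0]
    while u > acc and key < N_KEYS - 1:
        key += 1
        acc += col[key]
    return MOVES[a], KEYS[key]


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------


class Agent:
    """Base class: mapping/goal bookkeeping, planning, and action selection."""

    def __init__(self, params: AgentParams, design, rng):
        self.params = params
        self.design = design
        self.rng = rng
        self.goal_labels = design.goal_labels
        self.n_goals = len(self.goal_labels)
        self._goal_idx = {g: i for i, g in enumerate(self.goal_labels)}
        self.stats: dict[int, ContextStats] = {}
        self.context: int | None = None
        self._q = None
        self._phi_dirty = True
        self._assign_dirty = False
        self._phi_key = None
        self._phi_out = None

    # -- hooks ------------------------------------------------------------
    def _ensure_context(self, context: int):
        if context not in self.stats:
            self.stats[context] = ContextStats(self.n_goals)

    def goal_values(self, context: int) -> np.ndarray:
        raise NotImplementedError

    def _mapping_counts_for_action(self, context: int) -> np.ndarray:
        """Counts backing phi(key|movement) during action selection."""
        raise NotImplementedError

    def _cluster_models(self) -> list:
        return []

    def begin_trial(self, context: int, trial) -> None:
        """Trial start: reassign clusters (where applicable) and re-plan."""
        self._ensure_context(context)
        self.context = context
        self._trial = trial
        for m in self._cluster_models():
            m.clear_trial_cache()
        self._reassign(context)
        self._replan()
        self._phi_dirty = True
        self._assign_dirty = False

    def _replan(self) -> None:
        values = np.asarray(self.goal_values(self.context), dtype=float)
        self._planned_values = values
        goal_vals = {g: values[i] for i, g in enumerate(self.goal_labels)}
        self._q = planner.plan_value_iteration(self._trial, goal_vals,
                                               self.params.gamma)

    def _reassign(self, context: int) -> None:
        pass

    def _midtrial_update(self) -> None:
        """React to mapping evidence arriving within a trial.

        Cluster assignments are maximum-a-posteriori and track the evidence
        continuously: a surprising keypress outcome (e.g. an inert key under
        the assumed mapping) can flip the context to another cluster mid-trial.
        If that changes the goal belief, the trial is re-planned.
        """
        pass

    def act(self, cell):
        if self._phi_dirty:
            if self._assign_dirty:
                self._midtrial_update()
                self._assign_dirty = False
                if not np.array_equal(self._planned_values,
                                      np.asarray(self.goal_values(self.context))):
                    self._replan()
            counts = self._mapping_counts_for_action(self.context)
            self._phi_out, self._phi_key = mapping_estimate(counts)
            self._phi_dirty = False
        return select_action(self._q, cell, self.params.beta, self._phi_key, self.rng)

    #: an observed keypress outcome with estimated probability below this
    #: value under the acting mapping estimate triggers an immediate cluster
    #: re-evaluation; consistent outcomes leave the assignment standing
    SURPRISE_THRESHOLD = 0.5

    def observe_mapping(self, key: str, attempted_movement: str) -> None:
        """Record a (keypress, attempted movement) outcome.

        The attempted movement is fully supervised — a press that was blocked
        by a barrier still reveals the movement direction it attempted.
        """
        st = self.stats[self.context]
        ki, oi = _KEY_IDX[key], _OUT_IDX[attempted_movement]
        if self._phi_out is not None and self._phi_out[ki, oi] < self.SURPRISE_THRESHOLD:
            self._assign_dirty = True
        st.map_counts[ki, oi] += 1
        self._phi_dirty = True

    def observe_goal(self, goal: str | None, reward: int) -> None:
        if goal is None:
            return
        st = self.stats[self.context]
        g = self._goal_idx[goal]
        if reward:
            st.goal_pos[g] += 1
        else:
            st.goal_neg[g] += 1
        st.goal_seq.append((g, int(reward)))
        for m in self._cluster_models():
            m.clear_goal_cache()
        # Re-evaluate the goal-bearing assignment immediately: an outcome that
        # contradicts the current cluster (zero likelihood) must not leave the
        # context poisoning that cluster's belief until its own next trial.
        self._post_outcome_reassign()

    def _post_outcome_reassign(self) -> None:
        pass


class ClusteringAgent(Agent):
    """Joint, independent, or flat context-clustering agent."""

    def __init__(self, params: AgentParams, design, rng):
        super().__init__(params, design, rng)
        alpha = params.alpha
        kw = dict(rng=rng, likelihood=params.likelihood)
        if params.model == "joint":
            self.map_model = self.goal_model = ClusterModel(
                self.stats, alpha, "joint", self.n_goals, **kw)
        elif params.model == "independent":
            self.map_model = ClusterModel(self.stats, alpha, "mapping_only",
                                          self.n_goals, **kw)
            self.goal_model = ClusterModel(self.stats, alpha, "reward_only",
                                           self.n_goals, **kw)
        elif params.model == "flat":
            self.map_model = self.goal_model = ClusterModel(
                self.stats, np.inf, "joint", self.n_goals, **kw)
        else:
            raise ValueError(f"{params.model!r} is not a clustering model")

    def _cluster_models(self) -> list:
        if self.goal_model is self.map_model:
            return [self.map_model]
        return [self.map_model, self.goal_model]

    def _reassign(self, context: int) -> None:
        if self.params.model == "flat":
            # one permanent cluster per context; no pooling
            if context not in self.map_model.assignments:
                self.map_model.assignments[context] = self.map_model._next_id
                self.map_model._next_id += 1
            return
        self.map_model.assign_map(context)
        if self.goal_model is not self.map_model:
            self.goal_model.assign_map(context)

    def _midtrial_update(self) -> None:
        # Goal-cluster posteriors cannot change mid-trial (goal outcomes only
        # arrive at trial end), so only the mapping-bearing clustering moves.
        if self.params.model != "flat":
            self.map_model.assign_map(self.context)

    def _post_outcome_reassign(self) -> None:
        if self.params.model != "flat":
            self.goal_model.assign_map(self.context)

    def goal_values(self, context: int) -> np.ndarray:
        return self.goal_model.goal_belief_of(self.goal_model.cluster_of(context))

    def _mapping_counts_for_action(self, context: int) -> np.ndarray:
        k = self.map_model.cluster_of(context)
        ctxs = [c for c, kk in self.map_model.assignments.items() if kk == k]
        mc = np.zeros((N_KEYS, N_OUTCOMES))
        for c in ctxs:
            mc += self.stats[c].map_counts
        return mc


class QLearningAgent(Agent):
    """Per-context delta-rule goal values; flat (per-context) mapping learning."""

    def __init__(self, params: AgentParams, design, rng):
        super().__init__(params, design, rng)
        self.values: dict[int, np.ndarray] = {}

    def _ensure_context(self, context: int):
        super()._ensure_context(context)
        if context not in self.values:
            self.values[context] = np.full(self.n_goals, 1.0 / self.n_goals)

    def goal_values(self, context: int) -> np.ndarray:
        return self.values[context]

    def _mapping_counts_for_action(self, context: int) -> np.ndarray:
        return self.stats[context].map_counts

    def observe_goal(self, goal, reward):
        super().observe_goal(goal, reward)
        if goal is None:
            return
        g = self._goal_idx[goal]
        v = self.values[self.context]
        v[g] = q_learning_update(v[g], reward, self.params.eta)


class UCBAgent(Agent):
    """Kalman-filter reward tracking with upper-confidence-bound exploration."""

    def __init__(self, params: AgentParams, design, rng,
                 gain_from_variance: bool = False):
        super().__init__(params, design, rng)
        self.mu: dict[int, np.ndarray] = {}
        self.sigma2: dict[int, np.ndarray] = {}
        self.gain_from_variance = gain_from_variance

    def _ensure_context(self, context: int):
        super()._ensure_context(context)
        if context not in self.mu:
            # optimistic, symmetric initialization
            self.mu[context] = np.full(self.n_goals, 1.0 / self.n_goals)
            self.sigma2[context] = np.ones(self.n_goals)

    def goal_values(self, context: int) -> np.ndarray:
        return self.mu[context] + self.params.omega * self.sigma2[context]

    def _mapping_counts_for_action(self, context: int) -> np.ndarray:
        return self.stats[context].map_counts

    def observe_goal(self, goal, reward):
        super().observe_goal(goal, reward)
        if goal is None:
            return
        g = self._goal_idx[goal]
        mu, s2, _ = kalman_ucb_update(
            self.mu[self.context][g], self.sigma2[self.context][g], reward,
            self.params.zeta, self.params.epsilon, self.params.omega,
            self.gain_from_variance)
        self.mu[self.context][g] = mu
        self.sigma2[self.context][g] = s2


class MetaAgent(Agent):
    """Evidence-weighted arbitration between joint and independent clustering.

    Both sub-strategies observe every trial; once per trial (before planning)
    the acting strategy is sampled with probability proportional to its
    accumulated reward-prediction evidence times its random prior.
    """

    STRATEGIES = ("independent", "joint")

    def __init__(self, params: AgentParams, design, rng):
        super().__init__(params, design, rng)
        kw = dict(rng=rng, likelihood=params.likelihood)
        self.joint = ClusterModel(self.stats, params.alpha, "joint",
                                  self.n_goals, **kw)
        self.ind_map = ClusterModel(self.stats, params.alpha, "mapping_only",
                                    self.n_goals, **kw)
        self.ind_goal = ClusterModel(self.stats, params.alpha, "reward_only",
                                     self.n_goals, **kw)
        self.meta_state = MetaState(prior=np.asarray(params.meta_prior, dtype=float))
        self.active = 0  # index into STRATEGIES
        self._beliefs = None  # per-strategy goal beliefs stashed at plan time

    def _reassign(self, context: int) -> None:
        self.joint.assign_map(context)
        self.ind_map.assign_map(context)
        self.ind_goal.assign_map(context)
        w = self.meta_state.weights()
        self.active = int(self.rng.choice(len(w), p=w))

    def _cluster_models(self) -> list:
        return [self.joint, self.ind_map, self.ind_goal]

    def _midtrial_update(self) -> None:
        self.joint.assign_map(self.context)
        self.ind_map.assign_map(self.context)

    def _post_outcome_reassign(self) -> None:
        self.joint.assign_map(self.context)
        self.ind_goal.assign_map(self.context)

    def _strategy_beliefs(self, context: int):
        b_ind = self.ind_goal.goal_belief_of(self.ind_goal.cluster_of(context))
        b_joint = self.joint.goal_belief_of(self.joint.cluster_of(context))
        return (b_ind, b_joint)

    def goal_values(self, context: int) -> np.ndarray:
        return self._strategy_beliefs(context)[self.active]

    def _mapping_counts_for_action(self, context: int) -> np.ndarray:
        model = self.ind_map if self.active == 0 else self.joint
        k = model.cluster_of(context)
        mc = np.zeros((N_KEYS, N_OUTCOMES))
        for c, kk in model.assignments.items():
            if kk == k:
                mc += self.stats[c].map_counts
        return mc

    def observe_goal(self, goal, reward):
        if goal is not None:
            g = self._goal_idx[goal]
            pred = []
            # each strategy's prediction for the observed outcome, evaluated
            # before this trial's goal update
            for b in self._strategy_beliefs(self.context):
                p = b[g] if reward else 1.0 - b[g]
                pred.append(max(p, META_EVIDENCE_FLOOR))
            self.meta_state.log_evidence = self.meta_state.log_evidence + np.log(pred)
        super().observe_goal(goal, reward)


def make_agent(params: AgentParams, design, rng) -> Agent:
    if params.model in ("joint", "independent", "flat"):
        return ClusteringAgent(params, design, rng)
    if params.model == "qlearn":
        return QLearningAgent(params, design, rng)
    if params.model == "ucb":
        return UCBAgent(params, design, rng)
    if params.model == "meta":
        return MetaAgent(params, design, rng)
    raise ValueError(f"unknown model {params.model!r}")
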