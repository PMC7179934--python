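# gridgen

Context-clustering reinforcement-learning agents for grid-world navigation
tasks that dissociate *what to do* (which goal is rewarded) from *how to do
it* (which keys move the agent), and the statistical machinery to compare
their generalization predictions with human-style choice data.

When people meet a novel situation they can re-use whole task strategies
(conjunctive transfer) or recombine parts — a reward preference learned in
one place with a motor mapping learned in another (compositional transfer).
This package implements the computational account of that trade-off: agents
that cluster contexts with a Chinese-restaurant-process (CRP) prior and
either tie the transition function φ(a, A) and reward function R(g) together
in one cluster per context (**joint**), cluster them separately
(**independent**), or arbitrate between both strategies by their accumulated
reward-prediction evidence, w_m ∝ (∏_t Pr(r_t|m))·Pr(m) (**meta**) — plus
three non-generalizing controls (flat / Q-learning / Kalman-UCB). Planning is
tabular value iteration on the 6×6 grid (γ = 0.8) with softmax action
selection, Pr(A|s) ∝ exp(β·Q(s, A)).

Three built-in task designs vary how informative the mapping is about the
rewarded goal across training contexts, indexed by the normalized mutual
information NMI = I(G; M)/H(G) over contexts (1.0, ≈0.17, ≈0.31). The
agents' diagnostic test-context contrasts — batch-level accuracy difference
scores with 95% highest-density intervals — separate the three
generalization strategies, and a hierarchical Bayesian logistic regression
(β_i ~ N(μ, σ), μ ~ N(0, 100), σ ~ Half-Cauchy(0, 100), custom blocked MCMC)
provides the subject-level analysis, validated by parameter recovery on a
synthetic choice generator.

## Layout

    src/gridgen/        library: taskenv, planner, agents, simulation,
                        analysis, behavstats
    analysis/           numbered drivers (01 designs ... 06 similarity)
    scripts/acceptance.py
    tests/              pytest suite (unit, property, acceptance)
    docs/methods.md     model, parameters, numerical choices, limitations

## Worked example

Build the designs and check their structure statistics:

    $ python analysis/01_build_designs.py
    experiment  n_training_contexts  n_train_trials  n_test_trials    nmi
      1_repeat                    3              32             16 1.0000
      1_switch                    3              32             16 1.0000
             2                    7             112             24 0.1661
             3                    5             120             30 0.3063

Experiment 1's training contexts make the goal a deterministic function of
the mapping (NMI = 1); experiment 2 nearly decouples them (0.17); experiment
3 is intermediate (0.31). Simulate first-trial goal choices in experiment 2's
novel test contexts:

    $ python analysis/04_first_trial_choices.py --n-sims 100 --models independent flat
    independent  low_mapping_ctx12:  counts {'A': 152, 'B': 40, 'C': 4, 'D': 4}   E[theta_A]=0.757  A-(B+C)/2=+0.644
    independent  high_mapping_ctx34: counts {'A': 160, 'B': 25, 'C': 6, 'D': 9}   E[theta_A]=0.797  A-(B+C)/2=+0.716
    flat         low_mapping_ctx12:  counts {'A': 45, 'B': 56, 'C': 47, 'D': 47}  E[theta_A]=0.233  A-(B+C)/2=-0.033
    flat         high_mapping_ctx34: counts {'A': 49, 'B': 45, 'C': 51, 'D': 49}  E[theta_A]=0.255  A-(B+C)/2=+0.005

The independent agent tries the overall-most-popular goal A first regardless
of which mapping the context uses (posterior choice probability ≈ 0.76–0.80,
contrast against goals B/C strongly positive), while the non-generalizing
flat agent explores uniformly (≈ 0.25, contrast ≈ 0). That mapping-blind
preference for the popular goal is the signature of compositional
generalization.

The same pipeline exposes the full contrast tables
(`analysis/03_model_contrasts.py`), the batch protocol
(`analysis/02_simulate_agents.py`), regression parameter recovery
(`analysis/05_behavior_recovery.py`) and the model-behavior angle-cosine
similarity (`analysis/06_similarity.py`).

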