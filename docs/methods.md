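# Methods

## The task family

Each task is a 6×6 grid world. On every trial the subject (or simulated
agent) starts at a random cell and must enter one of several labeled goal
squares, whose locations are re-randomized each trial. A color-cued *context*
determines two hidden pieces of structure:

* the **mapping** — which four of the eight response keys
  (`a s d f j k l ;`) move the agent North/South/East/West. One mapping uses
  the left hand, one the right, each with a different left-to-right ordering
  (`W N S E` or `N W E S`), so knowledge of one mapping cannot be transformed
  into the other. Keys of the inactive hand do nothing.
* the **rewarded goal** — exactly one labeled goal pays a unit reward; the
  others pay nothing.

Movement is deterministic; on a third of trials four random interior wall
edges are added (re-sampled until every goal stays reachable) to force
re-planning. Trials end on entry into any goal square.

Three built-in designs manipulate the statistical relationship between
mapping and rewarded goal across training contexts, summarized by the
normalized mutual information NMI = I(G;M)/H(G) computed over distinct
training contexts (each context counted once — "context popularity"):

| design | training contexts (mapping, goal × trials) | test contexts | NMI |
|---|---|---|---|
| 1 | high×(A,8), high×(A,8), low×(B,16) | A4, A4, B8 (repeat or switch mapping pairing, between-subjects) | 1.0 |
| 2 | low: A14 B14 C28; high: A7 A7 B14 D28 | A-low 6, B-low 6, C-high 6, D-high 6 | 0.166 |
| 3 | low: A20 C40; high: A10 A10 B40 | A-low 10, B-high 10, C-high 5, C-low 5 | 0.306 |

Training trial counts satisfy the balance constraint (equal totals per
mapping and per rewarded goal). The experiment-2 allocation is
under-determined by that constraint; the table above is the smallest-integer
solution. Experiment 1 displays two goal squares (A, B; chance = 1/2): its
training contexts pair "one of two potential goals" and the test phase only
ever rewards A or B. Experiments 2 and 3 display four and three goal squares
(chance 1/4 and 1/3).

Training context order is generated half-by-half: each context contributes
half its trials to each half (±1 for odd counts, totals balanced), and the
within-half order realizes a target context-switch hazard (25% first half, 8%
second) by drawing the switch count from the corresponding binomial, clamped
to the feasible range, splitting each context's trials into runs, and
arranging runs with no two adjacent runs sharing a context. Test order is a
uniform permutation.

Coordinates are `(col, row)` with the origin at the north-west corner; `E`
increments `col`, `S` increments `row`.

## Agents

All six agents share the same planner and action selection and differ only in
how they carry structure across contexts.

**Learning.** Mapping knowledge is a count table over (key × outcome), where
an outcome is one of N/S/E/W/NONE; the attempted movement is fully observed
even when a barrier blocks it. Estimates are smoothed with a symmetric
pseudo-count of 0.01 per cell so that an empty table yields uniform
distributions. The rewarded-goal belief is eliminative: a rewarded outcome at
goal g makes the belief a point mass at g; an unrewarded outcome at g removes
g and renormalizes; contradictory evidence (possible only transiently inside
a shared cluster) falls back to uniform over the non-eliminated goals. These
are the maximum-likelihood estimates for a deterministic task.

**Clustering.** The generalizing agents assign contexts to clusters under a
Chinese-restaurant-process prior, Pr(c∈k) = N_k/(N+α) for existing clusters
and α/(N+α) for a new one, where N_k counts *distinct* contexts. The
*joint* agent keeps one clustering whose likelihood combines mapping and goal
observations; the *independent* agent keeps two clusterings (mapping-only and
reward-only likelihoods); the *flat* agent is the α→∞ limit (one cluster per
context). Acting uses the maximum-a-posteriori assignment, re-evaluated

* at every trial start,
* within a trial whenever a keypress outcome is surprising (probability
  < 0.5 under the acting mapping estimate) — so a wrongly assumed mapping is
  abandoned mid-trial rather than wasting the whole trial, and
* immediately after each trial's goal outcome — so a context whose outcome
  contradicts its cluster leaves at once instead of poisoning the cluster's
  belief for other contexts.

Exact posterior ties break toward the oldest cluster, making assignment
deterministic given the history. Cluster statistics are sums over member
contexts, so reassignment automatically removes a context's evidence.

**Cluster likelihood.** The default likelihood of a context's history under a
candidate cluster is the posterior-predictive (exchangeable) form: a
Dirichlet-multinomial marginal for the mapping counts and a sequential
predictive replay for the goal outcomes, both conditioned on the cluster's
other members' data. The plug-in form (history evaluated against the
cluster's current smoothed ML estimates) is available via
`AgentParams(likelihood="plugin")`; it differs mainly in pathologically
penalizing a fresh cluster for data the cluster itself would have explained.

**Planning and acting.** Given the trial's grid and the acting cluster's goal
belief, values are solved by tabular value iteration with goal squares
absorbing and γ = 0.8: V(s) = max_A Σ_s' T(s,A,s')(R(s') + γV(s')); movement
values Q(s,A) use the same discounted backup (an undiscounted readout variant
exists behind a flag, matching a printed equation that omits γ). Movements
are sampled from a softmax with inverse temperature β over the four cardinal
movements; the keypress is then sampled from the inverse mapping estimate
φ̂(a|A). A trial is capped at 100 keypresses (far above optimal path
lengths); a capped trial scores zero with no goal outcome observed.

**Meta-generalization.** The meta agent maintains the joint and independent
clusterings simultaneously (both observe every trial) and, once per trial
before planning, samples which strategy acts with probability
w_m ∝ exp(Σ_t log Pr(r_t|m))·Pr(m). Pr(r_t|m) is the probability strategy m's
goal belief assigned to the observed outcome at the chosen goal, evaluated
before that trial's update and floored at 0.01 to keep the log evidence
finite; the priors Pr(m) are drawn once per subject, uniform on (0,1).

**Non-generalizing controls.** The Q-learning agent replaces the eliminative
goal belief with a per-context delta rule R(g) ← R(g) + η(r − R(g)); the UCB
agent tracks per-context Kalman estimates with exploration value
μ + ω σ², gain G = (μ+ζ)/(μ+ζ+ε) (implemented as printed, with μ in the gain;
a conventional variance-based gain sits behind a flag), clamped to [0, 1].
Both use flat, per-context mapping learning, and initialize goal values at
1/|goals| (σ² = 1), an optimistic symmetric start.

## Simulation protocol

Population parameter distributions: log α ~ N(−0.5, 1), log β ~ N(2, 0.5);
η, ω, ζ, ε are inverse-logit transforms of N(−1, 1) draws; γ is fixed at 0.8.
Each simulated subject draws fresh parameters and a fresh task instantiation
(context order, placements, barriers). Cohorts are resampled into 200
sample-size-matched batches (80/49 for experiment 1 repeat/switch, 114 and
115 for experiments 2 and 3), without replacement within a batch and
independently across batches. Contrasts are batch-level differences in mean
test accuracy between context sets (between cohorts for the experiment-1
repeat/switch comparison, whose test totals are matched by design).
Within-subjects contrasts compare contexts at **matched trials-in-context**:
every context in the comparison is truncated to the smallest per-context
trial count involved, so learning curves are compared at equal amounts of
experience. Without this, unequal trial counts alone manufacture differences —
a purely within-context learner loses its first-trial chance deficit at
weight 1/4 in a 4-trial context but 1/8 in an 8-trial one — whereas with it
the non-generalizing agents' contrasts are structurally zero, the property
that makes these comparisons diagnostic of generalization. Each contrast is
summarized by the mean over batches, the 95% highest-density interval
(shortest window over the sorted batch scores), and a one-tailed tail
probability floored at 1/200. Significance means the HPD excludes zero.

The published protocol simulates 2500 subjects per agent-task pair; the
acceptance script and tests use 500 (with identical batching), which leaves
batch means essentially unchanged and modestly narrows the spread of batch
scores. All randomness flows from a single seed per cohort through
`numpy.random.SeedSequence`.

## Subject-level statistics and their validation

Test accuracy is modeled with a hierarchical Bayesian logistic regression:
per-subject coefficient vectors β_i ~ N(μ, diag σ²) over the design's
predictors (experiment 1: switch condition S, high-popularity goal H;
experiments 2–3: three mutually orthogonal ±1 context contrasts; all designs:
trials-in-context t and the sequential-repeat-correct indicator rep), with
μ_p ~ N(0, 100) and σ_p ~ Half-Cauchy(0, 100). The sampler is Pólya-Gamma
Gibbs: PG(1, η) auxiliaries per trial (drawn exactly with Devroye's
alternating-series method, validated against the closed-form moments
E[PG(1,c)] = tanh(c/2)/(2c)) make each subject's coefficient block a
conjugate Gaussian; the group means get conjugate normal updates and the
group scales univariate slice sampling on log σ plus an interweaved
non-centered update (holding the standardized subject offsets fixed) that
breaks the funnel coupling with the subject effects. Convergence is monitored
with split-chain R̂ (arviz) on all group-level parameters; results are
withheld above 1.05 and the sampler re-run longer. The slowest-mixing
component is the scale of a between-subjects predictor (informative for only
one condition's subjects), with an autocorrelation time of roughly a dozen
sweeps; default runs draw enough samples to push its effective sample size
past the diagnostic's requirement.

Because the study's raw behavioral data are not distributed, the regression
is validated by parameter recovery: synthetic cohorts are generated from the
model itself (a generative twin: real generated context orders supply the
joint structure of t and rep; subject coefficients drawn around group values
with spread 0.5, a typical between-subject logit spread), using the published
human point estimates as generator settings. Posterior 95% HPDs should cover
the generating values in ≥90% of replications and cover zero at close to the
nominal rate on null-generated data. Passing these checks shows the fitter is
correct and calibrated at the study's scale; it does not certify any claim
about real subjects.

First-trial goal choices are analyzed with independent Bernoulli models per
goal under conjugate Beta(1,1) priors, summarized by posterior means, HPDs,
and the contrast θ_A − (θ_B+θ_C)/2. Model-behavior similarity is the cosine
of the angle between the two-dimensional vector of an agent's diagnostic
contrasts and the corresponding behavioral coefficient vector.

## Numerical and design choices

* Value iteration runs to a 1e-6 sup-norm tolerance (contraction at rate γ);
  the brute-force dynamic-programming oracle in the tests agrees to < 1e-6 on
  all 36 start cells.
* The HPD of n samples is the shortest window containing ⌈0.95·n⌉ sorted
  samples; this matches an exhaustive window search exactly and arviz's
  implementation to within one sample.
* Keypress cap 100: with median β ≈ 7.4 capped trials are rare (≪1%) and are
  scored unrewarded with no goal observation.
* Barrier placement ("a subset of trials"): one third of trials, four
  interior wall edges each, resampled until all goals are reachable.
* The hazard-rate order generator is one admissible reading of "permuting the
  order subject to a hazard rate"; its empirical first-half switch rate is
  0.25 ± 0.03 over seeds.
* Key symbols are fixed to the printed eight; permuting them across subjects
  is behaviorally inert for all agents and is omitted.

## Known limitations

* Simulated contrasts reproduce the published signs, the full significance
  pattern (including all null predictions), and most magnitudes; the joint
  agent's conditional-popularity contrasts (experiment 2 ctx3−ctx4, and to a
  lesser degree experiment 3 ctx2−ctx3) come out somewhat larger than
  published. These quantities are sensitive to post-failure exploration
  dynamics that the published equations do not fully pin down (our MAP agents
  recover from an elimination in a single trial and search same-mapping
  clusters in strict conditional-popularity order); several other contrasts
  sit within a batch-noise width of their published interval edges.
* The synthetic choice generator shares the regression model's functional
  form, so recovery tests validate the fitter, not the regression's adequacy
  for real behavior; covariate structure (t, rep) is realistic but outcome
  noise is exactly Bernoulli-logistic.
* The behavioral similarity analysis uses published point estimates as the
  behavioral vectors rather than subject-level posteriors.
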