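"""Synthetic choice data and subject-level Bayesian statistics.

Two analyses operate on subject choice data (binary goal accuracy per test
trial):

1. A hierarchical Bayesian logistic regression of accuracy on condition
   contrasts plus nuisance covariates (trials-in-context ``t`` and the
   sequential-repeat-correct indicator ``rep``), with per-subject coefficient
   vectors drawn from group-level normals: ``beta_i ~ N(mu, sigma)``,
   ``mu ~ N(0, 100)``, ``sigma ~ Half-Cauchy(0, 100)``.
2. Group-level Bernoulli models of first-trial goal choice with conjugate
   Beta(1, 1) priors, summarized by the contrast
   ``theta_A - (theta_B + theta_C) / 2``.

Because subject data are not distributed with the study, a generative twin of
the regression model produces synthetic datasets with realistic covariate
structure (context orders drawn from the task's own test-phase generator);
parameter-recovery studies validate the fitter against it.

The regression is fitted by Polya-Gamma Gibbs sampling: with PG(1, eta)
auxiliaries per trial (drawn exactly with Devroye's alternating-series
method), the per-subject coefficient blocks are conjugate Gaussians; the
group means have conjugate normal updates, the group scales use univariate
slice sampling plus an interweaved non-centered update that breaks the
funnel coupling with the subject effects. Split-chain R-hat (via arviz) is
the convergence diagnostic; results are withheld when it exceeds 1.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from . import taskenv
from .analysis import CONTRASTS, PosteriorSummary, hpd_interval

MU_PRIOR_SD = 100.0
SIGMA_PRIOR_SCALE = 100.0


class ConvergenceError(RuntimeError):
    """Raised when split-chain R-hat exceeds the contract threshold."""


@dataclass(frozen=True)
class RegressionSpec:
    """Predictor list for the hierarchical logistic regression."""

    predictors: tuple

    @staticmethod
    def for_experiment(experiment: int) -> "RegressionSpec":
        if experiment == 1:
            return RegressionSpec(("S", "H", "t", "rep"))
        key = str(experiment)
        names = tuple(c.name for c in CONTRASTS[key]) + ("t", "rep")
        return RegressionSpec(names)


def contrast_codes(experiment: int) -> pd.DataFrame:
    """Per-test-context contrast codes (+1 member of the positive set, -1
    negative, 0 otherwise). The three codes are mutually orthogonal."""
    specs = CONTRASTS[str(experiment)]
    ordinals = sorted({o for s in specs for o in s.positive + s.negative})
    table = {}
    for s in specs:
        if s.between_subjects:
            continue
        col = {o: 0.0 for o in ordinals}
        col.update({o: 1.0 for o in s.positive})
        col.update({o: -1.0 for o in s.negative})
        table[s.name] = col
    df = pd.DataFrame(table)
    mat = df.to_numpy()
    gram = mat.T @ mat
    if not np.allclose(gram - np.diag(np.diag(gram)), 0):
        raise ValueError("contrast codes are not orthogonal")
    return df


# ---------------------------------------------------------------------------
# Synthetic choice generation
# ---------------------------------------------------------------------------


def simulate_choices(design: taskenv.ExperimentDesign, coefficients: dict,
                     subject_sd: float, n_subjects: int, seed,
                     n_condition_b: int = 0) -> pd.DataFrame:
    """Generate a synthetic test-phase choice dataset.

    Outcomes are Bernoulli with ``logit(p) = x . beta_subject`` where each
    subject's coefficient vector is drawn Normal around the group values with
    spread ``subject_sd``. Covariates come from a real generated context order,
    so ``t`` (trials in context, counted from 1) and ``rep`` (sequential repeat
    of a previously-correct context) have their natural joint structure.

    For experiment 1, ``n_condition_b`` subjects receive ``S = 1`` (the
    between-subjects switch condition); the ``H`` covariate marks contexts
    whose rewarded goal is the high-popularity goal A.
    """
    rng = np.random.default_rng(seed)
    exp = int(design.experiment[0])
    spec = RegressionSpec.for_experiment(exp)
    unknown = set(coefficients) - set(spec.predictors)
    if unknown:
        raise ValueError(f"unknown predictor keys {sorted(unknown)}")
    group = np.array([coefficients.get(p, 0.0) for p in spec.predictors])
    codes = contrast_codes(exp) if exp != 1 else None
    test_ord = {c.context_id: i + 1 for i, c in enumerate(design.test_contexts)}

    rows = []
    for subj in range(n_subjects):
        beta = rng.normal(group, subject_sd)
        s_cov = 1.0 if subj >= n_subjects - n_condition_b else 0.0
        order = taskenv.generate_context_order(design, "test", rng)
        t_in_ctx: dict[int, int] = {}
        prev_ctx, prev_correct = None, False
        for ctx in order:
            t_in_ctx[ctx] = t_in_ctx.get(ctx, 0) + 1
            rep = 1.0 if (ctx == prev_ctx and prev_correct) else 0.0
            ordinal = test_ord[ctx]
            x = {}
            if exp == 1:
                x["S"] = s_cov
                x["H"] = 1.0 if design.context(ctx).rewarded_goal == "A" else 0.0
            else:
                for name in codes.columns:
                    x[name] = codes.loc[ordinal, name]
            x["t"] = float(t_in_ctx[ctx])
            x["rep"] = rep
            eta = sum(beta[i] * x[p] for i, p in enumerate(spec.predictors))
            y = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
            rows.append({"subject_id": subj, "context_id": ctx,
                         "test_index": ordinal, "outcome": y, **x})
            prev_ctx, prev_correct = ctx, bool(y)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hierarchical logistic regression (blocked MCMC)
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Posterior draws and summaries for the group-level coefficients."""

    summaries: dict  # predictor -> PosteriorSummary (on the group mean)
    mu_draws: np.ndarray  # (chains, draws, predictors)
    sigma_draws: np.ndarray
    rhat: dict
    predictors: tuple


def _log_half_cauchy(x, scale):
    return -np.log1p((x / scale) ** 2)  # up to a constant


def _slice_sample(logpdf, x0, rng, w=1.0, max_steps=50):
    """Univariate slice sampler (stepping-out then shrinkage)."""
    logy = logpdf(x0) + np.log(rng.random())
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logpdf(lo) < logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logpdf(hi) < logy:
            break
        hi += w
    while True:
        x1 = rng.uniform(lo, hi)
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


try:
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _row_eta(X, beta, subj_idx):  # pragma: no cover - jitted
        n, p = X.shape
        eta = np.zeros(n)
        for r in range(n):
            s = subj_idx[r]
            acc = 0.0
            for j in range(p):
                acc += X[r, j] * beta[s, j]
            eta[r] = acc
        return eta

    @njit(cache=True, fastmath=True)
    def _subject_ll_from_eta(eta, y, subj_idx, n_subj):  # pragma: no cover
        out = np.zeros(n_subj)
        for r in range(eta.shape[0]):
            e = eta[r]
            if e > 0:
                ll = y[r] * e - (e + np.log1p(np.exp(-e)))
            else:
                ll = y[r] * e - np.log1p(np.exp(e))
            out[subj_idx[r]] += ll
        return out

    @njit(cache=True, fastmath=True)
    def _total_ll_from_eta(eta, y):  # pragma: no cover
        acc = 0.0
        for r in range(eta.shape[0]):
            e = eta[r]
            if e > 0:
                acc += y[r] * e - (e + np.log1p(np.exp(-e)))
            else:
                acc += y[r] * e - np.log1p(np.exp(e))
        return acc

    @njit(cache=True, fastmath=True)
    def _shifted_total_ll(base, direction, scale, y):  # pragma: no cover
        """Total log-likelihood at eta = base + scale * direction (fused)."""
        acc = 0.0
        for r in range(base.shape[0]):
            e = base[r] + scale * direction[r]
            if e > 0:
                acc += y[r] * e - (e + np.log1p(np.exp(-e)))
            else:
                acc += y[r] * e - np.log1p(np.exp(e))
        return acc
except Exception:  # pragma: no cover
    def _row_eta(X, beta, subj_idx):
        return np.einsum("rp,rp->r", X, beta[subj_idx])

    def _subject_ll_from_eta(eta, y, subj_idx, n_subj):
        row_ll = y * eta - np.logaddexp(0.0, eta)
        return np.bincount(subj_idx, weights=row_ll, minlength=n_subj)

    def _total_ll_from_eta(eta, y):
        return float((y * eta - np.logaddexp(0.0, eta)).sum())

    def _shifted_total_ll(base, direction, scale, y):
        return _total_ll_from_eta(base + scale * direction, y)


def _subject_logliks(X, y, subj_idx, n_subj, beta):
    eta = _row_eta(X, beta, subj_idx)
    return _subject_ll_from_eta(eta, y, subj_idx, n_subj)


# ---------------------------------------------------------------------------
# Polya-Gamma PG(1, z) sampling (Devroye's alternating-series method)
# ---------------------------------------------------------------------------

_PG_TRUNC = 0.64

try:
    from numba import njit as _pg_njit
except Exception:  # pragma: no cover
    def _pg_njit(*a, **k):
        if a and callable(a[0]):
            return a[0]
        return lambda f: f


@_pg_njit(cache=True)
def _norm_cdf(x):  # pragma: no cover - jitted
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@_pg_njit(cache=True)
def _a_coef(n, x, t):  # pragma: no cover - jitted
    d = n + 0.5
    if x <= t:
        return (math.pi * d * math.pow(2.0 / (math.pi * x), 1.5)
                * math.exp(-2.0 * d * d / x))
    return math.pi * d * math.exp(-0.5 * x * math.pi * math.pi * d * d)


@_pg_njit(cache=True)
def _rtigauss(z, t):  # pragma: no cover - jitted
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t]."""
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection from the one-sided stable kernel
        while True:
            while True:
                e1 = -math.log(1.0 - np.random.random())
                e2 = -math.log(1.0 - np.random.random())
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    mu = 1.0 / z
    while x > t:
        y = np.random.normal()
        y = y * y
        x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(
            4.0 * mu * y + (mu * y) * (mu * y))
        if np.random.random() > mu / (mu + x):
            x = mu * mu / x
    return x


@_pg_njit(cache=True)
def _pg_draw(z_in):  # pragma: no cover - jitted
    z = abs(z_in) * 0.5
    t = _PG_TRUNC
    k = 0.125 * math.pi * math.pi + 0.5 * z * z
    if z > 1e-12:
        ig_cdf = (_norm_cdf((t * z - 1.0) / math.sqrt(t))
                  + math.exp(2.0 * z) * _norm_cdf(-(t * z + 1.0) / math.sqrt(t)))
    else:
        ig_cdf = 2.0 * _norm_cdf(-1.0 / math.sqrt(t))
    p = 0.5 * math.pi / k * math.exp(-k * t)
    q = 2.0 * math.exp(-z) * ig_cdf
    ratio = p / (p + q)
    while True:
        if np.random.random() < ratio:
            x = t - math.log(1.0 - np.random.random()) / k
        else:
            x = _rtigauss(z, t)
        s = _a_coef(0, x, t)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x, t)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x, t)
                if y > s:
                    break
        if accept:
            return 0.25 * x


@_pg_njit(cache=True)
def _pg_vector(zs, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    out = np.empty(zs.shape[0])
    for i in range(zs.shape[0]):
        out[i] = _pg_draw(zs[i])
    return out


def sample_polya_gamma(z, seed: int) -> np.ndarray:
    """Draw PG(1, z_i) variables elementwise (Devroye's exact method)."""
    return _pg_vector(np.ascontiguousarray(np.abs(z), dtype=np.float64),
                      int(seed) % (2**31 - 1))


def fit_hierarchical_logistic(data: pd.DataFrame, spec: RegressionSpec,
                              n_chains: int = 4, n_warmup: int = 400,
                              n_draws: int = 1500, seed=0,
                              rhat_threshold: float = 1.05) -> RegressionResult:
    """Fit the hierarchical logistic regression by Polya-Gamma Gibbs sampling.

    Raises :class:`ConvergenceError` if any group-level parameter's split-chain
    R-hat exceeds ``rhat_threshold``.
    """
    missing = [p for p in spec.predictors if p not in data.columns]
    if missing:
        raise ValueError(f"data lacks predictor columns {missing}")
    X = data[list(spec.predictors)].to_numpy(dtype=float)
    y = data["outcome"].to_numpy(dtype=float)
    subjects = np.unique(data["subject_id"])
    subj_idx = np.searchsorted(subjects, data["subject_id"].to_numpy())
    n_subj, p = len(subjects), len(spec.predictors)
    kappa = y - 0.5
    xk = X * kappa[:, None]
    diag = np.arange(p)

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    mu_out = np.empty((n_chains, n_draws, p))
    sigma_out = np.empty((n_chains, n_draws, p))

    for ch in range(n_chains):
        rng = np.random.default_rng(chain_seeds[ch])
        mu = rng.normal(0, 0.5, size=p)
        sigma = np.ones(p)
        beta = np.tile(mu, (n_subj, 1)) + rng.normal(0, 0.1, size=(n_subj, p))

        for it in range(n_warmup + n_draws):
            # -- Polya-Gamma augmentation: omega_r ~ PG(1, eta_r) -------
            eta = _row_eta(X, beta, subj_idx)
            omega = sample_polya_gamma(eta, rng.integers(2**31 - 1))

            # -- subject coefficients: exact conjugate Gaussian ---------
            # per subject: N(A^-1 b, A^-1), A = X' diag(omega) X + S^-1,
            # b = X' (y - 1/2) + S^-1 mu
            prec = np.empty((n_subj, p, p))
            for j in range(p):
                for k in range(j, p):
                    s = np.bincount(subj_idx, weights=omega * X[:, j] * X[:, k],
                                    minlength=n_subj)
                    prec[:, j, k] = s
                    prec[:, k, j] = s
            prec[:, diag, diag] += 1.0 / sigma**2
            b = np.empty((n_subj, p))
            for j in range(p):
                b[:, j] = np.bincount(subj_idx, weights=xk[:, j],
                                      minlength=n_subj)
            b += mu / sigma**2
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, b[..., None])[..., 0]
            eps = rng.standard_normal((n_subj, p))
            beta = mean + np.linalg.solve(
                np.transpose(chol, (0, 2, 1)), eps[..., None])[..., 0]

            # -- group means: conjugate Gibbs ---------------------------
            prec = n_subj / sigma**2 + 1.0 / MU_PRIOR_SD**2
            mean = (beta.sum(axis=0) / sigma**2) / prec
            mu = rng.normal(mean, 1.0 / np.sqrt(prec))

            # -- group scales: slice sampling on log sigma --------------
            for j in range(p):
                resid2 = ((beta[:, j] - mu[j]) ** 2).sum()

                def logpdf(x, resid2=resid2):
                    s = np.exp(x)
                    return (-n_subj * x - 0.5 * resid2 / s**2
                            + _log_half_cauchy(s, SIGMA_PRIOR_SCALE) + x)

                sigma[j] = np.exp(_slice_sample(logpdf, np.log(sigma[j]), rng))

            # -- interweaved (non-centered) scale update ----------------
            # holding z = (beta - mu) / sigma fixed, a change in sigma moves
            # every subject's coefficient, which breaks the funnel coupling
            # between the scales and the subject effects
            z = (beta - mu) / sigma
            eta0 = _row_eta(X, beta, subj_idx)
            for j in range(p):
                zj_rows = z[subj_idx, j] * X[:, j]
                base = eta0 - sigma[j] * zj_rows

                def logpdf_nc(x, base=base, zj_rows=zj_rows):
                    s = np.exp(x)
                    ll = _shifted_total_ll(base, zj_rows, s, y)
                    return ll + _log_half_cauchy(s, SIGMA_PRIOR_SCALE) + x

                new = np.exp(_slice_sample(logpdf_nc, np.log(sigma[j]), rng,
                                           w=0.5))
                eta0 = base + new * zj_rows
                sigma[j] = new
                beta[:, j] = mu[j] + sigma[j] * z[:, j]

            if it >= n_warmup:
                mu_out[ch, it - n_warmup] = mu
                sigma_out[ch, it - n_warmup] = sigma

    idata = az.from_dict(posterior={
        "mu": mu_out, "sigma": sigma_out,
    })
    rhat_ds = az.rhat(idata)
    rhat = {}
    for j, name in enumerate(spec.predictors):
        rhat[f"mu[{name}]"] = float(rhat_ds["mu"].values[j])
        rhat[f"sigma[{name}]"] = float(rhat_ds["sigma"].values[j])
    worst = max(rhat.values())
    if worst > rhat_threshold:
        raise ConvergenceError(
            f"split-chain R-hat {worst:.3f} exceeds {rhat_threshold}; "
            "results withheld")

    summaries = {}
    for j, name in enumerate(spec.predictors):
        draws = mu_out[:, :, j].ravel()
        low, high = hpd_interval(draws)
        mean = float(draws.mean())
        wrong = (draws <= 0).mean() if mean > 0 else (draws >= 0).mean()
        summaries[name] = PosteriorSummary(
            mean=mean, hpd_low=low, hpd_high=high,
            p_one_tail=max(float(wrong), 1.0 / draws.size))
    return RegressionResult(summaries=summaries, mu_draws=mu_out,
                            sigma_draws=sigma_out, rhat=rhat,
                            predictors=spec.predictors)


def sample_prior(spec: RegressionSpec, n: int, seed=0) -> pd.DataFrame:
    """Draws from the group-level prior (for prior-predictive checks)."""
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, MU_PRIOR_SD, size=(n, len(spec.predictors)))
    sigma = np.abs(SIGMA_PRIOR_SCALE * rng.standard_cauchy((n, len(spec.predictors))))
    out = {}
    for j, name in enumerate(spec.predictors):
        out[f"mu[{name}]"] = mu[:, j]
        out[f"sigma[{name}]"] = sigma[:, j]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Group-level Bernoulli goal-choice model
# ---------------------------------------------------------------------------


def goal_choice_binomial(counts: dict, contrast_goals=("A", ("B", "C")),
                         n_draws: int = 20_000, seed=0) -> dict:
    """Conjugate Beta posteriors for first-trial goal-choice rates.

    ``counts`` maps each goal label to its choice count; every first-trial
    choice is a Bernoulli success for the chosen goal and failure for the rest.
    Returns per-goal :class:`PosteriorSummary` objects plus the contrast
    ``theta_A - mean(theta_B, theta_C)``.
    """
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no choices recorded")
    rng = np.random.default_rng(seed)
    draws = {}
    out = {}
    for g, k in counts.items():
        d = rng.beta(1 + k, 1 + total - k, size=n_draws)
        draws[g] = d
        low, high = hpd_interval(d)
        out[f"theta[{g}]"] = PosteriorSummary(float(d.mean()), low, high)
    top, others = contrast_goals
    contrast = draws[top] - np.mean([draws[g] for g in others], axis=0)
    low, high = hpd_interval(contrast)
    mean = float(contrast.mean())
    wrong = (contrast <= 0).mean() if mean > 0 else (contrast >= 0).mean()
    out["contrast"] = PosteriorSummary(
        mean, low, high, p_one_tail=max(float(wrong), 1.0 / n_draws))
    return out
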