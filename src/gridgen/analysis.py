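"""Model-prediction statistics: accuracies, batch contrasts, HPDs, similarity.

The central quantity is a batch-level contrast: for each of the 200
sample-size-matched batches, the mean goal accuracy over one set of test
contexts minus the mean over another (or, between subjects, one cohort's test
accuracy minus another's). The distribution of the 200 batch scores yields a
mean, a 95% highest-density interval, and a one-tailed tail probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulation import BatchSet


@dataclass(frozen=True)
class ContrastSpec:
    """A named difference score between sets of test contexts (by ordinal)."""

    experiment: str
    name: str
    positive: tuple  # test-context ordinals (1-based), or () for between-subjects
    negative: tuple
    between_subjects: bool = False

    def __post_init__(self):
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative context sets must be disjoint")


#: The published contrast catalogue. Experiment-1 "repeat_switch" is the
#: between-subjects repeat-minus-switch test accuracy; "goal" compares test
#: contexts rewarded at the popular goal A against the goal-B context.
CONTRASTS = {
    "1": [
        ContrastSpec("1", "repeat_switch", (), (), between_subjects=True),
        ContrastSpec("1", "goal", (1, 2), (3,)),
    ],
    "2": [
        ContrastSpec("2", "c1_c2", (1,), (2,)),
        ContrastSpec("2", "c3_c4", (3,), (4,)),
        ContrastSpec("2", "mapping", (1, 2), (3, 4)),
    ],
    "3": [
        ContrastSpec("3", "c1_c4", (1,), (4,)),
        ContrastSpec("3", "c2_c3", (2,), (3,)),
        ContrastSpec("3", "mapping", (1, 4), (2, 3)),
    ],
}


@dataclass
class PosteriorSummary:
    """Mean, 95% HPD and one-tailed tail probability of a score distribution."""

    mean: float
    hpd_low: float
    hpd_high: float
    mass: float = 0.95
    p_one_tail: float | None = None

    @property
    def significant(self) -> bool:
        """Whether the HPD excludes zero."""
        return not (self.hpd_low <= 0.0 <= self.hpd_high)


def context_accuracy(records: pd.DataFrame, by: str = "phase") -> pd.Series:
    """Mean binary reward per group (``by`` = "phase" or "context")."""
    if records.empty:
        raise ValueError("records are empty")
    if by not in ("phase", "context"):
        raise ValueError("by must be 'phase' or 'context'")
    return records.groupby(by)["reward"].mean()


def _per_sim_accuracy(records: pd.DataFrame, ordinals,
                      max_visits: int | None = None) -> np.ndarray:
    """Per-sim mean test accuracy pooled over the given test-context ordinals.

    ``max_visits`` truncates every context to its first ``max_visits`` trials,
    so contexts with different trial counts are compared at matched amounts of
    experience. Returns an array indexed by sim_id (all sims must share the
    design, so every sim has the same trial counts).
    """
    sel = records[records["test_index"].isin(list(ordinals))]
    if max_visits is not None:
        sel = sel.sort_values("trial")
        visit = sel.groupby(["sim_id", "context"]).cumcount()
        sel = sel[visit < max_visits]
    acc = sel.groupby("sim_id")["reward"].mean()
    return acc.reindex(range(records["sim_id"].max() + 1)).to_numpy()


def batch_scores(records: pd.DataFrame, batches: BatchSet, spec: ContrastSpec,
                 records_b: pd.DataFrame | None = None,
                 batches_b: BatchSet | None = None) -> np.ndarray:
    """Batch-level difference scores for one contrast.

    Within-subjects: per batch, pooled test accuracy over the positive context
    set minus the negative set, with every involved context truncated to the
    smallest per-context trial count in the contrast — accuracies are compared
    at matched trials-in-context, so unequal trial counts cannot manufacture a
    difference (a learner whose only structure is within-context learning
    scores exactly zero in expectation). Between-subjects: the first cohort's
    mean test accuracy minus the second cohort's, batch by batch (test totals
    are matched by design).
    """
    if spec.between_subjects:
        if records_b is None or batches_b is None:
            raise ValueError(
                "between-subjects contrast needs a second cohort's records/batches")
        all_test_a = sorted(records.loc[records["phase"] == "test", "test_index"].unique())
        all_test_b = sorted(records_b.loc[records_b["phase"] == "test", "test_index"].unique())
        acc_a = _per_sim_accuracy(records, all_test_a)
        acc_b = _per_sim_accuracy(records_b, all_test_b)
        return np.array([
            acc_a[ba].mean() - acc_b[bb].mean()
            for ba, bb in zip(batches.batches, batches_b.batches)
        ])
    involved = list(spec.positive) + list(spec.negative)
    counts = records[records["test_index"].isin(involved)].groupby(
        ["sim_id", "test_index"]).size()
    k = int(counts.min())
    pos = _per_sim_accuracy(records, spec.positive, max_visits=k)
    neg = _per_sim_accuracy(records, spec.negative, max_visits=k)
    return np.array([pos[b].mean() - neg[b].mean() for b in batches.batches])


def summarize(scores, mass: float = 0.95) -> PosteriorSummary:
    scores = np.asarray(scores, dtype=float)
    low, high = hpd_interval(scores, mass)
    mean = float(scores.mean())
    wrong = (scores <= 0).mean() if mean > 0 else (scores >= 0).mean()
    p = max(float(wrong), 1.0 / len(scores))
    return PosteriorSummary(mean=mean, hpd_low=low, hpd_high=high, mass=mass,
                            p_one_tail=p)


def contrast_scores(records, batches, spec, records_b=None, batches_b=None):
    """Batch difference scores plus their posterior summary."""
    scores = batch_scores(records, batches, spec, records_b, batches_b)
    return scores, summarize(scores)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing at least ``mass`` of the samples."""
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def first_trial_distribution(records: pd.DataFrame, ordinals) -> pd.Series:
    """Goal-choice counts over each sim's first visit to the given test contexts."""
    sel = records[
        records["test_index"].isin(list(ordinals)) & records["first_context_visit"]
    ]
    return sel.groupby("chosen_goal").size()


def angle_cosine(model_vector, behavior_vector) -> float:
    """Cosine of the angle between a model-contrast and a behavior vector."""
    a = np.asarray(model_vector, dtype=float)
    b = np.asarray(behavior_vector, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle cosine undefined for a zero vector")
    return float(a @ b / (na * nb))
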