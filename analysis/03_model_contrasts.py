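"""Compute the diagnostic test-context contrasts for every agent.

For each experiment and agent, runs the batch-simulation protocol and writes
the contrast table (mean, 95% HPD, one-tailed p) that the study uses to
separate joint, independent and meta generalization, plus a histogram figure
of batch-level effect sizes per agent.

Usage: python analysis/03_model_contrasts.py [--n-sims 200] [--seed 3]
       [--models joint independent meta] [--out results]
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from gridgen import analysis, simulation, taskenv

ALL_MODELS = ("joint", "independent", "meta", "flat", "qlearn", "ucb")


def exp1_scores(model, n_sims, n_batches, seed):
    dr = taskenv.build_design(1, "repeat")
    ds = taskenv.build_design(1, "switch")
    rr, br = simulation.run_cohort(dr, model, n_sims=n_sims,
                                   n_batches=n_batches,
                                   batch_size=min(80, n_sims),
                                   master_seed=seed)
    rs, bs = simulation.run_cohort(ds, model, n_sims=n_sims,
                                   n_batches=n_batches,
                                   batch_size=min(49, n_sims),
                                   master_seed=seed + 1)
    out = {}
    out["repeat_switch"] = analysis.contrast_scores(
        rr, br, analysis.CONTRASTS["1"][0], rs, bs)
    rs2 = rs.copy()
    rs2["sim_id"] += n_sims
    pooled = pd.concat([rr, rs2], ignore_index=True)
    bp = simulation.BatchSet(
        [np.concatenate([a, b + n_sims]) for a, b in zip(br.batches, bs.batches)],
        129)
    out["goal"] = analysis.contrast_scores(pooled, bp, analysis.CONTRASTS["1"][1])
    return out


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-sims", type=int, default=200)
    ap.add_argument("--n-batches", type=int, default=200)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--models", nargs="+", default=list(ALL_MODELS),
                    choices=ALL_MODELS)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    hists = {}
    for model in args.models:
        for name, (scores, summ) in exp1_scores(
                model, args.n_sims, args.n_batches, args.seed).items():
            rows.append({"experiment": "1", "model": model, "contrast": name,
                         "mean": summ.mean, "hpd_low": summ.hpd_low,
                         "hpd_high": summ.hpd_high,
                         "p_one_tail": summ.p_one_tail,
                         "significant": summ.significant})
            hists[("1", model, name)] = scores
        for exp in (2, 3):
            d = taskenv.build_design(exp)
            rec, batches = simulation.run_cohort(
                d, model, n_sims=args.n_sims, n_batches=args.n_batches,
                batch_size=min(args.n_sims, simulation.HUMAN_N[str(exp)]),
                master_seed=args.seed + exp * 100)
            for spec in analysis.CONTRASTS[str(exp)]:
                scores, summ = analysis.contrast_scores(rec, batches, spec)
                rows.append({"experiment": str(exp), "model": model,
                             "contrast": spec.name, "mean": summ.mean,
                             "hpd_low": summ.hpd_low,
                             "hpd_high": summ.hpd_high,
                             "p_one_tail": summ.p_one_tail,
                             "significant": summ.significant})
                hists[(str(exp), model, spec.name)] = scores
        print(f"{model}: done")

    table = pd.DataFrame(rows)
    table.to_csv(args.out / "contrasts.csv", index=False)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

    # histogram panels of batch effect sizes (diagnostic contrasts only)
    diag = {"1": ["repeat_switch", "goal"], "2": ["c1_c2", "c3_c4"],
            "3": ["c1_c4", "c2_c3"]}
    fig, axes = plt.subplots(len(args.models), 3, figsize=(11, 2.2 * len(args.models)),
                             squeeze=False)
    for i, model in enumerate(args.models):
        for j, exp in enumerate(("1", "2", "3")):
            ax = axes[i][j]
            for name in diag[exp]:
                ax.hist(hists[(exp, model, name)], bins=25, alpha=0.6,
                        label=name)
            ax.axvline(0, color="k", lw=0.8)
            if i == 0:
                ax.set_title(f"experiment {exp}")
            if j == 0:
                ax.set_ylabel(model)
            ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(args.out / "contrast_histograms.png", dpi=120)
    print(f"wrote {args.out / 'contrasts.csv'} and contrast_histograms.png")


if __name__ == "__main__":
    main()
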