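"""Model-behavior similarity across experiments (angle cosine).

For each experiment, the two diagnostic contrasts form a vector of model
predictions (per agent, from fresh simulations) and a vector of behavioral
regression coefficients. The cosine of the angle between them measures how
closely each fixed generalization strategy matches behavior; the published
subject-level point estimates are used as the behavioral vectors (the raw
choice data are not distributed).

Expected pattern: the joint agent is most similar to behavior where the
mapping-goal relationship is strongest (experiment 1, NMI = 1) and the
independent agent where it is weakest, with both positive in the ambiguous
design (experiment 3).

Usage: python analysis/06_similarity.py [--n-sims 200] [--seed 17]
"""

import argparse
from pathlib import Path

import pandas as pd

from gridgen import analysis, taskenv

#: Published human regression point estimates for the diagnostic contrasts.
HUMAN_COEFFICIENTS = {
    "1": {"repeat_switch": 0.41, "goal": 0.005},
    "2": {"c1_c2": 0.140, "c3_c4": 0.0476},
    "3": {"c1_c4": 0.231, "c2_c3": 0.123},
}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-sims", type=int, default=200)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    import importlib.util
    import sys
    contrasts_path = Path(__file__).parent / "03_model_contrasts.py"
    spec = importlib.util.spec_from_file_location("model_contrasts",
                                                  contrasts_path)
    mc = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mc)

    from gridgen import simulation

    rows = []
    for model in ("independent", "joint"):
        vectors = {}
        e1 = mc.exp1_scores(model, args.n_sims, 100, args.seed)
        vectors["1"] = {"repeat_switch": e1["repeat_switch"][1].mean,
                        "goal": e1["goal"][1].mean}
        for exp in (2, 3):
            d = taskenv.build_design(exp)
            rec, batches = simulation.run_cohort(
                d, model, n_sims=args.n_sims, n_batches=100,
                batch_size=min(args.n_sims, simulation.HUMAN_N[str(exp)]),
                master_seed=args.seed + exp)
            vectors[str(exp)] = {
                s.name: analysis.contrast_scores(rec, batches, s)[1].mean
                for s in analysis.CONTRASTS[str(exp)][:2]}
        for exp, human in HUMAN_COEFFICIENTS.items():
            names = list(human)
            cos = analysis.angle_cosine([vectors[exp][n] for n in names],
                                        [human[n] for n in names])
            rows.append({"experiment": exp, "model": model,
                         "angle_cosine": round(cos, 3)})
            print(f"exp {exp} {model:12s} angle cosine {cos:+.3f}")

    table = pd.DataFrame(rows)
    table.to_csv(args.out / "similarity.csv", index=False)
    print(f"wrote {args.out / 'similarity.csv'}")


if __name__ == "__main__":
    main()
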