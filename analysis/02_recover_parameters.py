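"""Parameter/trajectory recovery on noiseless dense-grid data.

For each formalism, samples a ground truth, simulates the wild type on a
21-point grid, and asks PSO (40 particles x 500 iterations) to re-estimate
the parameters from that noiseless data.  Reports the final objective and
how closely the fitted model's trajectories track the truth's.

What we find at this desk scale: trajectories are recovered to a few
percent for both formalisms, while the objective plateaus around 1e-1 —
the kr/dk (synthesis/decay) trade-off valleys are long, and a swarm cannot
walk them to the bottom within this budget (a pattern search started in the
box does better; see the methods note).

Writes results/recovery.tsv.
"""

from pathlib import Path

import pandas as pd

from floranet.experiments import recovery_experiment

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for formalism in ("mass_action", "s_system"):
        rec = recovery_experiment(formalism, seed=SEED)
        rows.append({
            "formalism": formalism,
            "final_objective": rec.objective,
            "trajectory_mre_pct": 100 * rec.trajectory_mre,
            "evaluations": rec.fit.evaluations,
            "stop": rec.fit.criterion,
        })
        print(f"{formalism}: O(p) = {rec.objective:.3e}, "
              f"trajectory MRE = {100 * rec.trajectory_mre:.2f}% "
              f"({rec.fit.evaluations} evaluations)")
    pd.DataFrame(rows).to_csv(OUT / "recovery.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
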