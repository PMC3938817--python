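"""Generate the synthetic study panels.

Emulates the microarray design — four genotypes (col, ler, co, ft), four
harvest days (0, 3, 5, 7), eight measured transcripts, 10% multiplicative
noise — from one sampled S-system ground truth, plus the noiseless 21-point
dense panel used by the recovery experiments.

Writes results/panels/*.tsv with truth sidecars.
"""

from pathlib import Path

from floranet import SyntheticConfig, generate_panel, sample_truth_parameters
from floranet.io import write_parameters, write_timecourses
from floranet.synthetic import dense_times

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "panels"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for formalism in ("s_system", "mass_action"):
        truth = sample_truth_parameters(formalism, SEED)
        design = SyntheticConfig(formalism=formalism, noise_cv=0.1, seed=SEED)
        write_timecourses(OUT / f"{formalism}_design.tsv", generate_panel(design, truth))
        dense = SyntheticConfig(formalism=formalism, genotypes=("col",),
                                timepoints=dense_times(), noise_cv=0.0, seed=SEED)
        write_timecourses(OUT / f"{formalism}_dense.tsv", generate_panel(dense, truth))
        write_parameters(OUT / f"{formalism}_truth.json", truth, seed=SEED, role="truth")
        print(f"{formalism}: design panel (4 genotypes x 4 days, cv=0.1) "
              f"and noiseless dense col panel written")


if __name__ == "__main__":
    main()
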