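# floranet

Kinetic model comparison for the photoperiod flowering-time gene regulatory
network of *Arabidopsis thaliana*.

When day length triggers the floral transition, a small all-activation
cascade relays the signal: PHYB → **CO** → **FT**; FT binds the bZIP factor
FD and the **FT/FD** complex switches on **SOC1** and **AP1**; SOC1 and
**AGL24** reinforce each other in the pathway's only feedback loop and
up-regulate **LFY**. How should the transcription kinetics of such a network
be written down? This package implements and compares three answers on one
shared topology:

* **S-system** power laws, `dXᵢ/dt = αᵢ∏Xⱼ^gᵢⱼ − βᵢ∏Xⱼ^hᵢⱼ` (31 parameters),
  whose fractional kinetic orders absorb the 1-D/3-D facilitated-diffusion
  kinetics of transcription-factor target search;
* **Michaelis–Menten** saturation, `Vmax·[TF]/(Km+[TF])` per binding event
  with linear decay (23 parameters);
* **mass action**, `kr·[TF]` with linear decay (15 parameters).

It is aimed at systems biologists who want a small, fully reproducible
test-bed for rate-law selection: simulate, perturb (co/ft knockouts), fit
with three derivative-free optimizers (particle swarm, evolutionary
programming, Hooke–Jeeves pattern search), rank by weighted least squares
`O(p) = Σᵢⱼ ωᵢ(Xᵢⱼ−Yᵢⱼ(p))²` (ωᵢ = 1/mean(Xᵢ)²), mean relative error
`MRE = mean |x−y|/x`, and `AIC = N·ln(RSS/N) + 2k`, and interrogate fitted
models with local (`Sᵢⱼ(t) = ∂lnXⱼ/∂lnpᵢ`) and global (MPSA,
Kolmogorov–Smirnov scored) sensitivity analysis. A synthetic-data generator
stands in for the original microarray time courses, emulating their design:
four genotypes (col, ler, co, ft), harvests 0/3/5/7 days after the
photoperiod shift, eight measured transcripts, multiplicative log-normal
noise.

## Worked example

```bash
floranet synth --formalism s_system --seed 1 --noise-cv 0 --genotypes col --out panel.tsv
floranet compare --data panel.tsv --seed 1 --particles 40 --iterations 200 --out report.tsv
```

or equivalently in Python:

```python
from floranet.experiments import comparison_experiment
from floranet.io import format_report

print(format_report(comparison_experiment(seed=1).report))
```

which prints (4-point wild-type panel generated from an S-system truth at
5% noise, all three families fitted with equal PSO budgets):

```
       formalism dataset  objective    rss  mre_mean  mre_sd  mre_overall  k  n_points       aic
        s_system     col     0.1332 0.9133    0.0701  0.0273       0.0701 31        32  -51.8052
michaelis_menten     col     0.0692 0.1768    0.0760  0.0681       0.0760 23        32 -120.3450
     mass_action     col     0.1312 0.1904    0.1205  0.0825       0.1205 15        32 -133.9806
ranking by mre (best first): s_system < michaelis_menten < mass_action
ranking by aic (best first): mass_action < michaelis_menten < s_system
```

Read: the well-specified S-system tracks its own noisy data best in
relative error (7.0% overall MRE vs 7.6% and 12.1%), but its 31 parameters
cost it the Akaike comparison — the 15-parameter mass-action model has the
lowest AIC once residuals are comparable. That tension (best fit vs
overfitting risk) is the heart of the rate-law selection question.

The numbered scripts under `analysis/` run the full study — panel
generation, noiseless parameter/trajectory recovery, the three-way
comparison, and the sensitivity analyses — writing tables under `results/`.

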