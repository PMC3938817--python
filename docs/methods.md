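# Methods

## The model

The photoperiod branch of the *Arabidopsis* floral-transition network is
modeled with nine species: seven dependent transcripts/complexes —
CO (X1), FT (X2), the FT/FD complex (X3), SOC1 (X4), AP1 (X5), AGL24 (X6),
LFY (X7) — and two constant inputs, FD (X8) and PHYB (X9). Wiring:
PHYB → CO → FT; FT + FD → FT/FD complex; the complex activates SOC1 and AP1;
SOC1 ⇄ AGL24 is the pathway's only (positive) feedback loop; AGL24 → LFY.
Every interaction is an activation. The complex, which is not directly
measurable, is closed at its formation equilibrium `[FT/FD] = k·[FT]·[FD]`
when an initial value is needed (k = 1 by default, configurable).

Each dependent species obeys `dX/dt = synthesis − decay` in one of three
rate-law families sharing the topology:

| family | synthesis | decay | free parameters |
|---|---|---|---|
| S-system | `α_i ∏_j X_j^g_ij` | `β_i ∏_j X_j^h_ij` | 31 |
| Michaelis–Menten | `∏_factors Vm·S/(Km+S)` | `dk_i·X_i` | 23 |
| mass action | `∏_factors kr·[TF]` | `dk_i·X_i` | 15 |

The S-system's real-valued kinetic orders absorb the 1-D/3-D facilitated
diffusion of transcription-factor target search; the other two laws assume a
homogeneous medium. Two printed idiosyncrasies are kept deliberately: FT's
S-system decay carries FD (`β₂·X2^h22·X8^h28`), and the mass-action SOC1
synthesis is the product of two first-order terms (`kr4a·X3·kr4b·X6`), making
it bilinear; only the product `kr4a·kr4b` is identifiable, which is harmless
for trajectory-level claims.

Parameter boxes: kinetic orders in [0, 2]; all rate-type constants in
[1e-6, 1e2] for the optimizers. States are clamped at a positivity floor of
1e-12 before exponentiation (fractional powers are undefined at 0, and
knockouts start there). Time is abstract "model time": the synthetic design
uses days, the sensitivity horizon is 100 units; no unit conversion is
implied.

## Simulation

LSODA (via `scipy.integrate.odeint`) on the seven dependent states, with the
two inputs held constant exactly. Defaults: rtol 1e-8, atol 1e-10 for
reporting runs; rtol 1e-6, atol 1e-9 inside optimization objectives (the
optimizer only needs a few digits); one order tighter than the reporting
default for sensitivity runs, which difference nearby trajectories. Reported
dependent trajectories are clamped at ≥ 0; solver failure or excursion
beyond 1e9 raises a `SimulationError` carrying the offending parameters, and
inside an objective it becomes a finite penalty of 1e10 (NaN would poison
swarm bests).

Knockouts (the *co* and *ft* genotypes) pin the gene's synthesis constant(s)
to exactly 0 and force its initial concentration to 0; bounds are relaxed
for that entry so the vector remains formally in-box.

## Synthetic data

The generator emulates the study design: harvests at days {0, 3, 5, 7}
after the photoperiod shift; genotypes col (wild type), ler (second
accession: all rate constants jittered once per panel by ±20% uniform),
co and ft (knockouts); eight observed species (X1..X8; the complex can be
switched latent); multiplicative log-normal measurement noise,
mean-unbiased, with CV 0.1 by default — the classical microarray error
model, keeping values positive. All randomness derives from one seed
through per-(genotype, replicate) `SeedSequence` keys, so panels are
bit-reproducible and every observation gets an independent factor.

Ground-truth parameters are sampled uniformly: kinetic orders over their
full [0, 2] range, rate constants over a physiological sub-box [0.05, 2.0]
(uniform draws over the full optimizer box blow up almost surely, which
would make rejection sampling vacuous). A draw is accepted only if the
wild-type simulation on the dense grid succeeds, stays below 50
concentration units, and ends with every dependent species above 0.01
(no blow-up, no collapse). A 21-point dense grid over [0, 7] is provided
alongside the 4-point design because four time points cannot identify
31 parameters.

What the generator does *not* emulate: probe-level microarray artifacts
(background, normalization), biological replicate variability distinct from
measurement noise, and any mismatch between the fitted family and the data's
true kinetics beyond what the cross-family comparison itself introduces.
Passing tests therefore demonstrate internal consistency of the pipeline
under its own assumptions, not fidelity to the original microarrays.

## Fitting

Objective: `O(p) = Σ_i Σ_j ω_i (X_ij − Y_ij(p))²` with per-gene weights
`ω_i = 1 / mean_t(X_ij)²`, making each gene's contribution scale-free.
Genes observed at the positivity floor throughout (a knocked-out
transcript) get zero weight. The simulation `Y(p)` starts from the data's
first time point; each genotype is fitted separately by default, and a
summed multi-genotype mode exists.

Optimizers (all box-bounded, all returning a monotone best-so-far trace):

* **PSO** — global-best swarm, 40 particles × 500 iterations, inertia 0.7,
  cognitive = social = 1.5, velocity clamp 0.5 box widths. Two published
  refinements are built in, because the textbook swarm measurably collapses
  onto a non-optimal point and stalls (on these objectives at ~1e-1, and
  even on a 15-D sphere at 8e-2): best-position updates are asynchronous
  within a sweep, and the current best particle follows the
  guaranteed-convergence (GCPSO) update — an adaptive-radius random search
  around the global best (radius doubled after 15 consecutive successes,
  halved after 5 failures).
* **EP** — self-adaptive evolutionary programming: population 50, Gaussian
  mutation with per-coordinate log-normal step-size adaptation
  (τ = 1/√(2√d), τ′ = 1/√(2d)), reflection at the box, (μ+μ) survival by
  q = 10 round-robin tournament.
* **Hooke–Jeeves** — deterministic pattern search: exploratory moves over
  each coordinate, pattern (extrapolation) moves while they help, step
  contraction by 0.5, convergence when the step falls below 1e-6 of the box
  width. Default start is the box center.

A finding worth stating plainly: on these smooth, near-separable synthetic
objectives, Hooke–Jeeves is the strongest of the three at every matched
evaluation budget we measured (e.g. 2000 evaluations on the S-system
recovery instance: HJ median 0.29 vs PSO median 3.9 over five
seeds/starts). The swarm's weakness is structural — the weighted objective
has long, narrow synthesis-vs-decay (kr_i vs dk_i) trade-off valleys over
the short observation window, which pattern moves traverse and swarm
dynamics do not. Recovery experiments consequently achieve trajectory-level
agreement (a few percent MRE) but not near-zero objectives at the 20k-
evaluation budget. This contrasts with the original study's real-data
experience, where PSO was reported the most suitable; both statements can
be true, as the landscapes differ.

## Ranking

* **MRE** — per gene, the time-mean of |x − y|/x; summarized as mean ± SD
  across genes (population SD, so a single gene is well-defined) and as one
  pooled mean over all gene-time pairs. Points with the observation at the
  positivity floor are excluded and counted.
* **AIC** — Gaussian least-squares reduction `N·ln(RSS/N) + 2k` with
  *unweighted* RSS over the points entering the fit; `RSS = 0` returns −∞
  with a warning (a perfect fit flags overfitting rather than erroring).
  With equal residuals the AIC ordering is the parameter-count ordering:
  mass action (15) < Michaelis–Menten (23) < S-system (31).
* Reports carry one row per (formalism, dataset); rankings average each
  formalism over its datasets and break ties toward fewer parameters.

## Sensitivity

* **Local** — normalized time-dependent sensitivity
  `S_ij(t) = (p_i/X_j)·∂X_j/∂p_i` by central differences with relative step
  0.01, default horizon 100 units on 201 points; the normalization floor
  prevents division blow-ups; a parameter at exactly 0 contributes an
  identically zero row; failed perturbed integrations flag the row rather
  than dropping it. In the all-activation network every synthesis-rate
  sensitivity is non-negative (asserted down to a finite-difference noise
  floor of 1e-3), and for stability-screened draws the response settles:
  the late-horizon slope of S is ≈ 0 while curves flatten to their
  steady-state values.
* **MPSA** — uniform Monte-Carlo sampling of the box, classification of
  each sample as acceptable/unacceptable at the median objective, and
  per-parameter Kolmogorov–Smirnov distance between the two marginal
  sample distributions. Sampling law, threshold and scoring are the
  standard recipe and all three are configurable; a degenerate split
  re-thresholds at the mean with a warning.

## Problem sizes and numerical checks

The reference experiments run at desk scale: recovery uses the noiseless
21-point wild-type grid with the full PSO budget (40×500); the three-way
comparison uses the 4-point design at 5% noise on the wild-type dataset
with equal 40×200 budgets; MPSA uses 1000 samples. The closed-form
sensitivity check (`S(X, dk)(t) = −dk·t` for pure decay) uses horizon 1.0
and rel_step 0.01 so the O(step²) discretization term (≈ p·t³·δ²/6) stays
an order below its 1e-4 tolerance.

## Known limitations

* Four design time points cannot identify any of the three models;
  parameter-level claims require the dense grid, and even there only
  trajectory-level recovery is claimed for the S-system (kinetic orders
  trade off against rate constants).
* The AIC reduction assumes i.i.d. Gaussian residuals on the raw scale;
  under multiplicative noise this is an approximation.
* Whether MRE dispersion should be taken across genes or across optimizer
  runs is ambiguous in general; across genes is implemented.
* No SBML import/export, no stochastic simulation, no delay/spatial terms.
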