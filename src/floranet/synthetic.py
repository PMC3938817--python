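"""Synthetic expression panels emulating the flowering-time microarray design.

The real study design: apical tissue harvested 0, 3, 5 and 7 days after a
short-day to long-day photoperiod shift, in four genotypes — the Columbia
(col) and Landsberg erecta (ler) wild-type accessions plus the co and ft
null mutants — with eight measurable transcripts.  This module generates
ground-truth parameter sets and noisy panels of exactly that shape, so that
fitting, ranking and sensitivity analysis are all testable without the
original microarrays.

Conventions:

* col is the wild-type simulation of the sampled truth parameters.
* ler stands in for a second accession: the same topology with every rate
  constant jittered by a fixed multiplicative factor (default +/-20%).
* co / ft are knockouts of CO / FT (synthesis pinned to 0, start at 0).
* Measurement noise is multiplicative log-normal with a configured
  coefficient of variation, mean-unbiased, seeded; microarray error is
  classically multiplicative and this keeps values positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import (
    Formalism,
    NetworkTopology,
    ParameterVector,
    build_flowering_topology,
    instantiate_model,
)
from .simulate import (
    SimulationError,
    TimeCourse,
    apply_knockout,
    integrate,
    knockout_initial_state,
)

#: Truth parameters are drawn from this physiological sub-box of the optimizer
#: box: rate-type constants uniform on [0.05, 2.0] (kinetic orders keep their
#: full [0, 2] range).  Uniform draws over the full optimizer box (up to 1e2)
#: blow up almost surely and would make rejection sampling vacuous.
TRUTH_RATE_BOX = (0.05, 2.0)

#: Genotypes of the emulated design.
GENOTYPES = ("col", "ler", "co", "ft")

_KNOCKOUT_GENE = {"co": "CO", "ft": "FT"}

#: The eight measurable species (the complex is observed by default and can
#: be switched latent).
OBSERVED_SPECIES = ("CO", "FT", "FTFD_complex", "SOC1", "AP1", "AGL24", "LFY", "FD")


def dense_times(n: int = 21, t_end: float = 7.0) -> np.ndarray:
    """Fine time grid for recovery experiments (default 21 points on [0, 7])."""
    return np.linspace(0.0, t_end, n)


@dataclass
class SyntheticConfig:
    """Study-design knobs for panel generation."""

    formalism: Formalism | str = Formalism.S_SYSTEM
    timepoints: Sequence[float] = (0.0, 3.0, 5.0, 7.0)
    genotypes: Sequence[str] = GENOTYPES
    noise_cv: float = 0.1
    replicate_count: int = 1
    seed: int = 0
    dense_grid: Sequence[float] | None = None
    observe_complex: bool = True
    ler_jitter: float = 0.2
    fd_level: float = 1.0
    phyb_level: float = 1.0
    complex_rate: float = 1.0  # k in the steady-state closure [FT/FD] = k*[FT]*[FD]

    def __post_init__(self) -> None:
        self.formalism = Formalism.coerce(self.formalism)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        unknown = set(self.genotypes) - set(GENOTYPES)
        if unknown:
            raise ValueError(f"unknown genotype label(s) {sorted(unknown)}; valid: {GENOTYPES}")

    @property
    def observed_labels(self) -> tuple[str, ...]:
        if self.observe_complex:
            return OBSERVED_SPECIES
        return tuple(l for l in OBSERVED_SPECIES if l != "FTFD_complex")


def default_initial_state(config: SyntheticConfig | None = None) -> np.ndarray:
    """Wild-type starting point: unit transcript levels, inputs at their
    configured constants, complex at its steady-state closure k*[FT]*[FD]."""
    cfg = config or SyntheticConfig()
    x0 = np.ones(9)
    x0[7] = cfg.fd_level
    x0[8] = cfg.phyb_level
    x0[2] = cfg.complex_rate * x0[1] * x0[7]
    return x0


def sample_truth_parameters(
    formalism: Formalism | str,
    seed: int,
    topology: NetworkTopology | None = None,
    *,
    max_tries: int = 200,
    config: SyntheticConfig | None = None,
) -> ParameterVector:
    """Draw a ground-truth parameter vector that yields sane wild-type dynamics.

    Rate constants are uniform on :data:`TRUTH_RATE_BOX`, kinetic orders
    uniform on [0, 2].  A draw is rejected unless the wild-type simulation on
    the dense default grid (i) integrates successfully, (ii) stays below 50
    concentration units (no blow-up), and (iii) ends with every dependent
    species above 0.01 (no collapse to zero).  Reproducible under ``seed``.
    """
    formalism = Formalism.coerce(formalism)
    top = topology or build_flowering_topology()
    model = instantiate_model(top, formalism)
    template = model.parameter_template
    cfg = config or SyntheticConfig(formalism=formalism)
    x0 = default_initial_state(cfg)
    grid = dense_times()
    rlo, rhi = TRUTH_RATE_BOX
    is_order = np.array([n[0] in "gh" and n[1].isdigit() for n in template.names])
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(11,)))
    dep0 = list(model.dependent_positions)
    for _ in range(max_tries):
        vals = rng.uniform(rlo, rhi, size=len(template))
        vals[is_order] = rng.uniform(0.0, 2.0, size=int(is_order.sum()))
        candidate = template.with_values(vals)
        try:
            tc = integrate(model, candidate, x0, grid, rtol=1e-7, atol=1e-9)
        except SimulationError:
            continue
        dep = tc.values[:, dep0]
        if dep.max() > 50.0:
            continue
        if dep[-1].min() < 0.01:
            continue
        return candidate
    raise RuntimeError(
        f"exhausted {max_tries} truth draws for {formalism.value} "
        f"(rate box {TRUTH_RATE_BOX}, orders {(0.0, 2.0)})"
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-unbiased multiplicative log-normal noise with the given CV."""
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size=shape) - sigma**2 / 2.0)


def generate_panel(
    config: SyntheticConfig, truth: ParameterVector
) -> list[TimeCourse]:
    """One noisy TimeCourse per genotype x replicate, emulating the design.

    Bit-reproducible under ``(config.seed, config, truth)``; ``noise_cv = 0``
    returns the deterministic simulations exactly.
    """
    if truth.formalism is not config.formalism:
        raise ValueError(
            f"truth parameters are {truth.formalism.value}, config expects "
            f"{config.formalism.value}"
        )
    top = build_flowering_topology()
    model = instantiate_model(top, config.formalism)
    times = config.dense_grid if config.dense_grid is not None else config.timepoints
    times = np.asarray(times, dtype=float)
    x0_wt = default_initial_state(config)
    obs = config.observed_labels
    obs_cols = [top.labels.index(l) for l in obs]

    ss = np.random.SeedSequence(entropy=int(config.seed))
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    noise_root = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(1,))

    panel: list[TimeCourse] = []
    for gi, genotype in enumerate(config.genotypes):
        params, x0 = truth, x0_wt
        if genotype == "ler":
            # fixed ecotype: jitter is drawn once per panel, shared by replicates
            jit = jitter_rng.uniform(1 - config.ler_jitter, 1 + config.ler_jitter,
                                     size=len(truth))
            is_order = np.array([n[0] in "gh" and n[1].isdigit() for n in truth.names])
            jit[is_order] = 1.0
            params = truth.with_values(np.clip(truth.values * jit, truth.lower, truth.upper))
        elif genotype in _KNOCKOUT_GENE:
            _, params, mask = apply_knockout(model, truth, _KNOCKOUT_GENE[genotype])
            x0 = knockout_initial_state(x0_wt, mask)
        clean = integrate(model, params, x0, times, genotype=genotype)
        clean_obs = clean.values[:, obs_cols]
        for rep in range(1, config.replicate_count + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(config.seed), spawn_key=(1, gi, rep))
            )
            if config.noise_cv > 0:
                vals = clean_obs * _lognormal_factors(rng, config.noise_cv, clean_obs.shape)
            else:
                vals = clean_obs.copy()
            panel.append(
                TimeCourse(
                    times, obs, vals, genotype,
                    meta={
                        "replicate": rep,
                        "seed": int(config.seed),
                        "noise_cv": float(config.noise_cv),
                        "source": f"synthetic:{config.formalism.value}",
                        "fd_level": float(config.fd_level),
                        "phyb_level": float(config.phyb_level),
                    },
                )
            )
    return panel
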