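"""Parameter sensitivity analysis.

Two complementary views of a fitted model:

* **Local, time-dependent:** the normalized (logarithmic) sensitivity
  ``S_ij(t) = d ln X_j(t) / d ln p_i = (p_i / X_j(t)) * dX_j(t)/dp_i``,
  computed by central finite differences with a relative parameter step.
  In an all-activation network every synthesis-rate sensitivity is
  non-negative, and for stable parameter sets the curves decay toward zero
  — perturbation responses are transient.
* **Global (MPSA):** Monte-Carlo multi-parametric sensitivity analysis.
  Parameters are sampled uniformly in their box, each sample is classified
  acceptable/unacceptable by its objective value against a reference data
  set (threshold: the median objective), and each parameter is scored by
  the Kolmogorov–Smirnov distance between the acceptable and unacceptable
  marginal distributions of that parameter.  Parameters the fit does not
  constrain score near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .models import POSITIVITY_FLOOR, KineticModel, ParameterVector
from .simulate import SimulationError, TimeCourse, integrate
from .estimate import Objective


@dataclass
class SensitivityResult:
    """Normalized sensitivities S[parameter, species, time]."""

    times: np.ndarray
    parameter_names: tuple[str, ...]
    species_labels: tuple[str, ...]
    matrix: np.ndarray  # shape (n_params, n_species, n_times)
    method: str
    perturbation: float | str
    seed: int | None = None
    failed: list[str] = field(default_factory=list)

    def for_parameter(self, name: str) -> np.ndarray:
        return self.matrix[self.parameter_names.index(name)]

    def for_pair(self, parameter: str, species: str) -> np.ndarray:
        return self.matrix[
            self.parameter_names.index(parameter),
            self.species_labels.index(species),
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long format (parameter, species, time, value) for heat-map plotting."""
        p, s, t = self.matrix.shape
        idx = pd.MultiIndex.from_product(
            [self.parameter_names, self.species_labels, self.times],
            names=["parameter", "species", "time"],
        )
        return pd.DataFrame(
            {"value": self.matrix.reshape(p * s * t)}, index=idx
        ).reset_index()


def local_sensitivity(
    model: KineticModel,
    params: ParameterVector,
    initial_state: Sequence[float],
    horizon: float = 100.0,
    rel_step: float = 0.01,
    *,
    n_grid: int = 201,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> SensitivityResult:
    """Central-finite-difference normalized sensitivities on [0, horizon].

    The integration tolerance is an order tighter than the reporting default
    because sensitivities difference two nearby trajectories.  A parameter
    at exactly 0 contributes an identically-zero row (the logarithmic
    sensitivity carries a factor p_i).  If integration fails at a perturbed
    point the parameter's row is flagged in ``failed`` and filled with NaN,
    never silently dropped.
    """
    times = np.linspace(0.0, float(horizon), int(n_grid))
    base = integrate(model, params, initial_state, times, rtol=rtol, atol=atol)
    x_base = np.maximum(base.values.T, POSITIVITY_FLOOR)  # (species, time)
    n_p = len(params)
    n_s = model.topology.n_species
    matrix = np.zeros((n_p, n_s, len(times)))
    failed: list[str] = []
    for i, name in enumerate(params.names):
        p_i = float(params.values[i])
        if p_i == 0.0:
            continue
        delta = rel_step * abs(p_i)
        try:
            up = params.with_values(params.values)  # copy
            up.values[i] = p_i + delta
            down = params.with_values(params.values)
            down.values[i] = p_i - delta
            tc_up = integrate(model, up, initial_state, times, rtol=rtol, atol=atol)
            tc_down = integrate(model, down, initial_state, times, rtol=rtol, atol=atol)
        except SimulationError:
            failed.append(name)
            matrix[i] = np.nan
            warnings.warn(f"sensitivity row for {name!r} failed to integrate")
            continue
        dxdp = (tc_up.values.T - tc_down.values.T) / (2.0 * delta)
        matrix[i] = p_i / x_base * dxdp
    return SensitivityResult(
        times,
        params.names,
        model.topology.labels,
        matrix,
        method="local_fd",
        perturbation=rel_step,
        failed=failed,
    )


@dataclass
class MPSAResult:
    parameter_names: tuple[str, ...]
    scores: np.ndarray
    threshold: float
    n_acceptable: int
    n_samples: int
    seed: int
    samples: np.ndarray | None = None
    objectives: np.ndarray | None = None

    def score(self, name: str) -> float:
        return float(self.scores[self.parameter_names.index(name)])


def mpsa_scores(
    func: Callable[[np.ndarray], float],
    lower: Sequence[float],
    upper: Sequence[float],
    n_samples: int,
    seed: int,
    *,
    names: Sequence[str] | None = None,
    keep_samples: bool = False,
) -> MPSAResult:
    """Kolmogorov–Smirnov importance scores for any box-bounded objective."""
    if n_samples < 100:
        raise ValueError("MPSA needs at least 100 samples")
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    d = lower.size
    rng = np.random.default_rng(int(seed))
    samples = lower + rng.random((int(n_samples), d)) * (upper - lower)
    objectives = np.array([func(s) for s in samples])
    threshold = float(np.median(objectives))
    acceptable = objectives <= threshold
    if acceptable.all() or not acceptable.any():
        warnings.warn(
            "degenerate objective split at the median; re-thresholding at the mean"
        )
        threshold = float(objectives.mean())
        acceptable = objectives <= threshold
        if acceptable.all() or not acceptable.any():  # constant objective
            scores = np.zeros(d)
            return MPSAResult(
                tuple(names or (f"p{i}" for i in range(d))), scores, threshold,
                int(acceptable.sum()), int(n_samples), int(seed),
                samples if keep_samples else None,
                objectives if keep_samples else None,
            )
    scores = np.array(
        [ks_2samp(samples[acceptable, i], samples[~acceptable, i]).statistic for i in range(d)]
    )
    return MPSAResult(
        tuple(names or (f"p{i}" for i in range(d))),
        scores,
        threshold,
        int(acceptable.sum()),
        int(n_samples),
        int(seed),
        samples if keep_samples else None,
        objectives if keep_samples else None,
    )


def mpsa(
    model: KineticModel,
    data: TimeCourse,
    bounds=None,
    n_samples: int = 1000,
    seed: int = 0,
    **objective_kwargs,
) -> MPSAResult:
    """MPSA of a model against a reference time course."""
    obj = Objective(model, data, **objective_kwargs)
    t = model.parameter_template
    lo, hi = (t.lower, t.upper) if bounds is None else bounds
    return mpsa_scores(obj, lo, hi, n_samples, seed, names=t.names)
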