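"""Forward integration of kinetic models and genotype perturbations.

Integration uses LSODA (stiff/non-stiff switching): S-system power laws with
large kinetic orders can be stiff, so an implicit-capable method is the
default.  Only the dependent species are integrated; independent inputs (FD,
PHYB) are held at their initial values, which keeps them frozen to machine
precision rather than merely to solver tolerance.

Reported trajectories of dependent species are clamped at zero from below:
the right-hand sides are defined via a positivity floor, and tiny solver
undershoots below zero are truncation artifacts, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .models import (
    DEPENDENT,
    KineticModel,
    ParameterVector,
    _suffix,
)

#: Default solver tolerances (relative, absolute) for user-facing integration.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: A trajectory exceeding this magnitude is treated as numerical blow-up.
BLOWUP_CAP = 1e9


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the offending parameters."""

    def __init__(self, message: str, params: Sequence[float] | None = None):
        super().__init__(message)
        self.params = None if params is None else np.asarray(params, dtype=float)


@dataclass
class TimeCourse:
    """A genotype-labeled matrix of concentrations over increasing times."""

    times: np.ndarray
    species_labels: tuple[str, ...]
    values: np.ndarray
    genotype: str = "col"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.species_labels = tuple(self.species_labels)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        if self.values.shape != (len(self.times), len(self.species_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.times)} times x {len(self.species_labels)} species"
            )
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def n_times(self) -> int:
        return len(self.times)

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.species_labels.index(label)
        except ValueError:
            raise KeyError(f"no species {label!r} in time course") from None
        return self.values[:, j]

    def subset(self, labels: Sequence[str]) -> "TimeCourse":
        cols = [self.species_labels.index(l) for l in labels]
        return TimeCourse(
            self.times, tuple(labels), self.values[:, cols], self.genotype, dict(self.meta)
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: columns time, gene, value, replicate, genotype."""
        rep = int(self.meta.get("replicate", 1))
        records = [
            (t, g, self.values[i, j], rep, self.genotype)
            for i, t in enumerate(self.times)
            for j, g in enumerate(self.species_labels)
        ]
        return pd.DataFrame(records, columns=["time", "gene", "value", "replicate", "genotype"])


def integrate(
    model: KineticModel,
    params: ParameterVector | Sequence[float],
    initial_state: Sequence[float],
    times: Sequence[float],
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    genotype: str = "col",
    mxstep: int = 10_000,
) -> TimeCourse:
    """Integrate the model from ``initial_state`` and report at ``times``.

    ``times`` must be strictly increasing with ``times[0]`` the initial time.
    Solver failure, non-finite output, or blow-up beyond ``BLOWUP_CAP`` raises
    :class:`SimulationError` with the parameter vector attached — never a
    silent NaN.
    """
    n = model.topology.n_species
    x0 = np.asarray(initial_state, dtype=float)
    if x0.shape != (n,):
        raise ValueError(f"initial_state must have length {n}")
    if np.any(x0 < 0):
        raise ValueError("initial_state must be non-negative")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing with at least 2 points")
    if isinstance(params, ParameterVector):
        if params.formalism is not model.formalism:
            raise ValueError("parameter vector formalism does not match model")
        pvals = params.values.tolist()
    else:
        pvals = list(map(float, params))

    dep0 = model.dependent_positions
    xbuf = x0.tolist()
    rhs = model.rhs_dependent

    def f(y, _t):
        for k, d in enumerate(dep0):
            xbuf[d] = y[k]
        return rhs(xbuf, pvals)

    y0 = x0[list(dep0)]
    import warnings

    with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # failure surfaces as SimulationError below
        y, info = odeint(
            f, y0, t, rtol=rtol, atol=atol, mxstep=mxstep, full_output=True
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
        raise SimulationError(
            f"ODE integration failed ({info['message']})", pvals
        )
    if np.max(np.abs(y)) > BLOWUP_CAP:
        raise SimulationError("trajectory blew up beyond the magnitude cap", pvals)

    values = np.tile(x0, (len(t), 1))
    values[:, list(dep0)] = np.maximum(y, 0.0)
    return TimeCourse(
        t, model.topology.labels, values, genotype,
        meta={"rtol": rtol, "atol": atol, "formalism": model.formalism.value},
    )


def _synthesis_rate_names(model: KineticModel, species_index: int) -> list[str]:
    d = species_index
    facs = model.topology.production[d]
    if model.formalism.value == "s_system":
        return [f"alpha{d}"]
    prefix = "Vm" if model.formalism.value == "michaelis_menten" else "kr"
    return [f"{prefix}{_suffix(d, len(facs), fi)}" for fi in range(len(facs))]


def apply_knockout(
    model: KineticModel,
    params: ParameterVector,
    gene: str,
) -> tuple[KineticModel, ParameterVector, np.ndarray]:
    """Null-mutant variant of a model: zero synthesis, zero starting level.

    Returns ``(model, params*, mask)`` where ``params*`` has the gene's
    synthesis rate constant(s) pinned to 0 (bounds relaxed accordingly) and
    ``mask`` is a boolean vector over species marking initial concentrations
    that must be forced to 0.  Independent species cannot be knocked out —
    set their constant level instead.
    """
    top = model.topology
    d = top.index_of(gene) if isinstance(gene, str) else int(gene)
    sp = top.species_by_index(d)
    if sp.role != DEPENDENT:
        raise ValueError(
            f"{sp.name} is an independent input; set its constant level instead of knocking it out"
        )
    ko = params.copy()
    for name in _synthesis_rate_names(model, d):
        ko.set(name, 0.0, relax_bounds=True)
    mask = np.zeros(top.n_species, dtype=bool)
    mask[d - 1] = True
    return model, ko, mask


def knockout_initial_state(
    initial_state: Sequence[float], mask: np.ndarray
) -> np.ndarray:
    """Apply a knockout mask to an initial state (returns a copy)."""
    x0 = np.asarray(initial_state, dtype=float).copy()
    x0[np.asarray(mask, dtype=bool)] = 0.0
    return x0
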