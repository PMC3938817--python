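"""Kinetic formalisms for the photoperiod flowering-time network of *Arabidopsis*.

The network couples nine species: the photoreceptor PHYB drives expression of
the zinc-finger transcription factor CO, CO activates the florigen FT, FT binds
the bZIP factor FD to form the FT/FD complex, the complex activates SOC1 and
AP1, SOC1 and AGL24 form the pathway's only feedback loop (a positive one), and
AGL24 up-regulates the meristem-identity gene LFY.  FD and PHYB are treated as
*independent* inputs: their levels are constant over the modeled time window
and carry no differential equation.

Each dependent species obeys ``dX/dt = synthesis(regulators) - decay(X)``
under one of three interchangeable rate-law families:

``s_system``
    Power-law (S-system) kinetics: synthesis and decay are products of
    regulator concentrations raised to real-valued *kinetic orders*
    (``alpha_i * prod X_j**g_ij - beta_i * prod X_j**h_ij``).  Fractional
    orders absorb the 1-D/3-D diffusion limitation of transcription-factor
    target search, which the saturating and linear laws ignore.
``michaelis_menten``
    Saturating synthesis ``Vm*S/(Km+S)`` per binding event with linear decay.
``mass_action``
    Bilinear/linear synthesis ``kr*[TF]`` with linear decay.

All three share one topology object and one flattened, bounded, named
parameter-vector contract so that the same optimizer and the same objective
can drive any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

#: States are clamped to this floor before exponentiation: power laws with
#: fractional exponents are undefined at exactly zero (knockouts start there).
POSITIVITY_FLOOR = 1e-12

#: Default optimizer box for every rate-type constant (alpha, beta, Vm, Km, kr, dk).
RATE_BOUNDS = (1e-6, 1e2)

#: Kinetic-order box for the S-system exponents g_ij, h_ij.
KINETIC_ORDER_BOUNDS = (0.0, 2.0)

DEPENDENT = "dependent"
INDEPENDENT = "independent"


class Formalism(str, Enum):
    """The three rate-law families under comparison."""

    S_SYSTEM = "s_system"
    MICHAELIS_MENTEN = "michaelis_menten"
    MASS_ACTION = "mass_action"

    @classmethod
    def coerce(cls, value: "Formalism | str") -> "Formalism":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown formalism {value!r}; valid options: {valid}"
            ) from None


@dataclass(frozen=True)
class Species:
    """One node of the network.

    ``index`` is the conventional 1-based subscript (X1..X9); ``role`` is
    either ``"dependent"`` (has an ODE) or ``"independent"`` (constant input).
    """

    index: int
    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in (DEPENDENT, INDEPENDENT):
            raise ValueError(f"role must be dependent/independent, got {self.role!r}")


@dataclass(frozen=True)
class NetworkTopology:
    """Signed wiring of the network, independent of any rate law.

    ``production`` maps each dependent species index to a tuple of *factors*;
    each factor is a tuple of regulator indices whose concentrations multiply
    into a single synthesis substrate.  A species with two factors (SOC1,
    which integrates the FT/FD complex and AGL24) gets one saturating term or
    one rate constant *per factor*; a factor with two members (the FT/FD
    complex formation from FT and FD) is a joint substrate.

    ``degradation`` maps each dependent species to the indices appearing in
    its decay term (always the species itself first; FT additionally carries
    FD in its S-system decay exponent, as the model is written).
    """

    species: tuple[Species, ...]
    production: Mapping[int, tuple[tuple[int, ...], ...]]
    degradation: Mapping[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        idx = {s.index for s in self.species}
        if idx != set(range(1, len(self.species) + 1)):
            raise ValueError("species indices must be 1..n without gaps")
        for d in self.dependent_indices:
            if d not in self.production:
                raise ValueError(f"dependent species X{d} has no production term")
            if d not in self.degradation:
                raise ValueError(f"dependent species X{d} has no degradation term")
            if self.degradation[d][0] != d:
                raise ValueError(f"X{d} degradation must be led by self-decay")
        for d, facs in self.production.items():
            for fac in facs:
                if not fac or not set(fac) <= idx:
                    raise ValueError(f"bad production factor {fac} for X{d}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def dependent_indices(self) -> tuple[int, ...]:
        return tuple(s.index for s in self.species if s.role == DEPENDENT)

    @property
    def independent_indices(self) -> tuple[int, ...]:
        return tuple(s.index for s in self.species if s.role == INDEPENDENT)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def index_of(self, name: str) -> int:
        for s in self.species:
            if s.name == name:
                return s.index
        raise KeyError(f"no species named {name!r}")

    def species_by_index(self, index: int) -> Species:
        return self.species[index - 1]


@dataclass
class ParameterVector:
    """A named, bounded, flattened parameter set for one formalism."""

    names: tuple[str, ...]
    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    formalism: Formalism

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float).copy()
        self.lower = np.asarray(self.lower, dtype=float).copy()
        self.upper = np.asarray(self.upper, dtype=float).copy()
        self.formalism = Formalism.coerce(self.formalism)
        n = len(self.names)
        if not (self.values.shape == self.lower.shape == self.upper.shape == (n,)):
            raise ValueError("names/values/lower/upper lengths disagree")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")
        self._index = {name: i for i, name in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"no parameter named {name!r}") from None

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.names, self.values, self.lower, self.upper, self.formalism)

    def with_values(self, values: Sequence[float]) -> "ParameterVector":
        out = self.copy()
        out.values = np.asarray(values, dtype=float).copy()
        if out.values.shape != (len(self.names),):
            raise ValueError("value vector has wrong length")
        return out

    def set(self, name: str, value: float, *, relax_bounds: bool = False) -> None:
        """Set one entry in place; ``relax_bounds`` widens the box to admit it
        (used by knockouts, which pin a synthesis constant to exactly 0)."""
        i = self.index(name)
        if relax_bounds:
            self.lower[i] = min(self.lower[i], value)
            self.upper[i] = max(self.upper[i], value)
        self.values[i] = value

    def within_bounds(self, atol: float = 0.0) -> bool:
        return bool(
            np.all(self.values >= self.lower - atol)
            and np.all(self.values <= self.upper + atol)
        )


def build_flowering_topology() -> NetworkTopology:
    """The canonical 9-species photoperiod flowering pathway.

    Wiring: PHYB -> CO -> FT; FT + FD -> FT/FD complex; complex -> SOC1 and
    AP1; SOC1 <-> AGL24 positive feedback; AGL24 -> LFY.  FD and PHYB are
    constant inputs.
    """
    species = (
        Species(1, "CO", DEPENDENT),
        Species(2, "FT", DEPENDENT),
        Species(3, "FTFD_complex", DEPENDENT),
        Species(4, "SOC1", DEPENDENT),
        Species(5, "AP1", DEPENDENT),
        Species(6, "AGL24", DEPENDENT),
        Species(7, "LFY", DEPENDENT),
        Species(8, "FD", INDEPENDENT),
        Species(9, "PHYB", INDEPENDENT),
    )
    production = {
        1: ((9,),),        # PHYB activates CO
        2: ((1,),),        # CO activates FT
        3: ((2, 8),),      # FT + FD form the complex (joint substrate)
        4: ((3,), (6,)),   # complex and AGL24 each gate SOC1 (two factors)
        5: ((3,),),        # complex activates AP1
        6: ((4,),),        # SOC1 activates AGL24 (feedback)
        7: ((6,),),        # AGL24 activates LFY
    }
    degradation = {
        1: (1,),
        2: (2, 8),         # FT decay carries FD in its S-system exponent
        3: (3,),
        4: (4,),
        5: (5,),
        6: (6,),
        7: (7,),
    }
    return NetworkTopology(species, production, degradation)


_FACTOR_LETTERS = "abcdefgh"


def _suffix(d: int, n_factors: int, fi: int) -> str:
    return str(d) if n_factors == 1 else f"{d}{_FACTOR_LETTERS[fi]}"


def build_parameter_template(
    topology: NetworkTopology, formalism: Formalism | str
) -> ParameterVector:
    """Deterministic flattening of a topology's free parameters.

    Ordering contract (documented, relied on by every optimizer):

    * ``s_system`` — alpha_i for each dependent i in species order, then
      beta_i likewise, then kinetic orders in equation-reading order (for
      each i: its g exponents, then its h exponents).
    * ``michaelis_menten`` — Vm per synthesis factor in species/factor order,
      then Km in the same order, then dk_i.
    * ``mass_action`` — kr per synthesis factor in species/factor order,
      then dk_i.
    """
    formalism = Formalism.coerce(formalism)
    rlo, rhi = RATE_BOUNDS
    olo, ohi = KINETIC_ORDER_BOUNDS
    deps = topology.dependent_indices
    names: list[str] = []
    lo: list[float] = []
    hi: list[float] = []

    def rate(name: str) -> None:
        names.append(name)
        lo.append(rlo)
        hi.append(rhi)

    def order(name: str) -> None:
        names.append(name)
        lo.append(olo)
        hi.append(ohi)

    if formalism is Formalism.S_SYSTEM:
        for d in deps:
            rate(f"alpha{d}")
        for d in deps:
            rate(f"beta{d}")
        for d in deps:
            for fac in topology.production[d]:
                for j in fac:
                    order(f"g{d}{j}")
            for j in topology.degradation[d]:
                order(f"h{d}{j}")
    elif formalism is Formalism.MICHAELIS_MENTEN:
        for d in deps:
            facs = topology.production[d]
            for fi in range(len(facs)):
                rate(f"Vm{_suffix(d, len(facs), fi)}")
        for d in deps:
            facs = topology.production[d]
            for fi in range(len(facs)):
                rate(f"Km{_suffix(d, len(facs), fi)}")
        for d in deps:
            rate(f"dk{d}")
    elif formalism is Formalism.MASS_ACTION:
        for d in deps:
            facs = topology.production[d]
            for fi in range(len(facs)):
                rate(f"kr{_suffix(d, len(facs), fi)}")
        for d in deps:
            rate(f"dk{d}")

    lo_a = np.asarray(lo)
    hi_a = np.asarray(hi)
    mid = np.sqrt(np.maximum(lo_a, 1e-6) * hi_a)  # geometric midpoint as a neutral default
    if formalism is Formalism.S_SYSTEM:
        is_order = np.array([n[0] in "gh" for n in names])
        mid[is_order] = 1.0
    return ParameterVector(tuple(names), mid, lo_a, hi_a, formalism)


@dataclass
class KineticModel:
    """A topology bound to one formalism, with a compiled right-hand side."""

    topology: NetworkTopology
    formalism: Formalism
    parameter_template: ParameterVector = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.formalism = Formalism.coerce(self.formalism)
        if self.parameter_template is None:
            self.parameter_template = build_parameter_template(self.topology, self.formalism)
        self._compile()

    # -- compilation -------------------------------------------------------
    def _compile(self) -> None:
        """Precompute (parameter index, species position) maps so the RHS is
        plain float arithmetic; called once per model."""
        idx = self.parameter_template.index
        top = self.topology
        deps = top.dependent_indices
        self._dep0 = tuple(d - 1 for d in deps)
        self._indep0 = tuple(i - 1 for i in top.independent_indices)
        if self.formalism is Formalism.S_SYSTEM:
            self._syn = tuple(
                (idx(f"alpha{d}"),
                 tuple((idx(f"g{d}{j}"), j - 1) for fac in top.production[d] for j in fac))
                for d in deps
            )
            self._dec = tuple(
                (idx(f"beta{d}"),
                 tuple((idx(f"h{d}{j}"), j - 1) for j in top.degradation[d]))
                for d in deps
            )
        elif self.formalism is Formalism.MICHAELIS_MENTEN:
            terms = []
            for d in deps:
                facs = top.production[d]
                fac_terms = tuple(
                    (idx(f"Vm{_suffix(d, len(facs), fi)}"),
                     idx(f"Km{_suffix(d, len(facs), fi)}"),
                     tuple(j - 1 for j in fac))
                    for fi, fac in enumerate(facs)
                )
                terms.append((fac_terms, idx(f"dk{d}"), d - 1))
            self._mm = tuple(terms)
        elif self.formalism is Formalism.MASS_ACTION:
            terms = []
            for d in deps:
                facs = top.production[d]
                fac_terms = tuple(
                    (idx(f"kr{_suffix(d, len(facs), fi)}"), tuple(j - 1 for j in fac))
                    for fi, fac in enumerate(facs)
                )
                terms.append((fac_terms, idx(f"dk{d}"), d - 1))
            self._ma = tuple(terms)

    # -- evaluation --------------------------------------------------------
    def rhs_dependent(self, x: Sequence[float], p: Sequence[float]) -> list[float]:
        """Time derivatives of the dependent species only, in species order.

        ``x`` is the full state (all species); entries are clamped to zero
        from below, and additionally to ``POSITIVITY_FLOOR`` before
        exponentiation.  Hot path: pure float arithmetic, no numpy.
        """
        out = []
        if self.formalism is Formalism.S_SYSTEM:
            floor = POSITIVITY_FLOOR
            for (ai, gl), (bi, hl) in zip(self._syn, self._dec):
                syn = p[ai]
                for gi, j in gl:
                    xj = x[j]
                    syn *= (xj if xj > floor else floor) ** p[gi]
                dec = p[bi]
                for hi, j in hl:
                    xj = x[j]
                    dec *= (xj if xj > floor else floor) ** p[hi]
                out.append(syn - dec)
        elif self.formalism is Formalism.MICHAELIS_MENTEN:
            for facs, dki, d0 in self._mm:
                rate = 1.0
                for vmi, kmi, regs in facs:
                    s = 1.0
                    for j in regs:
                        xj = x[j]
                        s *= xj if xj > 0.0 else 0.0
                    rate *= p[vmi] * s / (p[kmi] + s)
                xd = x[d0]
                out.append(rate - p[dki] * (xd if xd > 0.0 else 0.0))
        else:
            for facs, dki, d0 in self._ma:
                rate = 1.0
                for kri, regs in facs:
                    term = p[kri]
                    for j in regs:
                        xj = x[j]
                        term *= xj if xj > 0.0 else 0.0
                    rate *= term
                xd = x[d0]
                out.append(rate - p[dki] * (xd if xd > 0.0 else 0.0))
        return out

    @property
    def dependent_positions(self) -> tuple[int, ...]:
        return self._dep0

    @property
    def independent_positions(self) -> tuple[int, ...]:
        return self._indep0


def instantiate_model(
    topology: NetworkTopology, formalism: Formalism | str
) -> KineticModel:
    """Bind a topology to one rate-law family.

    Raises ``ValueError`` naming the valid options for an unknown formalism.
    """
    return KineticModel(topology, Formalism.coerce(formalism))


def count_parameters(model: KineticModel) -> int:
    """Number of free parameters of the instantiated model."""
    return len(model.parameter_template)


def evaluate_rhs(
    model: KineticModel,
    state: Sequence[float],
    params: ParameterVector | Sequence[float],
) -> np.ndarray:
    """Full-state time derivative; independent species get exactly 0.

    ``state`` must be non-negative (the integrator may wander slightly
    negative internally, but user-facing evaluation rejects it).
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (model.topology.n_species,):
        raise ValueError(
            f"state must have length {model.topology.n_species}, got {x.shape}"
        )
    if np.any(x < 0):
        raise ValueError("state entries must be non-negative")
    if isinstance(params, ParameterVector):
        if params.formalism is not model.formalism:
            raise ValueError(
                f"parameter vector is for {params.formalism.value}, "
                f"model is {model.formalism.value}"
            )
        p = params.values
    else:
        p = np.asarray(params, dtype=float)
        if p.shape != (len(model.parameter_template),):
            raise ValueError("parameter vector has wrong length")
    derivs = np.zeros(model.topology.n_species)
    derivs[list(model.dependent_positions)] = model.rhs_dependent(x.tolist(), p.tolist())
    return derivs
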