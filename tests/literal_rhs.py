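"""Independent oracle: literal, line-by-line transcriptions of the governing
equations of the flowering-time network, one function per rate-law family.

These are deliberately written against named parameters and explicit state
symbols, with no shared code with the package's compiled right-hand sides.
"""

import numpy as np


def s_system_rhs(x, p):
    """x: length-9 state (X1..X9); p: dict of named parameters."""
    X1, X2, X3, X4, X5, X6, X7, X8, X9 = x
    return np.array([
        p["alpha1"] * X9 ** p["g19"] - p["beta1"] * X1 ** p["h11"],
        p["alpha2"] * X1 ** p["g21"] - p["beta2"] * X2 ** p["h22"] * X8 ** p["h28"],
        p["alpha3"] * X2 ** p["g32"] * X8 ** p["g38"] - p["beta3"] * X3 ** p["h33"],
        p["alpha4"] * X3 ** p["g43"] * X6 ** p["g46"] - p["beta4"] * X4 ** p["h44"],
        p["alpha5"] * X3 ** p["g53"] - p["beta5"] * X5 ** p["h55"],
        p["alpha6"] * X4 ** p["g64"] - p["beta6"] * X6 ** p["h66"],
        p["alpha7"] * X6 ** p["g76"] - p["beta7"] * X7 ** p["h77"],
        0.0,
        0.0,
    ])


def michaelis_menten_rhs(x, p):
    X1, X2, X3, X4, X5, X6, X7, X8, X9 = x
    return np.array([
        p["Vm1"] * X9 / (p["Km1"] + X9) - p["dk1"] * X1,
        p["Vm2"] * X1 / (p["Km2"] + X1) - p["dk2"] * X2,
        p["Vm3"] * X2 * X8 / (p["Km3"] + X2 * X8) - p["dk3"] * X3,
        (p["Vm4a"] * X3 / (p["Km4a"] + X3))
        * (p["Vm4b"] * X6 / (p["Km4b"] + X6))
        - p["dk4"] * X4,
        p["Vm5"] * X3 / (p["Km5"] + X3) - p["dk5"] * X5,
        p["Vm6"] * X4 / (p["Km6"] + X4) - p["dk6"] * X6,
        p["Vm7"] * X6 / (p["Km7"] + X6) - p["dk7"] * X7,
        0.0,
        0.0,
    ])


def mass_action_rhs(x, p):
    X1, X2, X3, X4, X5, X6, X7, X8, X9 = x
    return np.array([
        p["kr1"] * X9 - p["dk1"] * X1,
        p["kr2"] * X1 - p["dk2"] * X2,
        p["kr3"] * X2 * X8 - p["dk3"] * X3,
        (p["kr4a"] * X3) * (p["kr4b"] * X6) - p["dk4"] * X4,
        p["kr5"] * X3 - p["dk5"] * X5,
        p["kr6"] * X4 - p["dk6"] * X6,
        p["kr7"] * X6 - p["dk7"] * X7,
        0.0,
        0.0,
    ])


LITERAL_RHS = {
    "s_system": s_system_rhs,
    "michaelis_menten": michaelis_menten_rhs,
    "mass_action": mass_action_rhs,
}


def random_parameters(template, rng):
    """Random draw inside the template's bounds as a name->value dict plus the
    flat vector in template order."""
    lo = np.where(np.isfinite(template.lower), template.lower, 0.0)
    hi = np.minimum(template.upper, 10.0)
    vals = lo + rng.random(len(template)) * (hi - lo)
    return dict(zip(template.names, vals)), vals
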