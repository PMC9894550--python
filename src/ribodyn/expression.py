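"""Closed-form hairpin-controlled expression model and fitting routines.

Protein synthesis controlled by a start-codon hairpin follows

    E = A / (1 + tau_u * B),        tau_u = exp(-beta*dG_F) / k_F,

where A (1/min) is the maximal synthesis rate with no TIR structure, B
(1/s) the hairpin unfolding rate at half-maximal expression, k_F (1/s) the
hairpin folding rate and dG_F (kcal/mol) the hairpin free energy of
formation. In relative form E_R = E/A, the model linearises to

    ln(1/E_R - 1) = ln(B/k_F) - beta*dG_F,

which is fitted by least squares (slope free, or fixed to the physical
beta as in the original analysis).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import DEFAULT_TEMPERATURE, K_F_HAIRPIN
from .energy import beta as beta_of

__all__ = [
    "ExpressionModel",
    "tau_unfold",
    "expression",
    "fit_linear",
    "fit_AB",
    "table1_report",
    "COAT_MUTANTS",
]

#: Coat-hairpin mutant panel: (label, dG_F at 315 K in kcal/mol, measured
#: relative expression). The free energies and measurements are the inputs
#: of the expression analysis.
COAT_MUTANTS = [
    ("18", -6.63, 0.800),
    ("wt", -7.93, 1.000),
    ("11", -9.49, 0.200),
    ("5", -10.27, 0.040),
    ("17", -10.50, 0.030),
    ("20", -10.52, 0.060),
    ("22", -11.81, 0.003),
    ("23", -12.20, 0.002),
    ("15", -12.85, 0.001),
]

#: Best-fit constants of the expression curve (A in 1/min, B in 1/s).
A_FIT = 28.8
B_FIT = 1.40


@dataclass(frozen=True)
class ExpressionModel:
    A: float = A_FIT            # 1/min
    B: float = B_FIT            # 1/s
    k_F: float = K_F_HAIRPIN    # 1/s
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def beta(self) -> float:
        return beta_of(self.temperature)

    @property
    def C(self) -> float:
        return self.B / self.k_F

    def tau_u(self, dG_F: float) -> float:
        return tau_unfold(dG_F, self.k_F, self.beta)

    def E(self, dG_F: float) -> float:
        return expression(self.tau_u(dG_F), self.A, self.B)[0]


def tau_unfold(dG_F: float, k_F: float = K_F_HAIRPIN,
               beta: float | None = None,
               temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Hairpin unfolding time tau_u = exp(-beta*dG_F) / k_F, in seconds."""
    if k_F <= 0:
        raise ValueError("k_F must be positive")
    beta = beta_of(temperature) if beta is None else beta
    return math.exp(-beta * dG_F) / k_F


def expression(tau_u: float, A: float = A_FIT, B: float = B_FIT) -> tuple[float, float]:
    """Synthesis rate E = A/(1 + tau_u*B) in 1/min and relative E_R = E/A."""
    if tau_u < 0:
        raise ValueError("tau_u must be non-negative")
    if A <= 0 or B <= 0:
        raise ValueError("A and B must be positive")
    E = A / (1.0 + tau_u * B)
    return E, E / A


def fit_linear(E_R, dG_F, beta: float | None = None,
               temperature: float = DEFAULT_TEMPERATURE,
               fix_slope: bool = True) -> tuple[float, float]:
    """Least-squares fit of ln(1/E_R - 1) = b + m*(-dG_F).

    With `fix_slope` the slope is fixed at the physical beta and only the
    intercept b = ln(B/k_F) is estimated; otherwise both are free. Points
    with E_R >= 1 (saturated expression) are dropped with a warning.

    Returns (intercept, slope).
    """
    E_R = np.asarray(E_R, dtype=float)
    dG_F = np.asarray(dG_F, dtype=float)
    keep = (E_R > 0) & (E_R < 1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} point(s) with E_R >= 1 "
                      "(saturated) or E_R <= 0", stacklevel=2)
    E_R, dG_F = E_R[keep], dG_F[keep]
    if len(E_R) < (1 if fix_slope else 2):
        raise ValueError("not enough points to fit")
    y = np.log(1.0 / E_R - 1.0)
    x = -dG_F
    if fix_slope:
        m = beta_of(temperature) if beta is None else beta
        b = float(np.mean(y - m * x))
        return b, m
    m, b = np.polyfit(x, y, 1)
    return float(b), float(m)


def fit_AB(tau_u, E, p0: tuple[float, float] = (10.0, 1.0)) -> tuple[float, float]:
    """Nonlinear least squares of E = A/(1 + tau_u*B).

    Needs at least 3 points spanning the saturation shoulder (some
    tau_u*B >~ 1); degenerate spans raise.
    """
    tau_u = np.asarray(tau_u, dtype=float)
    E = np.asarray(E, dtype=float)
    if len(tau_u) < 3:
        raise ValueError("need at least 3 points")
    if (tau_u * p0[1]).max() < 0.1 and tau_u.max() * 10 < 0.1:
        raise ValueError("tau_u span too small to constrain B")
    popt, _ = curve_fit(lambda t, A, B: A / (1.0 + t * B), tau_u, E,
                        p0=p0, maxfev=20000)
    A, B = float(popt[0]), float(popt[1])
    if A <= 0 or B <= 0:
        raise ValueError("degenerate fit")
    return A, B


def table1_report(mutants=None, A: float = A_FIT, B: float = B_FIT,
                  k_F: float = K_F_HAIRPIN,
                  temperature: float = DEFAULT_TEMPERATURE) -> pd.DataFrame:
    """Per-mutant tau_u, E and theoretical E_R for a hairpin panel.

    `mutants` is a list of (label, dG_F[, measured E_R]) tuples; defaults
    to the coat-hairpin panel. Returns a tidy DataFrame.
    """
    mutants = COAT_MUTANTS if mutants is None else mutants
    beta = beta_of(temperature)
    rows = []
    for entry in mutants:
        label, dG_F = entry[0], entry[1]
        measured = entry[2] if len(entry) > 2 else np.nan
        tu = tau_unfold(dG_F, k_F, beta)
        E, E_R = expression(tu, A, B)
        rows.append({"mutant": label, "dG_F": dG_F, "tau_u": tu,
                     "E": E, "E_R_measured": measured, "E_R_theory": E_R})
    return pd.DataFrame(rows)
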