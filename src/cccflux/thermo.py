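"""Thermodynamics of electroneutral cation-chloride cotransport.

Cation-chloride cotransporters (CCCs, SLC12 family) move Na+, K+ and Cl-
across a membrane with fixed integer coupling and zero net charge per
transport cycle.  Because no charge moves, the membrane potential drops out
and the chemical driving force per cycle is purely a function of the ion
concentration ratios:

    dmu = R * T * sum_x( n_x * ln([X]_i / [X]_o) )     [J/mol of cycles]

with x over {Na+, K+, Cl-} and n_x the stoichiometric count of each ion.
Negative dmu favors net influx; the flux reversal point (FRP) is the
internal Cl- concentration at which dmu = 0 and net cotransport stops.

Concentrations are in mM throughout, temperature in K, energies in J/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Gas constant, J mol^-1 K^-1.
R = 8.314

#: Default absolute temperature, K (25 degrees C).
DEFAULT_TEMPERATURE = 298.15

#: Faraday constant, C mol^-1 (used only by the Nernst potential).
FARADAY = 96485.33212


class ThermoError(ValueError):
    """Invalid thermodynamic input (concentration, stoichiometry, grid)."""


@dataclass(frozen=True)
class Stoichiometry:
    """Integer ion coupling of one electroneutral transport cycle.

    Electroneutrality requires the cation count to equal the anion count:
    ``n_na + n_k == n_cl``.  At least one cation must be carried.
    """

    n_na: int
    n_k: int
    n_cl: int

    def __post_init__(self) -> None:
        for name, n in (("n_na", self.n_na), ("n_k", self.n_k), ("n_cl", self.n_cl)):
            if int(n) != n or n < 0:
                raise ThermoError(f"{name} must be a non-negative integer, got {n!r}")
        if self.n_cl < 1:
            raise ThermoError("n_cl must be >= 1 for a chloride-coupled cycle")
        if self.n_na + self.n_k != self.n_cl:
            raise ThermoError(
                f"not electroneutral: n_na + n_k = {self.n_na + self.n_k} "
                f"!= n_cl = {self.n_cl}"
            )
        if self.n_na + self.n_k == 0:
            raise ThermoError("at least one cation count must be positive")

    def __str__(self) -> str:
        return f"{self.n_na}Na:{self.n_k}K:{self.n_cl}Cl"

    @classmethod
    def parse(cls, text: str) -> "Stoichiometry":
        """Parse ``"Na:K:Cl"`` integer triples such as ``"1:1:2"``."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ThermoError(f"expected Na:K:Cl triple, got {text!r}")
        return cls(*(int(p) for p in parts))


#: K+-Cl- cotransport (KCC-type), 1 K+ : 1 Cl- per cycle.
KCC = Stoichiometry(0, 1, 1)
#: Na+-K+-2Cl- cotransport (NKCC-type).
NKCC = Stoichiometry(1, 1, 2)
#: Na+-Cl- cotransport (NCC-type).
NCC = Stoichiometry(1, 0, 1)


@dataclass(frozen=True)
class BathConditions:
    """Intra/extracellular ion concentrations (mM) and temperature (K).

    The defaults reflect a Xenopus oocyte in standard ND96 bath solution:
    100 mM internal K+, 10 mM internal Na+, 96 mM external Na+, 2 mM
    external K+ and 106.6 mM external Cl-.  Internal Cl- defaults to the
    chloride-depleted state (0.1 mM) and is typically swept.
    """

    na_i: float = 10.0
    na_o: float = 96.0
    k_i: float = 100.0
    k_o: float = 2.0
    cl_i: float = 0.1
    cl_o: float = 106.6
    temperature: float = DEFAULT_TEMPERATURE
    cl_free: bool = False  # marks a chloride-free bath (dmu undefined if Cl-coupled)

    def __post_init__(self) -> None:
        for name in ("na_i", "na_o", "k_i", "k_o", "cl_i", "cl_o"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ThermoError(f"{name} must be finite and non-negative, got {v!r}")
        if not self.temperature > 0:
            raise ThermoError(f"temperature must be > 0 K, got {self.temperature!r}")

    def with_cl_i(self, cl_i: float) -> "BathConditions":
        return replace(self, cl_i=cl_i)


def _ion_ratios(stoich: Stoichiometry, cond: BathConditions) -> list[tuple[str, int, float, float]]:
    return [
        ("Na+", stoich.n_na, cond.na_i, cond.na_o),
        ("K+", stoich.n_k, cond.k_i, cond.k_o),
        ("Cl-", stoich.n_cl, cond.cl_i, cond.cl_o),
    ]


def driving_force(stoich: Stoichiometry, cond: BathConditions) -> float:
    """Chemical driving force per transport cycle, in J/mol.

    Negative values favor net influx, positive net efflux, zero is the
    flux reversal point.  Raises :class:`ThermoError` naming the offending
    ion if a concentration with a nonzero stoichiometric count is not
    strictly positive.
    """
    total = 0.0
    for ion, n, c_in, c_out in _ion_ratios(stoich, cond):
        if n == 0:
            continue
        if c_in <= 0 or c_out <= 0:
            raise ThermoError(
                f"{ion} concentration must be > 0 when carried "
                f"(got [in]={c_in}, [out]={c_out})"
            )
        total += n * math.log(c_in / c_out)
    return R * cond.temperature * total


def frp_chloride(stoich: Stoichiometry, cond: BathConditions) -> float:
    """Internal Cl- concentration (mM) at which the driving force is zero.

    Closed form from dmu = 0:

        cl_i* = cl_o * ( prod_cations ([X]_o / [X]_i)^n_x )^(1 / n_cl)

    For KCC (0:1:1) this is ``cl_o * k_o / k_i``; for NKCC (1:1:2) it is
    ``cl_o * sqrt(na_o * k_o / (na_i * k_i))``.  Independent of temperature.
    """
    log_sum = 0.0
    for ion, n, c_in, c_out in _ion_ratios(stoich, cond)[:2]:  # cations only
        if n == 0:
            continue
        if c_in <= 0 or c_out <= 0:
            raise ThermoError(
                f"{ion} concentration must be > 0 when carried "
                f"(got [in]={c_in}, [out]={c_out})"
            )
        log_sum += n * math.log(c_out / c_in)
    if cond.cl_o <= 0:
        raise ThermoError("Cl- concentration must be > 0 when carried (got [out]=%r)" % cond.cl_o)
    return cond.cl_o * math.exp(log_sum / stoich.n_cl)


def driving_force_curve(
    stoich: Stoichiometry,
    cond: BathConditions,
    cl_i_grid: Sequence[float] | np.ndarray,
) -> pd.DataFrame:
    """Evaluate the driving force along a grid of internal Cl- values.

    Returns a DataFrame with columns ``cl_i_mM`` and ``dmu_J_per_mol``.
    The curve is strictly increasing in Cl_i and crosses zero exactly once,
    at :func:`frp_chloride`.
    """
    grid = np.asarray(cl_i_grid, dtype=float)
    if grid.size == 0:
        raise ThermoError("cl_i grid is empty")
    if np.any(grid <= 0):
        raise ThermoError("cl_i grid must be strictly positive")
    if np.any(np.diff(grid) <= 0):
        raise ThermoError("cl_i grid must be strictly increasing")
    dmu = [driving_force(stoich, cond.with_cl_i(c)) for c in grid]
    return pd.DataFrame({"cl_i_mM": grid, "dmu_J_per_mol": dmu})


def nernst_potential(z: int, x_o: float, x_i: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Equilibrium (Nernst) potential for a single ion, in mV.

    E = (R*T)/(z*F) * ln([X]_o/[X]_i).  For a monovalent cation at 25 C
    this is 25.693 mV times the log concentration ratio.
    """
    if z == 0:
        raise ThermoError("valence z must be nonzero")
    if x_o <= 0 or x_i <= 0:
        raise ThermoError("concentrations must be > 0 for a Nernst potential")
    return (R * temperature) / (z * FARADAY) * math.log(x_o / x_i) * 1000.0


# ---------------------------------------------------------------------------
# Bath solution recipes

#: mM of each salt in standard ND96; total Cl- from salts is 103.6 mM
#: (96 + 2 + 2*1.8 + 2*1), but the conventional stated value 106.6 mM is
#: the default reported external Cl- (the salt sum is available by flag).
_ND96_SALTS = {"NaCl": 96.0, "KCl": 2.0, "CaCl2": 1.8, "MgCl2": 1.0}

ND96_STATED_CL = 106.6
ND96_SALT_SUM_CL = 96.0 + 2.0 + 2 * 1.8 + 2 * 1.0  # 103.6

RECIPES = (
    "ND96",
    "ND96-10K",
    "ND96-5Rb",
    "Na-free",
    "Cl-free",
    "TEVC-ND96",
)


def solution_conditions(
    recipe: str,
    *,
    na_i: float = 10.0,
    k_i: float = 100.0,
    cl_i: float = 0.1,
    temperature: float = DEFAULT_TEMPERATURE,
    use_salt_sum_chloride: bool = False,
) -> BathConditions:
    """External ion totals for a named oocyte bath solution.

    Recipes (K-substituted variants reduce NaCl mole-for-mole to keep
    osmolality; Rb+ is pooled into k_o as a K+ congener):

    - ``ND96``: 96 NaCl / 2 KCl / 1.8 CaCl2 / 1 MgCl2 (mM)
    - ``ND96-10K``: 2 mM KCl replaced by 10 mM KCl, NaCl reduced to 88
    - ``ND96-5Rb``: 2 mM KCl replaced by 5 mM RbCl, NaCl reduced to 93
    - ``Na-free``: NaCl replaced by NMDG-Cl (na_o = 0, Cl- unchanged)
    - ``Cl-free``: all Cl- salts as gluconate (cl_o = 0, flagged)
    - ``TEVC-ND96``: Ca-free clamp solution, 100 NaCl / 2 KCl / 5 MgCl2
    """
    name = recipe.strip()
    cl_o = ND96_SALT_SUM_CL if use_salt_sum_chloride else ND96_STATED_CL
    base = dict(na_i=na_i, k_i=k_i, cl_i=cl_i, temperature=temperature)
    if name == "ND96":
        return BathConditions(na_o=96.0, k_o=2.0, cl_o=cl_o, **base)
    if name == "ND96-10K":
        return BathConditions(na_o=88.0, k_o=10.0, cl_o=cl_o, **base)
    if name == "ND96-5Rb":
        return BathConditions(na_o=93.0, k_o=5.0, cl_o=cl_o, **base)
    if name == "Na-free":
        return BathConditions(na_o=0.0, k_o=2.0, cl_o=cl_o, **base)
    if name == "Cl-free":
        return BathConditions(na_o=96.0, k_o=2.0, cl_o=0.0, cl_free=True, **base)
    if name == "TEVC-ND96":
        return BathConditions(na_o=100.0, k_o=2.0, cl_o=100.0 + 2.0 + 2 * 5.0, **base)
    raise ThermoError(f"unknown solution recipe {recipe!r}; choose from {RECIPES}")
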