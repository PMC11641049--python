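"""Two-electrode voltage-clamp (TEVC) current-voltage analysis.

An oocyte is clamped stepwise across a voltage protocol (default range
-120..+60 mV) and the steady-state current recorded at each step.  From the
I/V relation we extract the reversal potential (zero-current voltage, by
linear interpolation between the bracketing steps), the whole-cell
conductance (least-squares slope of the I/V curve in a window around the
reversal potential), a smoothing polynomial fit, and group comparisons of
resting membrane potentials.

Units: voltages mV, currents uA, conductances uS (1 uA/mV = 1000 uS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

#: uA per mV is milli-siemens; report micro-siemens.
US_PER_UA_PER_MV = 1000.0

DEFAULT_WINDOW_MV = 20.0


class IVDataError(ValueError):
    """Invalid I/V input (mismatched lengths, bad protocol, replication)."""


@dataclass
class IVTrace:
    """Steady-state current-voltage pairs from a step protocol.

    Voltages are sorted ascending on construction (currents reordered with
    them).  Metadata identifies the oocyte, experimental group and any
    inhibitor present.
    """

    voltages_mv: np.ndarray
    currents_ua: np.ndarray
    oocyte_id: str = ""
    group: str = ""
    inhibitor: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages_mv, dtype=float)
        i = np.asarray(self.currents_ua, dtype=float)
        if v.shape != i.shape or v.ndim != 1:
            raise IVDataError("voltages and currents must be equal-length 1-D arrays")
        if v.size < 2:
            raise IVDataError("need at least 2 voltage steps")
        order = np.argsort(v)
        v, i = v[order], i[order]
        if np.any(np.diff(v) == 0):
            raise IVDataError("duplicate voltage steps in protocol")
        self.voltages_mv = v
        self.currents_ua = i


@dataclass
class ReversalResult:
    """Zero-current crossing of an I/V trace; ``found`` False if none in range."""

    e_rev_mv: Optional[float]
    found: bool
    message: str = ""


def steady_state_currents(time_series: np.ndarray, fraction: float = 0.2) -> float:
    """Steady-state current of one voltage step: mean of the final fraction."""
    ts = np.asarray(time_series, dtype=float)
    n_tail = max(1, int(round(ts.size * fraction)))
    return float(ts[-n_tail:].mean())


def reversal_potential(trace: IVTrace) -> ReversalResult:
    """Reversal potential by linear interpolation at the I = 0 crossing.

    If every current has the same sign the result is flagged not-found
    rather than extrapolated.
    """
    v, i = trace.voltages_mv, trace.currents_ua
    exact = np.flatnonzero(i == 0)
    if exact.size:
        return ReversalResult(float(v[exact[0]]), True)
    sign_change = np.flatnonzero(np.diff(np.sign(i)) != 0)
    if sign_change.size == 0:
        return ReversalResult(None, False, "no zero-current crossing within protocol range")
    j = int(sign_change[0])
    v0, v1, i0, i1 = v[j], v[j + 1], i[j], i[j + 1]
    e = v0 - i0 * (v1 - v0) / (i1 - i0)
    return ReversalResult(float(e), True)


def conductance_near_reversal(
    trace: IVTrace, window_mv: float = DEFAULT_WINDOW_MV
) -> float:
    """Whole-cell conductance (uS): I/V slope within +/-window of reversal.

    Falls back (with a warning) to the protocol-wide slope when fewer than
    3 points lie in the window or no reversal potential exists.
    """
    v, i = trace.voltages_mv, trace.currents_ua
    rev = reversal_potential(trace)
    if rev.found:
        mask = np.abs(v - rev.e_rev_mv) <= window_mv
        if mask.sum() < 3:
            warnings.warn(
                f"only {int(mask.sum())} points within +/-{window_mv} mV of reversal; "
                "using protocol-wide slope"
            )
            mask = np.ones_like(v, dtype=bool)
    else:
        warnings.warn(rev.message + "; using protocol-wide slope")
        mask = np.ones_like(v, dtype=bool)
    if np.allclose(i[mask], 0.0):
        return 0.0
    slope = stats.linregress(v[mask], i[mask]).slope  # uA / mV
    return float(slope * US_PER_UA_PER_MV)


def polynomial_iv_fit(trace: IVTrace, degree: int = 3) -> np.polynomial.Polynomial:
    """Least-squares polynomial smoothing of the I/V curve.

    Returns a ``numpy.polynomial.Polynomial`` in the data's natural domain
    (so ``.coef`` are plain power-series coefficients in mV).
    """
    v, i = trace.voltages_mv, trace.currents_ua
    if degree >= v.size:
        raise IVDataError(f"degree {degree} needs more than {v.size} points")
    if np.min(np.diff(v)) < 1e-9 * np.ptp(v):
        warnings.warn("near-duplicate voltages; polynomial fit may be ill-conditioned")
    return np.polynomial.Polynomial.fit(v, i, degree).convert()


def resting_vm_compare(groups: dict[str, np.ndarray]) -> dict:
    """Mean +/- SEM of resting membrane potential per group, unpaired t-test.

    ``groups`` maps label -> array of per-oocyte resting Vm (mV).  Exactly
    two groups are compared; each needs >= 2 oocytes.
    """
    if len(groups) != 2:
        raise IVDataError("resting-Vm comparison expects exactly 2 groups")
    clean = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in clean.items():
        if v.size < 2:
            raise IVDataError(f"group {g!r} has < 2 observations")
    labels = sorted(clean)
    summary = pd.DataFrame(
        {
            "n": {g: v.size for g, v in clean.items()},
            "mean_mv": {g: v.mean() for g, v in clean.items()},
            "sem_mv": {g: v.std(ddof=1) / np.sqrt(v.size) for g, v in clean.items()},
        }
    )
    t, p = stats.ttest_ind(clean[labels[0]], clean[labels[1]])
    return {
        "summary": summary,
        "test": {"name": "unpaired t-test", "statistic": float(t), "p_value": float(p)},
    }
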