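"""Radiotracer flux processing: counts-to-moles conversion and kinetics.

Oocyte uptake assays measure scintillation counts per minute (CPM) of a
radiotracer (86Rb standing in for K+).  Counts convert to transported
amount via the specific activity of the flux solution:

    SA     = (CPM_solution - CPM_blank) / pmol of monovalent carrier cation
    uptake = (CPM_sample  - CPM_blank) / SA          [pmol per oocyte]

The "monovalent carrier" denominator counts every cation the tracer rides
with (K+ plus Rb+ in Rb-substituted solutions).

Kinetic characterization distinguishes transporter classes: a carrier
operating near its flux reversal point saturates and is well described by
one-phase association, y(t) = ymax * (1 - exp(-k*t)) with half-time
ln(2)/k, while a carrier far from equilibrium gives near-linear uptake.
Model choice is reported by both R^2 and small-sample-corrected AIC (AICc),
since R^2 alone cannot adjudicate between models on different datasets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests


class FluxDataError(ValueError):
    """Invalid flux-experiment input (counts, aliquot, replication)."""


@dataclass(frozen=True)
class FluxExperiment:
    """A tracer-uptake experiment: per-oocyte counts plus conversion data.

    ``records`` columns: oocyte_id, group, time_min, cpm.  ``aliquot`` is
    the (cpm, pmol of monovalent carrier cation) pair measured on a known
    volume of flux solution, used for specific-activity determination.
    """

    records: pd.DataFrame
    blank_cpm: float = 0.0
    aliquot_cpm: float = float("nan")
    aliquot_pmol: float = float("nan")
    solution: str = "ND96"

    REQUIRED_COLUMNS = ("oocyte_id", "group", "time_min", "cpm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise FluxDataError(f"records missing columns: {missing}")
        if (self.records["cpm"] < 0).any():
            raise FluxDataError("cpm values must be >= 0")
        if (self.records["time_min"] < 0).any():
            raise FluxDataError("times must be >= 0")
        if self.records["group"].isna().any():
            raise FluxDataError("every record must carry a group label")

    @property
    def specific_activity(self) -> float:
        return specific_activity(self.aliquot_cpm, self.blank_cpm, self.aliquot_pmol)

    def to_uptake(self) -> pd.DataFrame:
        """Convert every record's CPM to pmol per oocyte (adds column ``uptake_pmol``)."""
        sa = self.specific_activity
        out = self.records.copy()
        out["uptake_pmol"] = [
            uptake_pmol(c, self.blank_cpm, sa) for c in out["cpm"].to_numpy()
        ]
        return out


def specific_activity(cpm_solution: float, cpm_blank: float, pmol_monovalent: float) -> float:
    """Specific activity of a flux solution, CPM per pmol of carrier cation."""
    if pmol_monovalent <= 0:
        raise FluxDataError(f"aliquot pmol must be > 0, got {pmol_monovalent}")
    net = cpm_solution - cpm_blank
    if net <= 0:
        raise FluxDataError(
            f"solution counts ({cpm_solution}) must exceed blank ({cpm_blank})"
        )
    sa = net / pmol_monovalent
    if sa < 1e-6:
        warnings.warn("specific activity is near zero; conversions will be unstable")
    return sa


def uptake_pmol(cpm_sample: float, cpm_blank: float, sa: float) -> float:
    """Per-oocyte uptake in pmol from sample counts and specific activity.

    Negative net counts (sample below blank) clamp to zero with a warning.
    """
    if sa <= 0:
        raise FluxDataError(f"specific activity must be > 0, got {sa}")
    net = cpm_sample - cpm_blank
    if net < 0:
        warnings.warn(f"sample counts below blank ({cpm_sample} < {cpm_blank}); clamping to 0")
        return 0.0
    return net / sa


@dataclass
class KineticFit:
    """Result of a kinetic model fit.

    ``model`` is ``"one_phase"`` (params ymax, k; half_time = ln2/k) or
    ``"linear"`` (params slope, intercept).  ``converged`` is False for
    degenerate/non-identifiable data; diagnostics then carry the reason.
    """

    model: Literal["one_phase", "linear"]
    params: dict
    r_squared: float
    aicc: float
    half_time: Optional[float] = None
    converged: bool = True
    message: str = ""

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        if self.model == "one_phase":
            return self.params["ymax"] * (1.0 - np.exp(-self.params["k"] * t))
        return self.params["slope"] * t + self.params["intercept"]


def _gof(y: np.ndarray, yhat: np.ndarray, n_params: int) -> tuple[float, float]:
    """R^2 and AICc for a least-squares fit (error variance counted as a parameter)."""
    resid = y - yhat
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    n = y.size
    k = n_params + 1
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    denom = n - k - 1
    aicc = aic + (2 * k * (k + 1) / denom) if denom > 0 else float("inf")
    return r2, aicc


def fit_one_phase(times, uptakes) -> KineticFit:
    """Least-squares fit of one-phase association y = ymax*(1 - exp(-k t)).

    Deterministic initialization (ymax0 = max(y), k0 = 1/mean(t)), k bounded
    positive.  Non-convergence or non-identifiable data (e.g. constant y)
    returns a ``KineticFit`` with ``converged=False`` rather than raising.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(uptakes, dtype=float)
    if np.unique(t).size < 4:
        raise FluxDataError("one-phase fit needs >= 4 distinct time points")
    if np.any(y < 0):
        raise FluxDataError("uptakes must be >= 0")

    def model(tt, ymax, k):
        return ymax * (1.0 - np.exp(-k * tt))

    if np.ptp(y) == 0:
        return KineticFit(
            model="one_phase", params={"ymax": float(y[0]), "k": float("nan")},
            r_squared=float("nan"), aicc=float("inf"), half_time=None,
            converged=False, message="constant response: rate non-identifiable",
        )
    p0 = (float(y.max()), 1.0 / float(t[t > 0].mean() if np.any(t > 0) else 1.0))
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return KineticFit(
            model="one_phase", params={"ymax": float("nan"), "k": float("nan")},
            r_squared=float("nan"), aicc=float("inf"), half_time=None,
            converged=False, message=f"fit failed: {exc}",
        )
    ymax, k = float(popt[0]), float(popt[1])
    r2, aicc = _gof(y, model(t, *popt), n_params=2)
    return KineticFit(
        model="one_phase", params={"ymax": ymax, "k": k},
        r_squared=r2, aicc=aicc, half_time=math.log(2) / k,
    )


def fit_linear(times, uptakes) -> KineticFit:
    """Ordinary least-squares line through the uptake time course."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(uptakes, dtype=float)
    if np.unique(t).size < 3:
        raise FluxDataError("linear fit needs >= 3 distinct time points")
    res = stats.linregress(t, y)
    yhat = res.slope * t + res.intercept
    r2, aicc = _gof(y, yhat, n_params=2)
    return KineticFit(
        model="linear",
        params={
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "slope_stderr": float(res.stderr),
        },
        r_squared=r2, aicc=aicc,
    )


def select_model(times, uptakes) -> KineticFit:
    """Fit both kinetic models and return the better-supported one.

    Primary criterion is AICc.  The saturating model is additionally
    required to be identifiable from the data: its fitted half-time must
    lie within the sampled time window.  A one-phase fit whose plateau is
    extrapolated beyond the data is indistinguishable from (and collapses
    to) a straight line, so AICc between the two equal-size models would
    reduce to comparing noise projections; in that regime the linear
    description is reported.
    """
    one = fit_one_phase(times, uptakes)
    lin = fit_linear(times, uptakes)
    if not one.converged:
        return lin
    t_max = float(np.max(np.asarray(times, dtype=float)))
    identifiable = one.half_time is not None and one.half_time <= t_max
    if identifiable and one.aicc < lin.aicc:
        return one
    return lin


def compare_groups(
    experiment: FluxExperiment | pd.DataFrame,
    *,
    value_column: str = "uptake_pmol",
    holm: bool = False,
) -> dict:
    """Group summary statistics and significance test for an uptake table.

    Two groups: unpaired two-sample t-test.  Three or more: one-way ANOVA,
    plus all pairwise t-tests (uncorrected by default, mirroring per-panel
    testing practice; ``holm=True`` applies Holm step-down correction).

    Returns a dict with ``summary`` (mean, sd, sem, n per group), ``test``
    (name, statistic, p value) and ``pairwise`` (DataFrame or None).
    """
    table = experiment.to_uptake() if isinstance(experiment, FluxExperiment) else experiment
    if value_column not in table.columns:
        raise FluxDataError(f"no column {value_column!r} in table")
    groups = {g: sub[value_column].to_numpy(dtype=float) for g, sub in table.groupby("group")}
    if len(groups) < 2:
        raise FluxDataError("need >= 2 groups to compare")
    for g, vals in groups.items():
        if vals.size < 2:
            raise FluxDataError(f"group {g!r} has < 2 observations")

    summary = pd.DataFrame(
        {
            "n": {g: v.size for g, v in groups.items()},
            "mean": {g: v.mean() for g, v in groups.items()},
            "sd": {g: v.std(ddof=1) for g, v in groups.items()},
            "sem": {g: v.std(ddof=1) / math.sqrt(v.size) for g, v in groups.items()},
        }
    )

    labels = sorted(groups)
    if len(groups) == 2:
        t, p = stats.ttest_ind(groups[labels[0]], groups[labels[1]])
        test = {"name": "unpaired t-test", "statistic": float(t), "p_value": float(p)}
        pairwise = None
    else:
        f, p = stats.f_oneway(*(groups[g] for g in labels))
        test = {"name": "one-way ANOVA", "statistic": float(f), "p_value": float(p)}
        rows = []
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                t, pp = stats.ttest_ind(groups[a], groups[b])
                rows.append({"group_a": a, "group_b": b, "t": float(t), "p_value": float(pp)})
        pairwise = pd.DataFrame(rows)
        if holm and not pairwise.empty:
            pairwise["p_holm"] = multipletests(pairwise["p_value"], method="holm")[1]
    return {"summary": summary, "test": test, "pairwise": pairwise}
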