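"""Synthetic fixtures for every stage of the pipeline.

Generates the three kinds of data the analysis consumes, with explicit
noise models and full ground-truth sidecars, so each stage can be tested
closed-loop without any external data:

- tracer-flux experiments (oocyte CPM tables): the uptake simulator is run
  for a known transporter class, converted to counts via a configured
  specific activity, and given multiplicative Gaussian per-oocyte noise
  (scintillation counts scale with uptake and cannot go negative, so the
  noise is CV-parameterized and truncated at zero);
- ohmic I/V traces with a known conductance and reversal potential per
  experimental group, plus per-group resting potentials;
- aligned CCC-like protein families with class signatures planted at the
  catalog's reference-anchored windows over a seed-fixed random scaffold
  (a synthetic stand-in for a real reference sequence), mutated outside
  signature columns at a configured background rate.

All generators are pure functions of (config, seed): the same inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import uptake as _uptake
from .signatures import AlignedFamily, SiteCatalog
from .tevc import IVTrace
from .thermo import KCC, NKCC, BathConditions, Stoichiometry, solution_conditions
from .tracer_flux import FluxExperiment

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Flux experiments


@dataclass
class FluxGeneratorConfig:
    """Design of a synthetic tracer-uptake time course.

    The defaults emulate a one-hour uptake assay: samples every 5 minutes,
    8 oocytes per time point, 10% coefficient of variation, a KCC-type
    transporter in standard ND96.  ``k_flux`` defaults differ by class:
    the KCC value saturates on the tens-of-minutes scale while the NKCC
    value stays far below its reversal point over the hour (quasi-linear
    uptake), mirroring expressed-vs-endogenous pathway rates.
    """

    true_model: str = "KCC"  # "KCC" or "NKCC"
    k_flux: Optional[float] = None
    volume_l: float = 1e-6
    noise_cv: float = 0.10
    n_oocytes: int = 8
    times_min: tuple[float, ...] = (0, 5, 10, 15, 20, 30, 40, 50, 60)
    solution: str = "ND96"
    specific_activity: float = 2.0  # CPM per pmol
    blank_cpm: float = 50.0
    aliquot_pmol: float = 1000.0
    dt_min: float = 0.05
    group: Optional[str] = None

    DEFAULT_K_FLUX = {"KCC": 0.025, "NKCC": 0.003}

    def __post_init__(self) -> None:
        if self.true_model not in ("KCC", "NKCC"):
            raise ConfigError(f"true_model must be KCC or NKCC, got {self.true_model!r}")
        if any(t < 0 for t in self.times_min):
            raise ConfigError("time grid must be non-negative")
        if self.noise_cv < 0:
            raise ConfigError("noise CV must be >= 0")
        if self.k_flux is None:
            self.k_flux = self.DEFAULT_K_FLUX[self.true_model]
        if self.group is None:
            self.group = self.true_model


def generate_flux_experiment(
    config: FluxGeneratorConfig, seed: int
) -> tuple[FluxExperiment, dict]:
    """Simulate a flux experiment; returns (experiment, ground truth).

    Truth carries the model class, k_flux, FRP, and the noiseless uptake
    (pmol) at each sampled time, sufficient to compute any recovery error.
    """
    rng = np.random.default_rng(seed)
    stoich = KCC if config.true_model == "KCC" else NKCC
    cond = solution_conditions(config.solution)
    model = _uptake.OocyteModel(
        stoich=stoich, k_flux=config.k_flux, volume_l=config.volume_l
    )
    horizon = max(config.times_min) if max(config.times_min) > 0 else config.dt_min
    sim = _uptake.simulate_uptake(
        model, cond, horizon_min=horizon, dt_min=config.dt_min
    )
    noiseless = np.interp(config.times_min, sim.times, sim.tracer_trace)

    records = []
    for t, clean in zip(config.times_min, noiseless):
        for k in range(config.n_oocytes):
            scale = max(rng.normal(1.0, config.noise_cv), 0.0) if config.noise_cv else 1.0
            pmol = clean * scale
            cpm = config.blank_cpm + pmol * config.specific_activity
            records.append(
                {
                    "oocyte_id": f"{config.group}_t{t:g}_o{k + 1}",
                    "group": config.group,
                    "time_min": float(t),
                    "cpm": float(cpm),
                }
            )
    experiment = FluxExperiment(
        records=pd.DataFrame(records),
        blank_cpm=config.blank_cpm,
        aliquot_cpm=config.blank_cpm + config.specific_activity * config.aliquot_pmol,
        aliquot_pmol=config.aliquot_pmol,
        solution=config.solution,
    )
    truth = {
        "true_model": config.true_model,
        "k_flux": config.k_flux,
        "frp_mM": sim.frp_mM,
        "saturated": sim.saturated,
        "times_min": list(map(float, config.times_min)),
        "noiseless_uptake_pmol": noiseless.tolist(),
        "specific_activity": config.specific_activity,
        "blank_cpm": config.blank_cpm,
        "seed": seed,
    }
    return experiment, truth


def flux_to_csv(experiment: FluxExperiment) -> str:
    return experiment.records.to_csv(index=False)


# ---------------------------------------------------------------------------
# I/V traces


@dataclass
class IVGeneratorConfig:
    """Design of synthetic ohmic TEVC recordings, two groups of oocytes.

    Defaults mirror a transporter-vs-control contrast: the expressing
    group has a 4x larger whole-cell conductance and a depolarized
    resting potential (pulled from the control value toward the Na+
    equilibrium potential).
    """

    g_us: dict = field(default_factory=lambda: {"VvCCC": 20.0, "water": 5.0})
    e_rev_mv: float = -10.0
    noise_sd_ua: float = 0.05
    protocol_mv: tuple[float, ...] = tuple(range(-120, 61, 20))
    n_per_group: int = 4
    resting_vm_mv: dict = field(default_factory=lambda: {"VvCCC": -20.0, "water": -40.0})
    resting_vm_sd: float = 3.0

    def __post_init__(self) -> None:
        if not self.protocol_mv:
            raise ConfigError("voltage protocol is empty")
        lo, hi = min(self.protocol_mv), max(self.protocol_mv)
        if not (lo < self.e_rev_mv < hi):
            raise ConfigError(
                f"protocol [{lo}, {hi}] mV does not bracket e_rev = {self.e_rev_mv} mV"
            )


def generate_iv_traces(config: IVGeneratorConfig, seed: int) -> tuple[list[IVTrace], dict]:
    """Ohmic traces I = g*(V - E) + noise per oocyte; returns (traces, truth)."""
    rng = np.random.default_rng(seed)
    v = np.asarray(config.protocol_mv, dtype=float)
    traces: list[IVTrace] = []
    resting: dict[str, list[float]] = {}
    for group, g in config.g_us.items():
        resting[group] = []
        for k in range(config.n_per_group):
            i_clean = g * (v - config.e_rev_mv) / 1000.0  # uA
            noise = rng.normal(0.0, config.noise_sd_ua, size=v.size) if config.noise_sd_ua else 0.0
            traces.append(
                IVTrace(
                    voltages_mv=v.copy(),
                    currents_ua=i_clean + noise,
                    oocyte_id=f"{group}_o{k + 1}",
                    group=group,
                )
            )
            resting[group].append(
                float(rng.normal(config.resting_vm_mv[group], config.resting_vm_sd))
            )
    truth = {
        "g_us": dict(config.g_us),
        "e_rev_mv": config.e_rev_mv,
        "noise_sd_ua": config.noise_sd_ua,
        "resting_vm_mv": dict(config.resting_vm_mv),
        "resting_vm_samples": resting,
        "seed": seed,
    }
    return traces, truth


def iv_to_csv(traces: list[IVTrace]) -> str:
    rows = []
    for tr in traces:
        for v, i in zip(tr.voltages_mv, tr.currents_ua):
            rows.append(
                {"voltage_mV": v, "current_uA": i, "oocyte_id": tr.oocyte_id, "group": tr.group}
            )
    return pd.DataFrame(rows).to_csv(index=False)


# ---------------------------------------------------------------------------
# Sequence families


@dataclass
class SequenceGeneratorConfig:
    """Design of a motif-planted aligned CCC-like family.

    Emulates two diverged transporter classes: a seed-fixed random
    scaffold is first mutated (outside signature columns) into one
    ancestor per class at ``class_divergence``, so the classes carry
    shared derived substitutions the way real clades do; each row then
    descends from its class ancestor with independent background
    mutations at ``mutation_rate``.  Class-specific Na+-site motifs and
    the class-shared K+/Cl- site residues are planted at the catalog's
    reference-anchored windows and held fixed.
    """

    n_kcc: int = 20
    n_nkcc: int = 20
    length: int = 600
    mutation_rate: float = 0.05
    class_divergence: Optional[float] = None  # defaults to mutation_rate
    catalog: SiteCatalog = field(default_factory=SiteCatalog.default)
    reference_id: str = "REF_KCC"

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate < 1):
            raise ConfigError("mutation rate must be in [0, 1)")
        if self.class_divergence is None:
            self.class_divergence = self.mutation_rate
        if not (0 <= self.class_divergence < 1):
            raise ConfigError("class divergence must be in [0, 1)")
        if self.length < self.catalog.max_position():
            raise ConfigError(
                f"length {self.length} < max catalog position {self.catalog.max_position()}"
            )


#: Class-shared site residues (conserved in KCCs and NKCCs alike),
#: VvCCC numbering: K+ site N148/I149/Y233, SCl2 G151/I152/I153,
#: SCl1 G379/I380/M381/Y527.
_SHARED_SITE_RESIDUES = {
    148: "N", 149: "I", 233: "Y",
    151: "G", 152: "I", 153: "I",
    379: "G", 380: "I", 381: "M", 527: "Y",
}


def generate_sequence_family(
    config: SequenceGeneratorConfig, seed: int
) -> tuple[AlignedFamily, dict]:
    """Build an aligned family with planted class signatures.

    Returns (family, truth) where truth maps sequence id -> planted class
    ("KCC_like" / "NKCC_like"); the reference row is a KCC-class scaffold.
    """
    rng = np.random.default_rng(seed)
    scaffold = rng.choice(_AMINO_ACIDS, size=config.length)
    for pos, res in _SHARED_SITE_RESIDUES.items():
        scaffold[pos - 1] = res

    signature_cols = set()
    class_motifs: dict[str, list[tuple[tuple[int, ...], tuple[str, ...]]]] = {
        "KCC_like": [],
        "NKCC_like": [],
    }
    for site in config.catalog.sites:
        for p in site.positions:
            signature_cols.add(p - 1)
        if site.discriminative:
            class_motifs["KCC_like"].append((site.positions, site.kcc_motifs))
            class_motifs["NKCC_like"].append((site.positions, site.nkcc_motifs))

    def mutate_rows(base: np.ndarray, rate: float) -> np.ndarray:
        row = base.copy()
        if rate > 0:
            for h in np.flatnonzero(rng.random(config.length) < rate):
                if h in signature_cols:
                    continue
                choices = _AMINO_ACIDS[_AMINO_ACIDS != row[h]]
                row[h] = choices[int(rng.integers(choices.size))]
        return row

    # shared derived substitutions per class, the hallmark of a real clade
    ancestors = {
        cls: mutate_rows(scaffold, config.class_divergence)
        for cls in ("KCC_like", "NKCC_like")
    }

    def build_row(cls: str, mutate: bool) -> str:
        row = ancestors[cls].copy()
        for positions, motifs in class_motifs[cls]:
            motif = motifs[int(rng.integers(len(motifs)))]
            for p, aa in zip(positions, motif):
                row[p - 1] = aa
        if mutate:
            row = mutate_rows(row, config.mutation_rate)
        return "".join(row)

    ids = [config.reference_id]
    rows = [build_row("KCC_like", mutate=False)]
    truth: dict[str, str] = {config.reference_id: "KCC_like"}
    for i in range(config.n_kcc):
        sid = f"KCC_{i + 1:02d}"
        ids.append(sid)
        rows.append(build_row("KCC_like", mutate=True))
        truth[sid] = "KCC_like"
    for i in range(config.n_nkcc):
        sid = f"NKCC_{i + 1:02d}"
        ids.append(sid)
        rows.append(build_row("NKCC_like", mutate=True))
        truth[sid] = "NKCC_like"
    family = AlignedFamily(ids=ids, rows=rows, reference_id=config.reference_id)
    return family, {"classes": truth, "seed": seed, "mutation_rate": config.mutation_rate}


# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Bundle of all three generator designs plus the master seed."""

    seed: int = 0
    flux: FluxGeneratorConfig = field(default_factory=FluxGeneratorConfig)
    iv: IVGeneratorConfig = field(default_factory=IVGeneratorConfig)
    sequences: SequenceGeneratorConfig = field(default_factory=SequenceGeneratorConfig)
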