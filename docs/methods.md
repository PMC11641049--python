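# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `cccflux`. It is written for users who want to know
exactly what the package computes and what passing its tests does — and
does not — demonstrate about real data.

## 1. Cotransport thermodynamics

Cation–chloride cotransporters (SLC12 family) are electroneutral: each
transport cycle moves `n_Na` Na⁺, `n_K` K⁺ and `n_Cl` Cl⁻ with
`n_Na + n_K = n_Cl`, so no net charge crosses the membrane and the
membrane potential does not enter the energetics. The chemical driving
force per mole of cycles is

    Δμ = R·T · Σ_X n_X · ln([X]ᵢ / [X]ₒ),    X ∈ {Na⁺, K⁺, Cl⁻}

with R = 8.314 J·mol⁻¹·K⁻¹ and T defaulting to 298.15 K. The sign
convention is: **negative Δμ favors net influx**. Setting Δμ = 0 and
solving for internal chloride gives the flux reversal point (FRP) in
closed form:

    [Cl⁻]ᵢ* = [Cl⁻]ₒ · ( Π_cations ([X]ₒ/[X]ᵢ)^{n_X} )^{1/n_Cl}

For K⁺:Cl⁻ (0:1:1) coupling this reduces to `cl_o·k_o/k_i`; for
Na⁺:K⁺:2Cl⁻ (1:1:2) to `cl_o·sqrt(na_o·k_o/(na_i·k_i))`. Under standard
oocyte conditions (100 mM [K⁺]ᵢ, 10 mM [Na⁺]ᵢ, ND96 bath with 106.6 mM
[Cl⁻]ₒ) the two intercepts are 2.132 mM and 46.71 mM respectively — the
quantitative core of the KCC-vs-NKCC argument: a KCC in a Cl⁻-depleted
oocyte sits close to equilibrium and stops quickly; an NKCC stays far from
it for the whole assay. The FRP is independent of temperature (T cancels
in Δμ = 0).

Two bookkeeping conventions:

- **ND96 chloride.** Summing the ND96 salts (96 NaCl + 2 KCl + 1.8 CaCl₂
  + 1 MgCl₂) gives 103.6 mM Cl⁻, but the conventional stated value for
  this solution is 106.6 mM. The stated value is the default (it is what
  published FRP predictions use); the salt sum is available via
  `use_salt_sum_chloride=True`. The 3 mM discrepancy is inherited from
  the source conventions and left visible rather than silently resolved.
- **Rb⁺ as a K⁺ congener.** ⁸⁶Rb is the standard K⁺ tracer, and
  Rb-substituted recipes pool Rb⁺ into `k_o`. A separate selectivity
  factor can be layered on by the caller if needed.

K-substituted recipes (ND96-10K, ND96-5Rb) reduce NaCl mole-for-mole to
maintain osmolality, so raising `k_o` 2→10 mM lowers `na_o` 96→88 mM.

## 2. Uptake simulation

`uptake.simulate_uptake` integrates internal Cl⁻ and tracer-cation
accumulation for a single oocyte treated as a well-mixed compartment
(default volume 1 µL, the order of magnitude of a stage V–VI oocyte;
volume only rescales time) in an infinite bath.

**Flux law.** No kinetic constants are available for these transporters
in oocytes, so the law is a modeling choice, and it is pluggable
(`flux_law=` accepts any function of Δμ). The default is **bounded linear
response**:

    J = −k_flux · clip(Δμ, ±Δμ_sat) · inhibition,   [pmol cycles/min]

Near equilibrium (|Δμ| < Δμ_sat) this is ordinary linear response — the
regime that matters for the saturation argument. Far from equilibrium the
carrier runs at its maximal turnover `k_flux·Δμ_sat`, reflecting the fact
that cycling rates saturate rather than growing without bound with the
thermodynamic push. Δμ_sat defaults to 5000 J·mol⁻¹ (≈ 2RT). Without the
bound, a transporter starting at 0.1 mM internal Cl⁻ sees |Δμ| fall from
~30 to ~8 kJ·mol⁻¹ as Cl⁻ climbs, producing a log-shaped trace even far
from the reversal point; with it, far-from-equilibrium uptake is linear
in time, which is the observed phenomenology for NKCC-mediated uptake.

`k_flux` is a free parameter. The default 0.025 pmol·min⁻¹/(J·mol⁻¹)
makes a KCC-type oocyte in ND96 saturate with a half-time of ~12 min,
matching the observed tens-of-minutes scale of oocyte uptake assays; this
is a calibration, not a prediction. The NKCC generator default (0.003)
keeps internal Cl⁻ below 4% of its 46.7 mM reversal point over a one-hour
assay — the "far from equilibrium" regime.

**Tracer bookkeeping.** The tracer trace counts *net* cation influx
(`n_K·max(J, 0)`), so accumulation ceases at the FRP. Unidirectional
isotope exchange at equilibrium is deliberately not modeled; if real
transporters exchange isotopes at the reversal point, measured uptake
would keep creeping upward where the simulation plateaus.

**Integration.** Fixed-step classical Runge–Kutta (RK4), default
dt = 0.05 min, chosen for bit-reproducibility over adaptive stepping; the
terminal values change by <0.1% under dt halving. A guard raises
`StepSizeError` if any RK4 stage or step overshoots the reversal point by
more than 1% (tiny overshoot from roundoff is clamped to the FRP).
Cl⁻-depleted oocytes start at 0.1 mM (not 0, keeping the logarithm
defined). Inhibition is single-site binding, `1/(1 + [I]/EC₅₀)`, with
class-typical bumetanide EC₅₀ values of 0.1 µM (NKCC) and 100 µM (KCC):
100 µM bumetanide silences an endogenous NKCC pathway (factor ~0.001)
while only halving a KCC.

## 3. Flux-data processing and kinetics

Counts convert to moles via specific activity:
`SA = (CPM_solution − CPM_blank)/pmol of monovalent carrier cation` and
`uptake = (CPM_sample − CPM_blank)/SA`. The denominator counts every
carrier cation the tracer rides with (K⁺ plus Rb⁺ where Rb-substituted
solutions are used — parameterized, since conventions differ). Negative
net counts clamp to zero with a warning.

Kinetic models: one-phase association `y = ymax·(1 − e^{−kt})`
(half-time ln2/k) and ordinary least squares. Fits report R² and AICc
(both models have two mean parameters plus an error variance, so AICc
differences reduce to RSS ratios at fixed n — AICc is carried anyway so
the comparison generalizes). One-phase fitting uses deterministic
initialization (ymax₀ = max y, k₀ = 1/mean t) with k bounded positive;
degenerate data (constant y) returns a flagged non-identifiable result
rather than raising.

**Model selection** (`select_model`) compares AICc with one guard: the
saturating model is accepted only when its fitted half-time lies within
the sampled time window. A one-phase curve whose plateau is extrapolated
beyond the data is indistinguishable from a straight line (the line is in
the closure of the one-phase family), so an unguarded AICc comparison
between the two equal-size models would reduce to comparing noise
projections; requiring the plateau to be observed is the standard remedy
for plateau models and makes selection consistent on both sides of the
dichotomy.

Group statistics mirror per-panel practice: unpaired t-test for two
groups, one-way ANOVA plus uncorrected pairwise t-tests for more
(`holm=True` enables Holm step-down for users who want family-wise
control).

## 4. TEVC analysis

Steady-state current per voltage step (mean of the final 20% of the step
when a raw time series is supplied), reversal potential by linear
interpolation at the zero-current crossing (never extrapolated: traces
with no sign change are flagged), and whole-cell conductance as the
least-squares I/V slope within ±20 mV of the reversal potential. The
20 mV window is a package default (it spans 2–3 steps of a typical 20 mV
protocol) and is configurable; with fewer than 3 in-window points the
protocol-wide slope is used and flagged. Units are fixed: mV, µA, µS
(1 µA/mV = 1000 µS). Polynomial I/V smoothing uses numpy's scaled-domain
least squares and returns plain power-series coefficients.

## 5. Signature classification

Structures of animal CCCs assign the K⁺ site, two Cl⁻ sites and — in
Na⁺-coupled transporters only — a Na⁺ site built by two short motifs:
LNIW/LNIL/LNIF plus ATLSS in NKCC/NCC proteins, versus QNIL plus STLGA in
KCCs and plant CCCs (which therefore lack the Na⁺ site). The catalog
anchors all positions in the reference sequence's own 1-based numbering
(grapevine VvCCC coordinates by default: K⁺ site 148/149/233, Cl⁻ site 2
at 151–153, Cl⁻ site 1 at 379–381/527, Na⁺-site anchors 453/456/457) and
maps them through the alignment, so gapped MSAs are handled exactly.
The two discriminative motif windows default to 147–150 and 453–457;
these window coordinates are package-chosen anchors consistent with the
site positions (the serine-window letters S453/G456/A457 are the known
Na⁺-site anchor residues) and are user-overridable.

A window matches a class when it is within the mismatch tolerance
(default 1, accommodating the LNIL(W/F) variation seen within the NKCC
class) *and* strictly closer to that class's motifs than to the rival's —
necessary because QNIL and LNIL differ by a single residue. Both windows
must agree for a call; conflicting or gap-obscured evidence returns
`ambiguous`. K⁺/Cl⁻-site residues are conserved across both classes and
are reported as supporting evidence only.

**Conservation score.** Per-column conservation is the frequency of the
modal residue among non-gap symbols, mapped linearly onto the
conventional 1–9 bins. This is a deliberate, declared stand-in for
evolutionary-model-based (Bayesian) conservation scoring, which requires
an external homolog search and is out of scope; the two are not
numerically comparable.

## 6. Phylogenetics

p-distance (proportion of differing residues over shared non-gap columns;
pairwise deletion by default, complete deletion by flag — the
gap-handling convention of distance-based protein phylogenies), Saitou–Nei
neighbor joining, column-resampling bootstrap, and Newick IO are
implemented from first principles; an established library implementation
serves as an independent cross-check in the test suite only.

NJ details: Q-matrix ties break on the lowest index pair; negative branch
length estimates are clamped to zero with the deficit moved to the
sibling so the joined pair's total is preserved; the unrooted tree is
stored rooted at the final trifurcation. NJ is exact — topology and
branch lengths — on additive matrices, and the test suite verifies
path-length-matrix recovery to 1e-12.

Bootstrap supports are split frequencies mapped onto the full-data NJ
tree (not a majority-rule consensus topology): simpler, deterministic
given the seed, and sufficient for asking whether a particular
bipartition is robust. Replicates in which some pair loses all comparable
columns are dropped and counted. The seed is a required parameter; there
is no hidden global state.

## 7. Synthetic data

The generators are pure functions of (config, seed) — same inputs, same
bytes — and every generated dataset ships a ground-truth sidecar
sufficient to compute any recovery error.

- **Flux experiments**: the uptake simulator is run for the configured
  truth class, sampled on a 0–60 min grid (8 oocytes per time point by
  default), converted to CPM via a configured specific activity, and
  given multiplicative Gaussian noise (CV 10% default) truncated at zero
  — scintillation counts scale with uptake and cannot be negative.
- **I/V traces**: ohmic, `I = g·(V − E_rev) + noise`, over a
  −120…+60 mV protocol; two groups emulating an expressing-vs-control
  contrast (20 vs 5 µS, resting potentials −20 vs −40 mV — the
  depolarized group lies between the control value and the Na⁺ Nernst
  potential, as expected for a cell gaining a Na⁺ conductance).
- **Sequence families**: a seed-fixed random scaffold (a synthetic
  stand-in for a real reference sequence, keeping the package
  download-free) is mutated once per class into a class ancestor
  (`class_divergence`, default 5%), giving the classes the shared derived
  substitutions real clades carry; rows then descend from their ancestor
  with independent background mutations (5% default) outside the
  signature columns, which are planted and held fixed.

What the generators do *not* emulate — and hence what passing tests do
not show about real data: oocyte batch effects beyond per-oocyte scaling,
endogenous background fluxes mixed into expressed-pathway data,
non-ohmic rectification of real whole-cell currents, alignment errors,
and any realistic amino-acid substitution process (mutations are uniform
over the 19 alternatives).

## 8. Pipeline verdict

Three independently reported evidence axes, requiring concordance (no
scalar score): (a) Na⁺-site signature absent (classification KCC_like),
(b) saturating uptake kinetics (guarded AICc selects one-phase),
(c) K⁺ₒ-dependent uptake — the ratio of simulated 60-min uptake under
10 vs 2 mM external K⁺ exceeds 1.5. The threshold separates the two
mechanisms by a wide margin: a transporter operating at its reversal
point scales its plateau with the FRP (ratio ~2.7 at the default
kinetics, ~5 asymptotically), while one far from equilibrium is
turnover-limited and gains nothing (ratio ~1.0). All axes KCC-consistent
→ "KCC-consistent"; none → "NKCC-consistent"; otherwise "mixed".

## 9. Problem sizes and tolerances

Defaults used throughout the test suite and examples: 0.05 min
integration step; 9-point, 0–60 min sampling grids with 8 oocytes per
point; 100-replicate model-selection sweeps; 40-sequence families of
length 600; 100 bootstrap replicates on desk-scale trees (the library
itself defaults to 1000 for real use). Closed-form vs numeric-root
agreement is asserted at relative 1e-9, additive-tree recovery at 1e-12,
and the driving force at the computed reversal point at |Δμ| < 1e-6
J·mol⁻¹.

## 10. Known limitations

- Absolute time courses depend on `k_flux` and Δμ_sat, which are
  calibrated, not derived; only the saturation-vs-linear *shape*
  dichotomy and the FRP positions are predictions.
- The FRP plateau assumes no isotope exchange at equilibrium (§2).
- The conservation score is frequency-based, not evolutionary (§5).
- Bootstrap supports are mapped onto the full-data topology; splits
  absent from that topology are not reported even if frequent among
  replicates.
- Electrogenic transport (and hence any membrane-potential term in Δμ)
  is out of scope; the TEVC module analyzes conductances empirically
  without modeling their molecular identity.
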