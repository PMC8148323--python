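# Methods

This note documents the models, numerical choices and free parameters of
`vapordose`, and states what the synthetic scenarios and calibrations do —
and do not — establish.

## Scope and reduction strategy

The package is a reduced-order re-implementation of a CFD/CSP vaping
dosimetry workflow: a CT-geometry respiratory tract with resolved
near-wall transport, a computer-simulated person in a displacement-
ventilated room, and quasi-coupled exhalation. None of the 3-D machinery
is reproduced. The reduction decisions are:

* the respiratory tract becomes a serial 1-D conduit path with lumped
  symmetric bronchial generations;
* near-wall transport becomes a gas-side film coefficient;
* turbulence and secondary flows become a single axial dispersion
  coefficient;
* the room becomes a two-zone (breathing-zone / far-field) box;
* the directed exhalation jet becomes a calibrated direct-transfer
  fraction into the near field.

Consequences: the four-way per-puff budget fractions produced by the 1-D
transport are *qualitatively* faithful (orderings across puff scenarios,
monotonicities, conservation) but quantitatively geometry-sensitive; the
published CFD fractions (84.1/85.0/64.4% absorbed for short/long/post
puff, 6.6/6.6/3.2% exhaled, 32.4% to the lungs for the post puff) are
therefore shipped as reference fixtures for the dose chain, not recomputed
by the solver. The dose-chain arithmetic itself is exact and is the
quantitative acceptance surface.

## Chemical properties

Species records carry a gas diffusivity, per-layer condensed-phase
diffusivities, and mucus:air / skin:air partition coefficients. The exact
values used in the original study are not published in its main text, so
defaults are estimation-based and everything is config-overridable:

* **Gas diffusivity** from the Fuller correlation (atomic diffusion
  volumes; THC C21H30O2 → 415 cm³/mol, giving D_air ≈ 4.0×10⁻⁶ m²/s at
  298 K). The correlation is monotone in temperature (T^1.75) and
  decreasing in molar mass; note that at *fixed* diffusion volume it
  saturates rather than vanishing as M → ∞ (the Lorentz-gas limit) — the
  vanishing limit holds in molar volume.
* **Condensed-phase diffusivities**: THC mucus 3×10⁻¹⁰ m²/s with tissue
  values ~1×10⁻¹⁰ m²/s; nicotine set 2–3× higher throughout (a much
  smaller molecule). This ordering is what makes THC retain more mass on
  the airway surface than nicotine.
* **Partition coefficients**: both species are treated as high-solubility
  (K_mucus_air = 10⁵); THC's skin:air partition is set a decade higher
  (10⁶, strongly lipophilic). These are declared assumptions, not
  measurements; the synthetic-scenario ranges bracket them by ×/÷10.

## Puff waveforms

Short/long puff inhalations default to half-sines of the stated durations;
the post puff defaults to a triangular waveform peaking at 30% of its
1.34 s duration (an early-peak, high-flow profile). Exhalations are
negative half-sines (1.8 s for short/long, 2.5 s for post). All waveforms
are renormalized on their discrete grid so the trapezoidal volume is exact
to machine precision; the half-sine peak flow is then πV/(2T) up to
O(dt²). Default sampling dt = 0.01 s resolves the shortest inhalation
with >100 points.

Puff volumes are not published. Defaults: 55 mL for the mouth puffs
(machine-smoking convention) and 500 mL for the post puff — a deep
mouth-to-lung breath, chosen so the post puff actually reaches the
bronchial generations (total conduit dead space of the default geometry is
~127 mL). The bystander breathes a sinusoidal nasal cycle, period 4 s
(three breaths in the 12 s exposure window) at 6 L/min minute volume.

## AMTB wall solver

Layers default to mucus 10 µm, epithelium 50 µm, sub-epithelium 100 µm
over a perfect blood sink (no systemic pharmacokinetics). The solver works
in the gas-equivalent variable ψ = C/K_cum: interfaces become continuity
conditions, layer conductivity is D·K_cum and capacity K_cum. Implicit
Euler on a cell-centered grid (default 40 cells/layer standalone, 12 in
the transport coupling) with harmonic-mean face conductances; the system
matrix is factorization-free (one banded solve per step). Discrete
bookkeeping uses exactly the scheme's flux terms, so cumulative uptake =
tissue inventory + sink outflow to machine precision. Verified against
the semi-infinite early-time flux K·C·√(D/(πt)) (≤2% error) and the
series-resistance steady state (≤0.5%).

A stack with zero partition coefficient is the insoluble limit and
short-circuits to zero flux (not an error). Fewer than 3 grid points per
layer is a configuration error.

## Gas-side film

Where no film coefficient is supplied, each airway segment uses the larger
of (i) the fully developed laminar duct value Sh = 3.66 on its hydraulic
diameter and (ii) the penetration-theory coefficient 2√(D/(π t_c)) with
contact time t_c = 1 s. A single puff is an entrance/impingement-dominated
transient over initially clean walls, for which the developed-flow value
is a severe underestimate in the wide upper-airway segments. Turbulent
enhancement is deliberately *not* applied to the film (it is lumped into
axial dispersion); applying it would make the fast post puff absorb more
than the short puff, inverting the physically expected ordering.

## Airway transport

Default geometry: oral cavity (100 mm × 5 cm²), oropharynx, larynx,
trachea (120 mm, 18 mm diameter), and symmetric bronchial generations 1–4
lumped across branches (2^g tubes per generation). Advection is
finite-volume with a van Leer flux limiter (second-order TVD away from
extrema), sub-stepped to a combined advective/dispersive positivity bound
(CFL 0.5); axial dispersion defaults to 5×10⁻⁴ m²/s. Each segment owns
one AMTB column driven by the segment-mean concentration; the mass the
column takes up is removed from the lumen cells in proportion to their
content, so the ledger closes exactly. Desorption back into the lumen is
disabled by default (a switch exists): when the column's surface flux
would go negative the column is held frozen for that step.

Mass past the distal (generation-4) boundary enters a well-mixed 0.5 L
distal reservoir which supplies the returning flow during exhalation —
this is what lets the post puff re-exhale part of its deep dose while
still leaving most of it "transported to the lungs". The budget counts:
absorbed (all columns), exhaled (mouth outflow), remaining (lumen at end),
to-lung (reservoir at end), each as percent of ∫max(Q,0)·C_inlet dt.

With the defaults the simulated budgets are: short puff 54.7% absorbed /
38.9% exhaled, long puff 70.0% / 25.9%, post puff 29.0% / 42.5% with
23.7% to the lungs. The orderings match the reference CFD study (longer
puffs absorb more; the post puff absorbs least and is the only scenario
with substantial lung transport), but the magnitudes do not — the CFD
budgets embed jet impingement on the tongue and palate and CT-specific
geometry that a serial 1-D model cannot localize. A green ordering test
establishes the reduced model's qualitative fidelity, nothing more.

## Room and bystander

Two-zone backward-Euler mass balance; the near field defaults to 8 L
(a breathing-zone box in front of the face) exchanging 0.8 L/s with the
far field; ventilation (0.018 m³/s) exhausts far-field air. Bookkeeping
uses the discrete update terms verbatim, so emitted = inventories +
exhausted + inhaled to machine precision, and the well-mixed pulse decays
as exp(−Qt/V) to 0.1%. Inhaled air is removed permanently (the bystander
returns none of the dose on exhalation — a worst-case accounting), and
dermal uptake samples the near-field concentration without depleting it
(a <3% effect).

Note the reference scenario's stated ventilation is internally
inconsistent: 0.018 m³/s in 27 m³ is 2.4 h⁻¹, not the stated 0.6 h⁻¹.
The package computes ACH from the flow and warns when a declared ACH
disagrees by >10%; it does not guess which value was intended.

### Secondhand calibration

Two reduced-order parameters have no published values and are fixed by a
one-time calibration (`scripts/calibrate_secondhand.py`) so that the
default post-puff scenario reproduces the study's worst-case secondhand
fractions over the 12 s window with breathing starting at plume arrival
(2 s):

* `direct_transfer_fraction` = **0.7173** → bystander inhales 5.9% of the
  exhaled mass;
* dermal `deposition_velocity` = **1.853×10⁻³ m/s** (with 0.025 m² of
  exposed facial skin) → 2.6% of the exhaled mass absorbed dermally.

These two numbers are reproduced *by construction*; tests asserting them
(±0.5 / ±0.3 percentage points) guard the calibration against regression,
they are not independent predictions. For soft (short/long-puff)
exhalations the plume never couples to the breathing zone: direct transfer
and near-field exchange are zero and the bystander dose is exactly zero.

## Dermal model

Skin is stratum corneum (20 µm, D = 10⁻¹² m²/s, partitioning against air
at K_skin_air) over viable epidermis (100 µm, partition 0.1 vs the SC)
with a perfused sink base, solved by the same layered column with the
deposition velocity as the gas film. For a strongly lipophilic vapor over
a 12 s window the stratum corneum is far from saturation, so uptake is
deposition-limited and absorbed mass tracks area·v_d·∫C dt (the solver
enforces this as a strict upper bound).

## Synthetic scenarios and parameter recovery

The generator draws complete runnable configs from declared ranges
(log-uniform for diffusivities and partition coefficients, bracketing the
THC/nicotine defaults by a factor of ten) using per-object child streams
of one seed, so ensembles are bit-exact reproducible regardless of
consumption order. Generated scenarios exercise solver stability and the
conservation/closure invariants; they emulate the *structure* of the
analysis (species, puff, room, skin), not any measured data, so green
ensemble tests establish robustness, not realism.

`recover_partition_coefficient` refits the air/mucus partition coefficient
from a wall-flux series by bounded 1-D least squares over log₁₀K. On
noise-free solver output it recovers K to well under 2%; with 5%
multiplicative noise the median error over 20 seeds stays under 10%. When
the gas film controls the flux (deposition-limited regime) K is
unidentifiable; the fit detects this by the flux's insensitivity to a
doubling of the fitted K (<2% relative change) and flags the result
instead of returning it silently.

## Numerical and rounding conventions

* SI units internally (m, s, kg); mg/µg appear only in the dose report.
* `paper_sigfigs` rounding: per-puff masses to 2 significant figures
  except the exhaled mass (1); overall secondhand percentages to 2
  decimals in percent; bystander doses computed from the *rounded*
  percentages and session emission from the *rounded* exhaled mass. This
  order of operations is the only one that makes every link of the
  printed reference chain (4 → 2.6 / 1.3 / 0.1 mg; 0.19% / 0.08%;
  7.6 / 3.2 µg; 2 mg/session) internally consistent.
* Degenerate inputs: zero inhaled mass makes a budget undefined (error);
  K = 0 is the insoluble limit (zero flux, not an error); configs with
  unknown keys are rejected outright.

## Known limitations

No aerosol-phase dynamics (vapor only), no temperature or buoyancy
coupling (supply/vapor/wall temperatures are metadata), no breath-holding
topography beyond an optional zero-flow hold, no metabolism or systemic
pharmacokinetics, no multi-puff accumulation, and no intra-segment
regional localization of uptake (tongue vs palate). Regional per-segment
uptake is reported but has no independent validation target.
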