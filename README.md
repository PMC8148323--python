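# vapordose

Reduced-order simulation of first- and secondhand exposure to THC vapor
from e-cigarette cannabis vaping: transient puff waveforms, airway wall
uptake through a layered air–mucus–tissue–blood (AMTB) diffusion model,
indoor dispersion of the exhaled pulse, bystander nasal inhalation and
dermal absorption, and the explicit dose-chain mass budget that turns
these fractions into per-puff milligrams and bystander micrograms.

It is written for exposure scientists and indoor-air researchers who need
a desk-scale, fully scriptable stand-in for CFD-based vaping dosimetry:
every stage is a plain Python function over NumPy arrays, every parameter
is a config key, and every result is reproducible from a config hash.

## The model

**Puff topography.** Three scenarios are built in, distinguished by their
inhalation/exhalation times: short puff (2.43 s in / 1.8 s out), long puff
(5.0 s / 1.8 s) and post puff (1.34 s / 2.5 s) — the post puff being the
fast, deep mouth-to-lung inhalation followed by a forceful exhalation.
Waveforms are half-sine (or early-peaked triangular) profiles normalized
so that ∫q dt equals the requested volume exactly.

**Airway wall uptake (AMTB).** Each airway wall is a stack of diffusive
layers — mucus, epithelium, sub-epithelium — over a perfectly perfused
blood sink. Writing ψ = C/K<sub>cum</sub> for the gas-equivalent
concentration, the layered diffusion problem becomes

∂(K·ψ)/∂t = ∂/∂x ( D·K · ∂ψ/∂x ),  flux|surface = k_g (C_air − ψ_s),  ψ|base = 0,

with continuity of ψ at layer interfaces (the double-film air/mucus
boundary condition collapses to the Robin condition above). The solver is
implicit-Euler finite volume with harmonic-mean face conductances; the
discrete uptake, inventory and sink-outflow ledgers close to machine
precision.

**Airway transport.** The tract is a serial path — oral cavity, pharynx,
larynx, trachea, symmetric bronchial generations 1–4 — carrying
flux-limited (van Leer) upwind advection plus a lumped axial dispersion,
with one AMTB column per segment and a well-mixed distal reservoir that
supplies returning flow during exhalation. Each puff yields the four-way
budget: absorbed / exhaled / remaining in tract / transported to the
lungs, as percent of inhaled mass.

**Room and bystander.** The 3 m × 3 m × 3 m displacement-ventilated room
(0.018 m³/s) is a two-zone model: a small near field around the
bystander's breathing zone exchanging with the far field. The directed
post-puff exhalation jet is abstracted into a calibrated
`direct_transfer_fraction`; dermal uptake at the face reuses the layered
solver with a calibrated gas-side deposition velocity. Both calibrations
(to the 5.9% inhaled / 2.6% dermal worst-case fractions of exhaled mass)
ship in `scripts/calibrate_secondhand.py`.

**Dose chain.** Per-puff dose = oil mass × THC fraction / puffs per fill;
downstream masses are products with the budget fractions. A
`paper_sigfigs` rounding mode reproduces printed-precision chains; a
`full_precision` mode carries exact arithmetic.

## Worked example

The reference dose chain — 0.5 g of 80% THC oil over 100 puffs, post-puff
budget (64.4% absorbed / 3.2% exhaled / 32.4% to the lungs), worst-case
secondhand fractions (5.9% / 2.6% of exhaled):

```sh
$ vapordose dose-chain --out out/
per-puff inhaled dose      : 4 mg
absorbed (respiratory)     : 2.6 mg
to lungs / remaining       : 1.3 mg
exhaled to room            : 0.1 mg
session emission           : 2 mg
bystander inhaled per puff : 7.6 ug (0.19% of inhaled dose)
bystander dermal per puff  : 3.2 ug (0.08% of inhaled dose)
```

One puff inhales 4 mg of THC; 2.6 mg is absorbed by the respiratory
surfaces, 1.3 mg reaches the lungs or stays in the tract, and 0.1 mg is
exhaled into the room — about 2 mg over a 20-puff session. Of the user's
inhaled dose, the bystander receives 0.19% by nasal inhalation (7.6 µg)
and 0.08% through facial skin (3.2 µg) in the worst case.

The full simulation pipeline (puff → airway → room → bystander) runs from
a scenario config:

```sh
$ vapordose run --config examples/post_puff.yaml --out out/
```

which writes the simulated budget (for the default reduced-order geometry:
29.0% absorbed, 42.5% exhaled, 4.8% remaining, 23.7% to the lungs — the
1-D model conserves the qualitative structure of the CFD budgets but not
their magnitudes; see `docs/methods.md`), the room concentration series,
and the dose report. The soft-exhalation scenario
(`examples/soft_exhalation.yaml`) yields zero bystander dose.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline per-puff dose-chain quantities — absorbed, exhaled
and lung/remaining masses per post puff, and the overall secondhand
inhaled and dermal fractions — by running the dose chain in
printed-precision mode from the reference scenario inputs, and writes them
as JSON.
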