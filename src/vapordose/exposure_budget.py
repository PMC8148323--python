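"""Dose-chain accounting: from e-liquid fill to bystander micrograms.

The chain is multiplicative: a per-puff inhaled dose (oil mass x THC mass
fraction / puffs per fill) is split by the per-puff exposure budget into
absorbed / exhaled / lung-or-remaining masses; the exhaled mass seeds the
room, of which the bystander inhales and dermally absorbs stated
fractions.  Overall secondhand fractions are therefore products of the
exhaled fraction and the secondhand fractions of exhaled mass.

Two rounding modes are provided.  ``full_precision`` carries exact
arithmetic through the chain.  ``paper_sigfigs`` reproduces the rounding
conventions of published exposure summaries: masses to 2 significant
figures except the exhaled-per-puff mass (1), overall percentages to 2
decimals in percent, and bystander doses computed *from the rounded*
overall percentages — the order of operations that makes every link of a
printed chain internally consistent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

from .airway_transport import ExposureBudget
from .errors import InvalidArgumentError

__all__ = [
    "DoseChainInputs",
    "DoseReport",
    "per_puff_dose",
    "dose_chain",
    "session_emission",
    "round_sig",
    "post_puff_reference_budget",
    "short_puff_reference_budget",
    "long_puff_reference_budget",
    "reference_dose_chain_inputs",
]


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0.0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass
class DoseChainInputs:
    """Everything the dose chain needs, fractions in percent."""

    oil_mass: float  # g
    thc_mass_fraction: float  # dimensionless in [0, 1]
    puffs_per_fill: int
    puffs_per_session: int
    budget: ExposureBudget
    secondhand_inhaled_frac_of_exhaled: float  # %
    secondhand_dermal_frac_of_exhaled: float  # %

    def __post_init__(self) -> None:
        if self.oil_mass < 0 or not 0.0 <= self.thc_mass_fraction <= 1.0:
            raise InvalidArgumentError("oil mass must be >=0 and mass fraction in [0,1]")
        if self.puffs_per_fill <= 0 or self.puffs_per_session < 0:
            raise InvalidArgumentError("puff counts must be positive / non-negative")
        for f in (
            self.secondhand_inhaled_frac_of_exhaled,
            self.secondhand_dermal_frac_of_exhaled,
        ):
            if not 0.0 <= f <= 100.0:
                raise InvalidArgumentError(f"secondhand fraction {f} outside [0, 100]")


@dataclass
class DoseReport:
    """Per-puff and session dose ledger (mg and ug; percents of inhaled dose)."""

    per_puff_dose: float  # mg
    absorbed_per_puff: float  # mg
    exhaled_per_puff: float  # mg
    lung_or_remaining_per_puff: float  # mg
    session_emission: float  # mg
    bystander_inhaled_per_puff: float  # ug
    bystander_dermal_per_puff: float  # ug
    overall_inhaled_frac: float  # % of inhaled dose
    overall_dermal_frac: float  # % of inhaled dose
    rounding: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def to_text(self) -> str:
        return (
            f"per-puff inhaled dose      : {self.per_puff_dose:g} mg\n"
            f"absorbed (respiratory)     : {self.absorbed_per_puff:g} mg\n"
            f"to lungs / remaining       : {self.lung_or_remaining_per_puff:g} mg\n"
            f"exhaled to room            : {self.exhaled_per_puff:g} mg\n"
            f"session emission           : {self.session_emission:g} mg\n"
            f"bystander inhaled per puff : {self.bystander_inhaled_per_puff:g} ug"
            f" ({self.overall_inhaled_frac:g}% of inhaled dose)\n"
            f"bystander dermal per puff  : {self.bystander_dermal_per_puff:g} ug"
            f" ({self.overall_dermal_frac:g}% of inhaled dose)\n"
        )


def per_puff_dose(oil_mass: float, thc_mass_fraction: float, puffs_per_fill: int) -> float:
    """Inhaled THC per puff in mg: oil(g) x fraction / puffs x 1000."""
    if oil_mass <= 0 or thc_mass_fraction <= 0 or puffs_per_fill <= 0:
        raise InvalidArgumentError("per_puff_dose arguments must be positive")
    return oil_mass * thc_mass_fraction / puffs_per_fill * 1000.0


def session_emission(exhaled_per_puff: float, puffs: int) -> float:
    """Exhaled mass over a session, mg."""
    if exhaled_per_puff < 0 or puffs < 0:
        raise InvalidArgumentError("session_emission arguments must be non-negative")
    return exhaled_per_puff * puffs


def dose_chain(inputs: DoseChainInputs, rounding: str = "paper_sigfigs") -> DoseReport:
    """Run the full first-to-secondhand multiplicative dose chain."""
    if rounding not in ("paper_sigfigs", "full_precision"):
        raise InvalidArgumentError(f"unknown rounding mode {rounding!r}")
    b = inputs.budget
    dose = per_puff_dose(inputs.oil_mass, inputs.thc_mass_fraction, inputs.puffs_per_fill)

    absorbed = dose * b.absorbed_frac / 100.0
    exhaled = dose * b.exhaled_frac / 100.0
    lung_rem = dose * (b.remaining_frac + b.to_lung_frac) / 100.0
    overall_in = b.exhaled_frac * inputs.secondhand_inhaled_frac_of_exhaled / 100.0
    overall_derm = b.exhaled_frac * inputs.secondhand_dermal_frac_of_exhaled / 100.0

    if rounding == "paper_sigfigs":
        absorbed = round_sig(absorbed, 2)
        lung_rem = round_sig(lung_rem, 2)
        exhaled = round_sig(exhaled, 1)
        overall_in = round(overall_in, 2)
        overall_derm = round(overall_derm, 2)
        bystander_in = round_sig(dose * 1000.0 * overall_in / 100.0, 2)
        bystander_derm = round_sig(dose * 1000.0 * overall_derm / 100.0, 2)
        session = round_sig(session_emission(exhaled, inputs.puffs_per_session), 2)
    else:
        bystander_in = dose * 1000.0 * overall_in / 100.0
        bystander_derm = dose * 1000.0 * overall_derm / 100.0
        session = session_emission(exhaled, inputs.puffs_per_session)

    return DoseReport(
        per_puff_dose=dose,
        absorbed_per_puff=absorbed,
        exhaled_per_puff=exhaled,
        lung_or_remaining_per_puff=lung_rem,
        session_emission=session,
        bystander_inhaled_per_puff=bystander_in,
        bystander_dermal_per_puff=bystander_derm,
        overall_inhaled_frac=overall_in,
        overall_dermal_frac=overall_derm,
        rounding=rounding,
    )


# ---------------------------------------------------------------------------
# Reference fixtures: per-puff budget fractions reported by the CT-geometry
# CFD study this package reduces.  They embed jet-impingement and geometry
# effects a 1-D model cannot reproduce, so they are shipped as data, not
# recomputed.
# ---------------------------------------------------------------------------

def post_puff_reference_budget(inhaled_mass: float = 1.0) -> ExposureBudget:
    """Post puff: 64.4% absorbed, 3.2% exhaled, 32.4% to lungs."""
    return ExposureBudget(64.4, 3.2, 0.0, 32.4, inhaled_mass)


def short_puff_reference_budget(inhaled_mass: float = 1.0) -> ExposureBudget:
    """Short puff: 84.1% absorbed, 6.6% exhaled, 9.3% remaining."""
    return ExposureBudget(84.1, 6.6, 9.3, 0.0, inhaled_mass)


def long_puff_reference_budget(inhaled_mass: float = 1.0) -> ExposureBudget:
    """Long puff: 85.0% absorbed, 6.6% exhaled, 8.4% remaining."""
    return ExposureBudget(85.0, 6.6, 8.4, 0.0, inhaled_mass)


def reference_dose_chain_inputs(
    budget: Optional[ExposureBudget] = None,
) -> DoseChainInputs:
    """The reference secondhand scenario: 0.5 g oil at 80%, 100 puffs/fill,
    20 puffs/session, bystander fractions 5.9% (inhaled) / 2.6% (dermal) of
    exhaled mass, post-puff budget by default."""
    return DoseChainInputs(
        oil_mass=0.5,
        thc_mass_fraction=0.80,
        puffs_per_fill=100,
        puffs_per_session=20,
        budget=budget if budget is not None else post_puff_reference_budget(),
        secondhand_inhaled_frac_of_exhaled=5.9,
        secondhand_dermal_frac_of_exhaled=2.6,
    )
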