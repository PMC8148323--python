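"""Physicochemical property sets for vapor-phase species.

All transport and uptake physics in the package is parameterized by a
:class:`ChemicalSpecies` record: a gas-phase diffusivity, per-layer
condensed-phase diffusivities, and the air/liquid partition coefficients
that drive solubility-limited wall uptake.  Internal units are strictly SI
(m, s, kg, mol); masses are converted to mg/µg only at the reporting layer.

Default THC and nicotine records are estimation-based (Fuller-style gas
diffusivity plus documented literature-style assumptions for the condensed
phases) and every field is overridable through the scenario config.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

from .errors import InvalidArgumentError

__all__ = [
    "ChemicalSpecies",
    "estimate_gas_diffusivity",
    "thc_defaults",
    "nicotine_defaults",
]

#: Fuller atomic diffusion volume of air (cm^3/mol) and molar mass of air (g/mol).
_AIR_DIFFUSION_VOLUME = 20.1
_AIR_MOLAR_MASS = 28.97

_ATM_PA = 101325.0


@dataclass
class ChemicalSpecies:
    """A vapor-phase chemical with the transport properties the solvers need.

    Parameters
    ----------
    name
        Species label.
    molar_mass
        g/mol.
    D_air
        Gas-phase binary diffusivity in air, m^2/s.
    D_layer
        Map of layer name -> condensed-phase diffusivity, m^2/s. Layer names
        must cover every tissue/skin layer a scenario references
        (``mucus``, ``epithelium``, ``subepithelium``, ``stratum_corneum``,
        ``viable_epidermis``, ...).
    K_mucus_air
        Dimensionless mucus:air equilibrium partition coefficient.
    K_skin_air
        Dimensionless outer-skin:air partition coefficient.
    gas_film_coeff
        Optional gas-side mass-transfer coefficient override, m/s. When None
        the solvers derive one from a Sherwood-number correlation.
    """

    name: str
    molar_mass: float
    D_air: float
    D_layer: dict[str, float] = field(default_factory=dict)
    K_mucus_air: float = 0.0
    K_skin_air: float = 0.0
    gas_film_coeff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise InvalidArgumentError(f"molar_mass must be positive, got {self.molar_mass}")
        if self.D_air <= 0:
            raise InvalidArgumentError(f"D_air must be positive, got {self.D_air}")
        for layer, d in self.D_layer.items():
            if d <= 0:
                raise InvalidArgumentError(f"D_layer[{layer!r}] must be positive, got {d}")
            if d >= self.D_air:
                raise InvalidArgumentError(
                    f"D_layer[{layer!r}]={d} must be smaller than D_air={self.D_air}: "
                    "condensed-phase diffusion is slower than gas-phase"
                )
        if self.K_mucus_air < 0 or self.K_skin_air < 0:
            raise InvalidArgumentError("partition coefficients must be non-negative")
        if self.gas_film_coeff is not None and self.gas_film_coeff <= 0:
            raise InvalidArgumentError("gas_film_coeff must be positive when given")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ChemicalSpecies":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "ChemicalSpecies":
        return cls.from_dict(json.loads(s))


def estimate_gas_diffusivity(
    molar_mass: float,
    molar_volume: float,
    temperature: float = 298.15,
    pressure: float = _ATM_PA,
) -> float:
    """Binary gas diffusivity in air from the Fuller correlation, m^2/s.

    ``molar_volume`` is the Fuller atomic diffusion volume of the diffusing
    species (cm^3/mol).  The correlation is monotone increasing in
    temperature (T^1.75) and monotone decreasing in molar mass and molar
    volume, which is all the downstream physics relies on.

    Parameters are SI except the conventional correlation inputs
    (g/mol, cm^3/mol).
    """
    if molar_mass <= 0 or molar_volume <= 0 or temperature <= 0 or pressure <= 0:
        raise InvalidArgumentError("all arguments to estimate_gas_diffusivity must be positive")
    p_atm = pressure / _ATM_PA
    m_term = math.sqrt(1.0 / molar_mass + 1.0 / _AIR_MOLAR_MASS)
    v_term = (molar_volume ** (1.0 / 3.0) + _AIR_DIFFUSION_VOLUME ** (1.0 / 3.0)) ** 2
    d_cm2_s = 1.0e-3 * temperature**1.75 * m_term / (p_atm * v_term)
    return d_cm2_s * 1.0e-4


#: Fuller diffusion volumes (cm^3/mol) assembled from atomic increments
#: (C 15.9, H 2.31, O 6.11, aromatic/heterocyclic N 4.54).
_THC_DIFFUSION_VOLUME = 21 * 15.9 + 30 * 2.31 + 2 * 6.11  # C21H30O2
_NICOTINE_DIFFUSION_VOLUME = 10 * 15.9 + 14 * 2.31 + 2 * 4.54  # C10H14N2


def thc_defaults() -> ChemicalSpecies:
    """Default THC property record.

    THC (C21H30O2, 314.5 g/mol) is highly lipophilic: the mucus:air
    partition coefficient is set in the same high-solubility band as
    nicotine's, which is what makes the absorbed fractions of the two
    species comparable.  Its condensed-phase diffusivities are set lower
    than nicotine's (it is a much larger molecule), which slows tissue
    penetration and raises the residual airway-surface burden.
    """
    return ChemicalSpecies(
        name="THC",
        molar_mass=314.5,
        D_air=estimate_gas_diffusivity(314.5, _THC_DIFFUSION_VOLUME),
        D_layer={
            "mucus": 3.0e-10,
            "epithelium": 1.0e-10,
            "subepithelium": 1.2e-10,
            "surface_lipid": 1.0e-11,
            "stratum_corneum": 1.0e-12,
            "viable_epidermis": 1.0e-10,
        },
        K_mucus_air=1.0e5,
        K_skin_air=1.0e6,
    )


def nicotine_defaults() -> ChemicalSpecies:
    """Default nicotine property record (comparison species).

    Nicotine (C10H14N2, 162.2 g/mol) diffuses faster than THC in both the
    gas and condensed phases; its air/liquid partitioning is likewise high
    (protonation in mucus makes it effectively non-volatile there).
    """
    return ChemicalSpecies(
        name="nicotine",
        molar_mass=162.23,
        D_air=estimate_gas_diffusivity(162.23, _NICOTINE_DIFFUSION_VOLUME),
        D_layer={
            "mucus": 6.0e-10,
            "epithelium": 2.5e-10,
            "subepithelium": 3.0e-10,
            "surface_lipid": 3.0e-11,
            "stratum_corneum": 3.0e-12,
            "viable_epidermis": 2.5e-10,
        },
        K_mucus_air=1.0e5,
        K_skin_air=1.0e5,
    )
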