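"""Transdermal uptake of vapor-phase THC at exposed skin.

Vapor is delivered to the skin through a gas-side boundary layer
(characterized by a deposition velocity, m/s) and then diffuses through
the skin layers — stratum corneum and viable epidermis by default — to a
perfused sink.  The solver is the same layered-diffusion column used for
the airway wall, re-parameterized: the first layer partitions against air
with ``K_skin_air``.

For a highly lipophilic vapor over short exposures the stratum corneum is
far from saturation and uptake is deposition-limited: absorbed mass tracks
``area * v_d * integral(C dt)``.  The default deposition velocity is
calibrated (scripts/calibrate_secondhand.py) so the default post-puff
near-field scenario absorbs 2.6% of the emitted mass through the face.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .airway_tissue import (
    TissueColumn,
    TissueLayer,
    TissueStack,
    _coerce_series,
    _resolve_layers,
)
from .chem_props import ChemicalSpecies
from .errors import InvalidArgumentError

__all__ = [
    "SkinStack",
    "default_skin_stack",
    "simulate_dermal",
    "steady_dermal_flux",
    "DermalResult",
]

#: Gas-side deposition velocity (m/s) calibrated so the default secondhand
#: scenario absorbs 2.6% of emitted mass through the face; see
#: scripts/calibrate_secondhand.py.
CALIBRATED_DEPOSITION_VELOCITY = 1.853e-3
#: Documented calibration target: dermal fraction of emitted mass.
DERMAL_FRACTION_TARGET = 0.026

#: Exposed face area, m^2 (short-range plume scenario).
DEFAULT_FACE_AREA = 0.025


@dataclass
class SkinStack:
    """Skin layer stack plus the gas-side delivery parameters."""

    layers: Sequence[TissueLayer]
    exposed_area: float = DEFAULT_FACE_AREA
    deposition_velocity: float = CALIBRATED_DEPOSITION_VELOCITY
    base_condition: str = "perfect_sink"
    grid_points_per_layer: int = 40

    def __post_init__(self) -> None:
        if self.exposed_area <= 0:
            raise InvalidArgumentError("exposed_area must be positive")
        if self.deposition_velocity <= 0:
            raise InvalidArgumentError("deposition_velocity must be positive")

    def as_tissue_stack(self) -> TissueStack:
        return TissueStack(
            layers=list(self.layers),
            base_condition=self.base_condition,
            grid_points_per_layer=self.grid_points_per_layer,
        )


def default_skin_stack(**overrides) -> SkinStack:
    """Stratum corneum (20 um) over viable epidermis (100 um)."""
    return SkinStack(
        layers=[
            TissueLayer("stratum_corneum", 20e-6),
            TissueLayer("viable_epidermis", 100e-6, partition_vs_previous=0.1),
        ],
        **overrides,
    )


@dataclass
class DermalResult:
    """Cumulative dermal absorption over the exposure window."""

    times: np.ndarray
    absorbed_cumulative: np.ndarray  # kg, over the whole exposed area
    flux: np.ndarray  # kg/(m^2 s)

    @property
    def absorbed_mass(self) -> float:
        return float(self.absorbed_cumulative[-1])


def simulate_dermal(
    skin: SkinStack,
    species: ChemicalSpecies,
    C_air_series,
    window: Optional[float] = None,
    dt: float = 0.005,
) -> DermalResult:
    """Integrate skin uptake under a time-varying air concentration.

    ``absorbed_cumulative`` is exposed_area times the cumulative surface
    flux and can never exceed the delivery bound
    ``exposed_area * v_d * integral(C dt)``.
    """
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    t_in, c_in = _coerce_series(C_air_series)
    t_end = window if window is not None else float(t_in[-1])
    if t_end <= 0:
        raise InvalidArgumentError("window must be positive")
    n = max(int(round(t_end / dt)), 1)
    col = TissueColumn(
        skin.as_tissue_stack(),
        species,
        dt,
        gas_film_coeff=skin.deposition_velocity,
        first_partition=species.K_skin_air,
    )
    times = np.zeros(n + 1)
    flux = np.zeros(n + 1)
    absorbed = np.zeros(n + 1)
    for k in range(1, n + 1):
        t = k * dt
        c = float(np.interp(t, t_in, c_in, left=0.0, right=0.0))
        flux[k] = col.step(c)
        times[k] = t
        absorbed[k] = col.cumulative_uptake * skin.exposed_area
    return DermalResult(times=times, absorbed_cumulative=absorbed, flux=flux)


def steady_dermal_flux(
    skin: SkinStack, species: ChemicalSpecies, C_air: float
) -> float:
    """Series-resistance steady flux: gas film + skin layers to the sink."""
    if C_air < 0:
        raise InvalidArgumentError("C_air must be non-negative")
    L, D, Kc = _resolve_layers(
        skin.as_tissue_stack(), species, first_partition=species.K_skin_air
    )
    if np.any(Kc == 0.0):
        return 0.0
    r = 1.0 / skin.deposition_velocity + float(np.sum(L / (D * Kc)))
    return C_air / r
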