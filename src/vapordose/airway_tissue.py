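"""Layered air–mucus–tissue–blood (AMTB) wall-uptake solver.

The airway wall is modeled as an ordered stack of diffusive layers
(mucus, epithelium, sub-epithelium) over a perfectly perfused blood sink.
Vapor in the lumen partitions into the mucus across a gas-side boundary
film and then diffuses through the stack; the blood compartment holds the
base concentration at zero.

Numerics
--------
The solver works in the *gas-equivalent* concentration
``psi(x) = C(x) / K_cum(x)``, where ``K_cum`` is the cumulative partition
coefficient of the layer relative to air.  In this variable the interface
condition between layers is plain continuity, the layer "conductivity" is
``kappa = D * K_cum`` and the volumetric capacity is ``K_cum``; the
double-film air/mucus boundary collapses to a Robin condition
``flux = k_g * (C_air - psi_surface)``.  Time stepping is implicit Euler
on a cell-centered finite-volume grid (harmonic-mean face conductances),
which is unconditionally stable and conserves mass to machine precision:
the discrete uptake, tissue inventory and sink outflow close exactly by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .chem_props import ChemicalSpecies
from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "TissueLayer",
    "TissueStack",
    "WallFluxResult",
    "TissueColumn",
    "interface_values",
    "solve_tissue_diffusion",
    "equilibrium_capacity",
    "series_resistance_flux",
    "default_airway_stack",
]


@dataclass
class TissueLayer:
    """One diffusive layer of an airway-wall or skin stack.

    ``diffusivity`` (m^2/s) and ``partition_vs_previous`` (equilibrium
    concentration ratio to the adjacent outer phase) may be left None, in
    which case they are resolved from the species record: the diffusivity
    from ``species.D_layer[name]``, and the first layer's partition from
    ``species.K_mucus_air`` (deeper layers default to 1, i.e. the same
    solubility as the layer above).
    """

    name: str
    thickness: float
    diffusivity: Optional[float] = None
    partition_vs_previous: Optional[float] = None

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InvalidArgumentError(f"layer {self.name!r}: thickness must be positive")
        if self.diffusivity is not None and self.diffusivity <= 0:
            raise InvalidArgumentError(f"layer {self.name!r}: diffusivity must be positive")
        if self.partition_vs_previous is not None and self.partition_vs_previous <= 0:
            raise InvalidArgumentError(f"layer {self.name!r}: partition must be positive")


@dataclass
class TissueStack:
    """An ordered stack of layers over a base boundary condition."""

    layers: Sequence[TissueLayer]
    base_condition: str = "perfect_sink"  # or "no_flux"
    grid_points_per_layer: int = 40

    def __post_init__(self) -> None:
        if not self.layers:
            raise InvalidArgumentError("a stack needs at least one layer")
        if self.base_condition not in ("perfect_sink", "no_flux"):
            raise InvalidArgumentError(f"unknown base_condition {self.base_condition!r}")
        if self.grid_points_per_layer < 3:
            raise ConfigurationError(
                "grid_points_per_layer must be >= 3 to resolve each layer"
            )

    @property
    def total_thickness(self) -> float:
        return sum(l.thickness for l in self.layers)


@dataclass
class WallFluxResult:
    """Transient wall-uptake solution.

    ``flux`` is kg/(m^2 s) into the tissue; ``cumulative_uptake`` its time
    integral (kg/m^2).  ``layer_profiles`` holds the *physical*
    concentration C (kg/m^3) on the spatial grid ``x`` at each saved time.
    """

    times: np.ndarray
    flux: np.ndarray
    cumulative_uptake: np.ndarray
    x: np.ndarray
    layer_profiles: np.ndarray
    profile_times: np.ndarray
    tissue_inventory: float
    sink_outflow: float

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.times,
                "flux_kg_m2_s": self.flux,
                "cumulative_kg_m2": self.cumulative_uptake,
            }
        ).to_csv(path, index=False)


def interface_values(
    C_air_bulk: float,
    gas_film_coeff: float,
    liquid_film_coeff: float,
    K: float,
    C_liquid_bulk: float = 0.0,
) -> tuple[float, float, float]:
    """Double-film air/liquid interface state under flux conservation.

    A gas-side film (coefficient ``k_g``) and a liquid-side film (``k_l``)
    meet at an interface in local equilibrium, ``C_liquid_surface = K *
    C_air_wall``.  Equating the two film fluxes gives the two-resistance
    flux ``(C_air_bulk - C_liquid_bulk / K) / (1/k_g + 1/(K k_l))``.

    Returns ``(C_air_wall, C_liquid_surface, flux)`` with flux positive
    into the liquid.  ``K = 0`` is the insoluble limit: zero flux with the
    wall concentration equal to the bulk.
    """
    if gas_film_coeff <= 0 or liquid_film_coeff <= 0:
        raise InvalidArgumentError("film coefficients must be positive")
    if K < 0:
        raise InvalidArgumentError("partition coefficient must be non-negative")
    if C_air_bulk < 0:
        raise InvalidArgumentError("bulk air concentration must be non-negative")
    if K == 0.0:
        return C_air_bulk, 0.0, 0.0
    resistance = 1.0 / gas_film_coeff + 1.0 / (K * liquid_film_coeff)
    flux = (C_air_bulk - C_liquid_bulk / K) / resistance
    C_air_wall = C_air_bulk - flux / gas_film_coeff
    return C_air_wall, K * C_air_wall, flux


def _resolve_layers(
    stack: TissueStack, species: ChemicalSpecies, first_partition: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-layer (thickness, diffusivity, cumulative partition vs air)."""
    L, D, Kc = [], [], []
    k_cum = 1.0
    for i, layer in enumerate(stack.layers):
        d = layer.diffusivity
        if d is None:
            if layer.name not in species.D_layer:
                raise ConfigurationError(
                    f"species {species.name!r} has no diffusivity for layer {layer.name!r}"
                )
            d = species.D_layer[layer.name]
        p = layer.partition_vs_previous
        if p is None:
            if i == 0:
                p = first_partition if first_partition is not None else species.K_mucus_air
            else:
                p = 1.0
        k_cum *= p
        L.append(layer.thickness)
        D.append(d)
        Kc.append(k_cum)
    return np.array(L), np.array(D), np.array(Kc)


class TissueColumn:
    """Stateful implicit-Euler integrator for one wall column.

    Used directly by the airway-transport and dermal modules so that the
    lumen/room coupling and the standalone solver share one discretization.
    The tridiagonal system matrix depends only on (stack, species, dt) and
    is assembled once; each :meth:`step` is a single banded solve.
    """

    def __init__(
        self,
        stack: TissueStack,
        species: ChemicalSpecies,
        dt: float,
        gas_film_coeff: Optional[float] = None,
        first_partition: Optional[float] = None,
    ) -> None:
        if dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        self.stack = stack
        self.species = species
        self.dt = dt
        L, D, Kc = _resolve_layers(stack, species, first_partition)
        self.insoluble = bool(np.all(Kc == 0.0))
        n = stack.grid_points_per_layer
        dx = np.repeat(L / n, n)
        kappa = np.repeat(D * Kc, n)  # conductivity in psi
        cap = np.repeat(Kc, n)  # capacity per volume in psi
        self.n_cells = len(dx)
        self.dx = dx
        self.cap_vol = cap * dx  # kg/m^2 per unit psi
        edges = np.concatenate([[0.0], np.cumsum(dx)])
        self.x = 0.5 * (edges[:-1] + edges[1:])

        k_g = gas_film_coeff if gas_film_coeff is not None else species.gas_film_coeff
        if k_g is not None and k_g <= 0:
            raise InvalidArgumentError("gas_film_coeff must be positive")
        self.k_g = k_g

        if self.insoluble:
            self.psi = np.zeros(self.n_cells)
            self.cumulative_uptake = 0.0
            self.sink_outflow = 0.0
            self.last_flux = 0.0
            return

        # Face conductances (per unit area): interior faces by series
        # (harmonic-mean) combination of adjacent half-cells.
        g_int = 1.0 / (dx[:-1] / (2 * kappa[:-1]) + dx[1:] / (2 * kappa[1:]))
        r_top = dx[0] / (2 * kappa[0])
        if k_g is not None:
            r_top += 1.0 / k_g
        self.g_top = 1.0 / r_top
        self.g_bot = (
            2 * kappa[-1] / dx[-1] if stack.base_condition == "perfect_sink" else 0.0
        )

        # Implicit Euler: (cap_vol/dt + G) psi^{n+1} = cap_vol/dt psi^n + g_top C_air
        nc = self.n_cells
        diag = self.cap_vol / dt
        lower = np.zeros(nc)
        upper = np.zeros(nc)
        diag = diag.copy()
        diag[:-1] += g_int
        diag[1:] += g_int
        diag[0] += self.g_top
        diag[-1] += self.g_bot
        upper[1:] = -g_int  # superdiagonal, banded storage
        lower[:-1] = -g_int  # subdiagonal
        self._ab = np.vstack([upper, diag, lower])
        self.psi = np.zeros(nc)
        self.cumulative_uptake = 0.0
        self.sink_outflow = 0.0
        self.last_flux = 0.0

    def step(self, C_air: float) -> float:
        """Advance one dt with the given bulk air concentration.

        Returns the surface flux (kg/m^2/s, positive into tissue) at the
        new time level; cumulative bookkeeping uses flux*dt so that uptake,
        inventory and sink outflow close to machine precision.
        """
        if self.insoluble:
            return 0.0
        rhs = self.cap_vol / self.dt * self.psi
        rhs[0] += self.g_top * C_air
        self.psi = solve_banded((1, 1), self._ab, rhs)
        flux = self.g_top * (C_air - self.psi[0])
        out = self.g_bot * self.psi[-1]
        self.cumulative_uptake += flux * self.dt
        self.sink_outflow += out * self.dt
        self.last_flux = flux
        return flux

    def snapshot_state(self):
        return (self.psi.copy(), self.cumulative_uptake, self.sink_outflow, self.last_flux)

    def restore_state(self, state) -> None:
        self.psi, self.cumulative_uptake, self.sink_outflow, self.last_flux = (
            state[0].copy(),
            state[1],
            state[2],
            state[3],
        )

    @property
    def inventory(self) -> float:
        """Tissue-phase mass per unit area, kg/m^2."""
        return float(np.dot(self.cap_vol, self.psi))

    @property
    def surface_gas_equivalent(self) -> float:
        """psi at the first cell (gas-equivalent surface concentration)."""
        return float(self.psi[0])

    def concentration_profile(self) -> np.ndarray:
        """Physical concentration C = K_cum * psi on the cell grid."""
        return self.psi * (self.cap_vol / self.dx)


def _coerce_series(series) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(series, "times"):
        t = np.asarray(series.times, dtype=float)
        v = np.asarray(getattr(series, "values", getattr(series, "flow", None)), dtype=float)
    else:
        t, v = series
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise InvalidArgumentError("concentration series must be non-negative")
    return t, v


def solve_tissue_diffusion(
    stack: TissueStack,
    species: ChemicalSpecies,
    C_air_series,
    dt: float,
    gas_film_coeff: Optional[float] = None,
    n_profile_saves: int = 20,
) -> WallFluxResult:
    """Integrate the layered-diffusion system under a time-varying exposure.

    ``C_air_series`` is either a ``(times, values)`` pair or any object
    with ``times`` and ``values``/``flow`` attributes; it is linearly
    interpolated onto the implicit time grid.  When no gas-side film
    coefficient is available the air/mucus boundary is treated as locally
    equilibrated (no gas-side resistance).
    """
    t_in, c_in = _coerce_series(C_air_series)
    t_end = t_in[-1]
    n_steps = max(int(round(t_end / dt)), 1)
    col = TissueColumn(stack, species, dt, gas_film_coeff=gas_film_coeff)

    times = np.zeros(n_steps + 1)
    flux = np.zeros(n_steps + 1)
    cum = np.zeros(n_steps + 1)
    save_stride = max(n_steps // max(n_profile_saves, 1), 1)
    profiles = [col.concentration_profile()]
    profile_times = [0.0]
    for k in range(1, n_steps + 1):
        t = k * dt
        c_air = float(np.interp(t, t_in, c_in))
        f = col.step(c_air)
        times[k] = t
        flux[k] = f
        cum[k] = col.cumulative_uptake
        if k % save_stride == 0 or k == n_steps:
            profiles.append(col.concentration_profile())
            profile_times.append(t)
    return WallFluxResult(
        times=times,
        flux=flux,
        cumulative_uptake=cum,
        x=col.x,
        layer_profiles=np.array(profiles),
        profile_times=np.array(profile_times),
        tissue_inventory=col.inventory,
        sink_outflow=col.sink_outflow,
    )


def equilibrium_capacity(
    stack: TissueStack, species: ChemicalSpecies, C_air: float
) -> float:
    """Total tissue loading (kg/m^2) at equilibrium with air at ``C_air``."""
    if C_air < 0:
        raise InvalidArgumentError("C_air must be non-negative")
    L, _, Kc = _resolve_layers(stack, species)
    return float(np.sum(L * Kc) * C_air)


def series_resistance_flux(
    stack: TissueStack,
    species: ChemicalSpecies,
    C_air: float,
    gas_film_coeff: Optional[float] = None,
) -> float:
    """Steady flux through the stack with a sink base: resistor network.

    Resistance of layer i is ``L_i / (D_i K_cum,i)`` in the gas-equivalent
    variable, plus ``1/k_g`` for the gas film when present.
    """
    L, D, Kc = _resolve_layers(stack, species)
    if np.any(Kc == 0.0):
        return 0.0
    r = float(np.sum(L / (D * Kc)))
    if gas_film_coeff is None:
        gas_film_coeff = species.gas_film_coeff
    if gas_film_coeff is not None:
        r += 1.0 / gas_film_coeff
    return C_air / r


#: Airway-wall layer thicknesses: mucus O(10 um), epithelium O(50 um),
#: sub-epithelium O(100 um).
def default_airway_stack(grid_points_per_layer: int = 40) -> TissueStack:
    return TissueStack(
        layers=[
            TissueLayer("mucus", 10e-6),
            TissueLayer("epithelium", 50e-6),
            TissueLayer("subepithelium", 100e-6),
        ],
        base_condition="perfect_sink",
        grid_points_per_layer=grid_points_per_layer,
    )
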