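"""Reduced-order vapor transport through a segmented airway path.

The respiratory tract is lumped into a single serial path — oral cavity,
oropharynx, larynx, trachea and symmetric bronchial generations 1–4 — with
per-segment length, total cross-section and wetted perimeter.  A puff
waveform drives 1-D advection (flux-limited upwind finite volume, CFL
sub-stepped) plus a configurable axial dispersion that stands in for the
secondary flows and turbulence a 3-D simulation would resolve.  Each
segment owns a layered AMTB wall column (``airway_tissue.TissueColumn``)
driven by the segment-mean lumen concentration; whatever the column takes
up is removed from the lumen, so the four-way mass ledger — absorbed,
exhaled, remaining in the tract, transported past the distal boundary
toward the lungs — closes to machine precision.

Mass past the distal boundary enters a well-mixed distal reservoir; during
exhalation the reservoir supplies the returning flow, so part of the
deep-lung mass can be re-exhaled (this is what differentiates the fast,
deep post puff from the shallow short/long puffs).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .airway_tissue import TissueColumn, TissueStack, default_airway_stack
from .chem_props import ChemicalSpecies
from .errors import ConfigurationError, InvalidArgumentError, UndefinedBudgetError
from .puff_profiles import FlowWaveform

__all__ = [
    "AirwaySegment",
    "AirwayResult",
    "ExposureBudget",
    "build_airway_tree",
    "default_tree",
    "simulate_puff",
    "budget",
    "gas_film_from_sherwood",
]

logger = logging.getLogger(__name__)

SEGMENT_ORDER = (
    "oral_cavity",
    "oropharynx",
    "larynx",
    "trachea",
    "bronchi_G1",
    "bronchi_G2",
    "bronchi_G3",
    "bronchi_G4",
)


@dataclass
class AirwaySegment:
    """One lumped conduit segment of the mouth-to-distal path.

    ``cross_section`` and ``perimeter`` are totals over all parallel
    branches of a lumped bronchial generation.
    """

    name: str
    length: float
    cross_section: float
    perimeter: float
    tissue_stack_ref: str = "default"

    def __post_init__(self) -> None:
        if self.length <= 0 or self.cross_section <= 0 or self.perimeter <= 0:
            raise InvalidArgumentError(
                f"segment {self.name!r}: length, cross_section and perimeter must be positive"
            )

    @property
    def volume(self) -> float:
        return self.length * self.cross_section

    @property
    def hydraulic_diameter(self) -> float:
        return 4.0 * self.cross_section / self.perimeter

    def to_dict(self) -> dict:
        return asdict(self)


# Symmetric-generation airway dimensions: (length m, total cross-section m^2,
# total perimeter m).  Upper airway from typical adult cast volumes; bronchial
# generations from the classic symmetric morphometry (n = 2^g branches).
_DEFAULT_GEOMETRY = {
    "oral_cavity": (0.10, 5.0e-4, 7.93e-2),
    "oropharynx": (0.08, 2.4e-4, 5.49e-2),
    "larynx": (0.05, 1.5e-4, 4.34e-2),
    "trachea": (0.12, 2.54e-4, 5.65e-2),
    "bronchi_G1": (0.0476, 2.34e-4, 7.67e-2),
    "bronchi_G2": (0.0190, 2.16e-4, 1.043e-1),
    "bronchi_G3": (0.0076, 1.97e-4, 1.407e-1),
    "bronchi_G4": (0.0127, 2.54e-4, 2.262e-1),
}


def default_tree() -> list[AirwaySegment]:
    """Default mouth-to-generation-4 path (see module docstring)."""
    return [
        AirwaySegment(name, *_DEFAULT_GEOMETRY[name]) for name in SEGMENT_ORDER
    ]


def build_airway_tree(config: Optional[dict] = None) -> list[AirwaySegment]:
    """Build the segment path from a config mapping, or the defaults.

    ``config['segments']`` may list per-segment dicts (name, length,
    cross_section, perimeter); omitted when ``config`` is None or requests
    defaults.  The total dead-space volume is logged.
    """
    if config is None or config.get("defaults", config.get("segments") is None):
        tree = default_tree()
    else:
        try:
            tree = [AirwaySegment(**seg) for seg in config["segments"]]
        except TypeError as exc:
            raise ConfigurationError(f"malformed segment definition: {exc}") from exc
        if not tree:
            raise ConfigurationError("airway tree needs at least one segment")
    dead_space = sum(s.volume for s in tree)
    logger.info("airway path dead-space volume: %.1f mL", dead_space * 1e6)
    return tree


@dataclass
class ExposureBudget:
    """Four-way per-puff mass ledger, in percent of inhaled mass."""

    absorbed_frac: float
    exhaled_frac: float
    remaining_frac: float
    to_lung_frac: float
    inhaled_mass: float

    def __post_init__(self) -> None:
        fracs = (self.absorbed_frac, self.exhaled_frac, self.remaining_frac, self.to_lung_frac)
        for f in fracs:
            if not -1e-9 <= f <= 100.0 + 1e-9:
                raise InvalidArgumentError(f"budget fraction {f} outside [0, 100]")
        if abs(sum(fracs) - 100.0) > 0.1:
            raise InvalidArgumentError(
                f"budget fractions sum to {sum(fracs):.4f}, must close to 100 +/- 0.1"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class AirwayResult:
    """Transport solution and mass ledger for one puff-exhale maneuver."""

    times: np.ndarray
    segment_names: list[str]
    segment_concentrations: np.ndarray  # (n_saved, n_segments) mean kg/m^3
    wall_uptake_per_segment: np.ndarray  # kg
    exhaled_mass: float
    distal_outflow_mass: float
    resident_mass: float
    inhaled_mass: float
    exhaled_rate: np.ndarray  # kg/s at the mouth, per saved time
    dead_space_volume: float

    @property
    def absorbed_mass(self) -> float:
        return float(np.sum(self.wall_uptake_per_segment))

    def mouth_emission_series(self, rezero: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(times, kg/s) mass release rate at the mouth — the room-model input.

        With ``rezero`` (default) the clock restarts at the onset of
        exhalation, which is when the indoor-exposure window begins.
        """
        if not rezero or not np.any(self.exhaled_rate > 0):
            return self.times, self.exhaled_rate
        first = int(np.argmax(self.exhaled_rate > 0))
        i0 = max(first - 1, 0)
        return self.times[i0:] - self.times[i0], self.exhaled_rate[i0:]

    def segments_to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.segment_concentrations, columns=self.segment_names)
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False)


def gas_film_from_sherwood(
    segment: AirwaySegment,
    species: ChemicalSpecies,
    contact_time: float = 1.0,
) -> float:
    """Gas-side film coefficient for one segment, m/s.

    Two estimates are combined and the larger taken: (i) the fully
    developed laminar duct value, Sh = 3.66 on the segment hydraulic
    diameter; and (ii) penetration theory for transient diffusion to a
    fresh wall over the puff contact time, ``k = 2 sqrt(D / (pi t_c))``.
    A single puff is an entrance/impingement-dominated transient, so (i)
    alone badly underestimates uptake in the wide upper-airway segments;
    (ii) is the reduced-order stand-in for the near-wall boundary layers a
    3-D simulation would resolve.  Turbulence and secondary-flow mixing
    are lumped into the axial dispersion coefficient instead of the film.
    """
    k_duct = 3.66 * species.D_air / segment.hydraulic_diameter
    k_pen = 2.0 * math.sqrt(species.D_air / (math.pi * contact_time))
    return max(k_duct, k_pen)


def _limited_face_conc(c: np.ndarray, q: float, h: float, vol: np.ndarray) -> np.ndarray:
    """Interior-face concentrations for signed plug flow q (van Leer limiter).

    Second-order TVD reconstruction: face value is the upwind cell plus a
    limited anti-diffusive correction scaled by (1 - local Courant number).
    Falls back to first order where the second upwind neighbor is missing
    or the solution is non-monotone (limiter closes).
    """
    if q > 0:
        up, down = c[:-1], c[1:]
        upup = np.concatenate([[c[0]], c[:-2]])
        nu = q * h / vol[:-1]
    else:
        up, down = c[1:], c[:-1]
        upup = np.concatenate([c[2:], [c[-1]]])
        nu = -q * h / vol[1:]
    dc = down - up
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(dc != 0.0, (up - upup) / np.where(dc != 0.0, dc, 1.0), 0.0)
    phi = (r + np.abs(r)) / (1.0 + np.abs(r))
    return up + 0.5 * phi * np.maximum(1.0 - nu, 0.0) * dc


def _flow_function(puff_in: FlowWaveform, exhale: FlowWaveform, pause: float):
    """Total flow Q(t): puff, optional zero-flow hold, then exhalation."""
    t_in_end = puff_in.times[-1]
    t_ex_start = t_in_end + pause
    t_end = t_ex_start + exhale.times[-1]
    q_in = puff_in.interpolator()
    q_ex = exhale.interpolator()

    def q(t: float) -> float:
        if t <= t_in_end:
            return float(q_in(t))
        if t < t_ex_start:
            return 0.0
        return float(q_ex(t - t_ex_start))

    return q, t_end


def simulate_puff(
    tree: Sequence[AirwaySegment],
    species: ChemicalSpecies,
    puff_in: FlowWaveform,
    exhale: FlowWaveform,
    C_inlet: float,
    dt: float = 0.005,
    pause: float = 0.0,
    dispersion: float = 5e-4,
    distal_volume: float = 5e-4,
    tissue_stacks: Optional[dict[str, TissueStack]] = None,
    grid_points_per_layer: int = 12,
    dx_target: float = 0.01,
    allow_desorption: bool = False,
    cfl: float = 0.5,
) -> AirwayResult:
    """Advect a puff through the airway path with wall uptake per segment.

    Parameters of note: ``dispersion`` (m^2/s) is the lumped axial mixing
    coefficient; ``distal_volume`` (m^3) the well-mixed deep-lung reservoir
    that supplies returning flow during exhalation; ``dx_target`` the lumen
    cell size (each segment gets at least 4 cells).  Sub-steps are chosen
    automatically to satisfy the advective CFL and diffusive stability
    limits, so ``dt`` only sets the wall-coupling and output cadence.
    """
    if C_inlet < 0:
        raise InvalidArgumentError("C_inlet must be non-negative")
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    if puff_in.flow.min() < -1e-300:
        raise InvalidArgumentError("puff_in must be an inhalation (non-negative flow)")
    if exhale.flow.max() > 1e-300:
        raise InvalidArgumentError("exhale must be an exhalation (non-positive flow)")

    tree = list(tree)
    if tissue_stacks is None:
        tissue_stacks = {}
    default_stack = default_airway_stack(grid_points_per_layer)

    # Lumen grid
    seg_cells, cell_area, cell_dx, cell_seg = [], [], [], []
    for i, seg in enumerate(tree):
        n = max(int(round(seg.length / dx_target)), 4)
        seg_cells.append(n)
        cell_area += [seg.cross_section] * n
        cell_dx += [seg.length / n] * n
        cell_seg += [i] * n
    area = np.array(cell_area)
    dx = np.array(cell_dx)
    vol = area * dx
    seg_of_cell = np.array(cell_seg)
    n_cells = len(vol)
    seg_slices = []
    start = 0
    for n in seg_cells:
        seg_slices.append(slice(start, start + n))
        start += n

    # Dispersion face conductances (m^3/s per unit concentration difference)
    a_face = 2.0 / (1.0 / area[:-1] + 1.0 / area[1:])
    d_face = dispersion * a_face / (0.5 * (dx[:-1] + dx[1:]))

    q_of_t, t_end = _flow_function(puff_in, exhale, pause)
    n_steps = int(math.ceil(t_end / dt))

    # One wall column per segment; film coefficient from the laminar
    # Sherwood / penetration-theory estimate unless the species overrides it.
    columns = []
    wall_area = []
    for seg in tree:
        stack = tissue_stacks.get(seg.tissue_stack_ref, default_stack)
        k_g = species.gas_film_coeff
        if k_g is None:
            k_g = gas_film_from_sherwood(seg, species)
        columns.append(TissueColumn(stack, species, dt, gas_film_coeff=k_g))
        wall_area.append(seg.perimeter * seg.length)
    wall_area = np.array(wall_area)

    m = np.zeros(n_cells)  # lumen mass per cell, kg
    m_distal = 0.0
    inhaled = 0.0
    exhaled = 0.0
    uptake_seg = np.zeros(len(tree))
    cfl_warned = False

    times = np.zeros(n_steps + 1)
    seg_conc = np.zeros((n_steps + 1, len(tree)))
    exh_rate = np.zeros(n_steps + 1)

    for k in range(1, n_steps + 1):
        t0, t1 = min((k - 1) * dt, t_end), min(k * dt, t_end)
        if t1 - t0 <= 1e-12:  # degenerate trailing step from dt rounding
            times[k] = t1
            seg_conc[k] = seg_conc[k - 1]
            continue
        # --- advection + dispersion, sub-stepped ---
        q_abs = max(abs(q_of_t(t0)), abs(q_of_t(0.5 * (t0 + t1))), abs(q_of_t(t1)))
        u_max = q_abs / area.min()
        # Positivity bound per cell: outflow |q| plus both dispersive face
        # conductances must not drain more than the cell holds in one sub-step.
        out_coef = np.full(n_cells, q_abs)
        out_coef[:-1] += d_face
        out_coef[1:] += d_face
        dt_stab = cfl * float(np.min(vol / np.maximum(out_coef, 1e-300)))
        n_sub = max(int(math.ceil((t1 - t0) / min(dt_stab, t1 - t0))), 1)
        if n_sub > 1 and u_max * (t1 - t0) / dx.min() > 1.0 and not cfl_warned:
            logger.warning(
                "advective CFL exceeds 1 at dt=%.3g s; sub-stepping by %d", dt, n_sub
            )
            cfl_warned = True
        h = (t1 - t0) / n_sub
        for j in range(n_sub):
            ts = t0 + (j + 0.5) * h
            q = q_of_t(ts)
            c = m / vol
            dm = np.zeros(n_cells)
            if q != 0.0:
                # signed face fluxes in the mouth->distal direction
                F = np.empty(n_cells + 1)
                F[1:-1] = q * _limited_face_conc(c, q, h, vol)
                if q > 0:
                    F[0] = q * C_inlet
                    F[-1] = q * c[-1]
                    inhaled += F[0] * h
                else:
                    c_res = m_distal / distal_volume if distal_volume > 0 else 0.0
                    F[0] = q * c[0]
                    F[-1] = q * c_res
                    exhaled += -F[0] * h
                m_distal += F[-1] * h
                dm += (F[:-1] - F[1:]) * h
            if dispersion > 0:
                jdif = d_face * (c[:-1] - c[1:])  # kg/s toward distal
                dm[:-1] -= jdif * h
                dm[1:] += jdif * h
            m += dm
        # --- wall uptake, one implicit tissue step per segment ---
        for i, (col, sl) in enumerate(zip(columns, seg_slices)):
            m_seg = float(np.sum(m[sl]))
            v_seg = float(np.sum(vol[sl]))
            c_mean = m_seg / v_seg
            if col.insoluble:
                continue
            state = col.snapshot_state()
            flux = col.step(c_mean)
            if flux < 0 and not allow_desorption:
                col.restore_state(state)
                continue
            dm_up = flux * wall_area[i] * dt
            if m_seg > 0 and dm_up > 0:
                dm_up = min(dm_up, m_seg)
                m[sl] -= m[sl] * (dm_up / m_seg)
            elif dm_up > 0:
                # nothing in the lumen to take; revert the column step
                col.restore_state(state)
                continue
            uptake_seg[i] += dm_up

        times[k] = t1
        q_now = q_of_t(t1)
        exh_rate[k] = -q_now * (m[0] / vol[0]) if q_now < 0 else 0.0
        for i, sl in enumerate(seg_slices):
            seg_conc[k, i] = np.sum(m[sl]) / np.sum(vol[sl])

    return AirwayResult(
        times=times,
        segment_names=[s.name for s in tree],
        segment_concentrations=seg_conc,
        wall_uptake_per_segment=uptake_seg,
        exhaled_mass=exhaled,
        distal_outflow_mass=m_distal,
        resident_mass=float(np.sum(m)),
        inhaled_mass=inhaled,
        exhaled_rate=exh_rate,
        dead_space_volume=float(np.sum(vol)),
    )


def budget(result: AirwayResult) -> ExposureBudget:
    """Convert an AirwayResult mass ledger to percent-of-inhaled fractions."""
    if result.inhaled_mass <= 0:
        raise UndefinedBudgetError("inhaled mass is zero; budget undefined")
    s = 100.0 / result.inhaled_mass
    return ExposureBudget(
        absorbed_frac=result.absorbed_mass * s,
        exhaled_frac=result.exhaled_mass * s,
        remaining_frac=result.resident_mass * s,
        to_lung_frac=result.distal_outflow_mass * s,
        inhaled_mass=result.inhaled_mass,
    )
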