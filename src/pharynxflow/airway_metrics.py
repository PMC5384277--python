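"""Outcome parameters: per-millimetre slice sweep, areas, volumes,
pressure drops, resistances, and extremum locations.

All slice quantities are area-weighted averages over the cross-section,
using the axisymmetric ring weights. Reported pressures are hydrostatic-
corrected by default when the solve included gravity, so pressure-drop
metrics reflect flow resistance only.

On resistance: the source formula is printed as R = Q/dP, but the
accompanying statement that the pressure drop tracks the resistance only
holds for R = dP/Q; that form is computed here and the discrepancy is
recorded in the output metadata (see ``AirwayMetrics.notes``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from pharynxflow.meshing import AxiGrid
from pharynxflow.flow_solver import FlowField
from pharynxflow.synthetic_anatomy import AirwayPhantom, REGION_NAMES
from pharynxflow.units import MM_TO_M, M2_TO_CM2

RESISTANCE_NOTE = (
    "resistance computed as dP/Q (Pa per mL/s); the printed form Q/dP is "
    "inconsistent with dP tracking resistance at constant Q"
)


@dataclass(frozen=True)
class SliceProfile:
    """One axial station: geometry + area-weighted flow averages."""

    z: float  # mm from choana
    area: float  # cm^2
    mean_pressure: float  # Pa
    mean_velocity: float  # m/s, speed


def _interp_extrap(z_m: float, zc: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Linear interpolation in z with linear end extrapolation.

    Slices at the domain planes sit half a cell outside the cell-centre
    range; clamping there would bias boundary-slice averages by half a
    cell's gradient (visible e.g. as a spurious hydrostatic residual).
    """
    if z_m <= zc[0]:
        slope = (col[1] - col[0]) / (zc[1] - zc[0])
        return col[0] + slope * (z_m - zc[0])
    if z_m >= zc[-1]:
        slope = (col[-1] - col[-2]) / (zc[-1] - zc[-2])
        return col[-1] + slope * (z_m - zc[-1])
    return np.interp(z_m, zc, col)


def _slice_ring_values(grid: AxiGrid, fld: FlowField, z_m: float):
    """Interpolate p and speed ring profiles at an axial position (SI)."""
    zc = grid.z_centers
    p_ring = np.array([_interp_extrap(z_m, zc, fld.p[:, j]) for j in range(grid.nr)])
    uz_c = fld.cell_axial_velocity()
    ur_c = fld.cell_radial_velocity()
    uz_ring = np.array([_interp_extrap(z_m, zc, uz_c[:, j]) for j in range(grid.nr)])
    ur_ring = np.array([_interp_extrap(z_m, zc, ur_c[:, j]) for j in range(grid.nr)])
    speed = np.hypot(uz_ring, ur_ring)
    ring_w = grid.eta_faces[1:] ** 2 - grid.eta_faces[:-1] ** 2  # area fractions
    return p_ring, speed, ring_w


def probe_plane(grid: AxiGrid, fld: FlowField, z_mm: float) -> tuple[float, float]:
    """Area-weighted mean pressure (Pa) and mean speed (m/s) at a station."""
    z_m = (z_mm - grid.phantom.z[0]) * MM_TO_M
    p_ring, speed, w = _slice_ring_values(grid, fld, z_m)
    return float((p_ring * w).sum() / w.sum()), float((speed * w).sum() / w.sum())


def slice_sweep(
    phantom: AirwayPhantom,
    fld: FlowField,
    spacing: float = 1.0,
    hydrostatic_correction: bool = True,
    force: bool = False,
) -> list[SliceProfile]:
    """Extract per-millimetre slice profiles from choana to hypopharynx bottom.

    Parameters
    ----------
    spacing
        Slice spacing in mm (the study uses 1 mm).
    hydrostatic_correction
        Subtract the rho*g*z head when the field was solved with gravity,
        so mean pressures reflect flow resistance only.
    force
        Allow extraction from an unconverged field.
    """
    if not fld.converged and not force:
        raise ValueError("flow field did not converge; pass force=True to extract anyway")
    grid = fld.grid
    z0, z1 = float(phantom.z[0]), float(phantom.z[-1])
    stations = np.arange(z0, z1 + 0.5 * spacing, spacing)
    stations[-1] = min(stations[-1], z1)

    rho_g = fld.fluid.density * fld.fluid.gravity if fld.fluid.gravity_enabled else 0.0
    if not hydrostatic_correction:
        rho_g = 0.0

    ring_w = grid.eta_faces[1:] ** 2 - grid.eta_faces[:-1] ** 2
    profiles = []
    for z in stations:
        z_m = (z - z0) * MM_TO_M
        p_ring, speed, _ = _slice_ring_values(grid, fld, z_m)
        mp = float((p_ring * ring_w).sum() / ring_w.sum()) - rho_g * z_m
        mv = float((speed * ring_w).sum() / ring_w.sum())
        area_cm2 = float(phantom.area_at(z)) * 1e-2
        profiles.append(SliceProfile(z=float(z), area=area_cm2, mean_pressure=mp, mean_velocity=mv))
    return profiles


@dataclass(frozen=True)
class AirwayMetrics:
    """The study's outcome parameters for one airway."""

    v_total: float  # cm^3
    v_na: float
    v_or: float
    v_hy: float
    a_min: float  # cm^2
    a_min_z: float  # mm
    a_min_region: str
    a_mean: float  # cm^2, V/L
    a_ratio: float  # A_min / A_mean
    dp_max: float  # Pa, choana slice to A_min slice
    dp_na: float
    dp_or: float
    dp_hy: float
    r_na: float  # Pa per (mL/s)
    r_or: float
    r_hy: float
    min_pressure_z: float  # mm
    min_pressure_region: str
    max_velocity_z: float  # mm
    max_velocity_region: str
    q: float  # mL/s
    notes: tuple[str, ...] = (RESISTANCE_NOTE,)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["notes"] = list(self.notes)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _region_of(z: float, boundaries: tuple[float, float]) -> str:
    b1, b2 = boundaries
    if z < b1:
        return "nasopharynx"
    if z < b2:
        return "oropharynx"
    return "hypopharynx"


def compute_metrics(
    profiles: list[SliceProfile],
    boundaries: tuple[float, float],
    q_ml_s: float,
) -> AirwayMetrics:
    """Aggregate slice profiles into the outcome parameter set.

    ``dp_max`` is the mean pressure at the choana slice minus that at the
    A_min slice (floored at zero with a warning if negative); regional
    drops are max - min of the slice mean pressure within each region; the
    A_min tie-break is the most superior slice.
    """
    if q_ml_s < 0:
        raise ValueError("flow rate must be >= 0")
    z = np.array([s.z for s in profiles])
    area = np.array([s.area for s in profiles])
    pres = np.array([s.mean_pressure for s in profiles])
    vel = np.array([s.mean_velocity for s in profiles])
    b1, b2 = boundaries
    if z.min() >= b1 or z.max() <= b2:
        raise ValueError("slice profiles must cover all three regions")

    region_masks = {
        "nasopharynx": z <= b1,
        "oropharynx": (z >= b1) & (z <= b2),
        "hypopharynx": z >= b2,
    }
    # region volumes via the cumulative integral evaluated exactly at the
    # boundary planes (the planes rarely fall on whole-millimetre slices)
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (area[1:] + area[:-1]) * np.diff(z)) * 1e-1]
    )  # cm^2 * mm -> cm^3
    at = np.interp([z[0], b1, b2, z[-1]], z, cum)
    vols = {
        "nasopharynx": float(at[1] - at[0]),
        "oropharynx": float(at[2] - at[1]),
        "hypopharynx": float(at[3] - at[2]),
    }
    v_total = float(at[3] - at[0])
    length = float(z[-1] - z[0])
    a_mean = v_total * 1e3 / length * 1e-2

    i_min = int(np.argmin(area))  # argmin returns the first (most superior) tie
    a_min = float(area[i_min])
    a_min_z = float(z[i_min])

    dp_max = float(pres[0] - pres[i_min])
    if dp_max < 0:
        warnings.warn(f"dp_max negative ({dp_max:.3g} Pa); flooring at 0", stacklevel=2)
        dp_max = 0.0

    dps = {}
    for name, m in region_masks.items():
        dps[name] = float(pres[m].max() - pres[m].min()) if m.any() else 0.0

    def resistance(dp: float) -> float:
        return dp / q_ml_s if q_ml_s > 0 else 0.0

    i_pmin = int(np.argmin(pres))
    i_vmax = int(np.argmax(vel))

    return AirwayMetrics(
        v_total=v_total,
        v_na=vols["nasopharynx"],
        v_or=vols["oropharynx"],
        v_hy=vols["hypopharynx"],
        a_min=a_min,
        a_min_z=a_min_z,
        a_min_region=_region_of(a_min_z, boundaries),
        a_mean=a_mean,
        a_ratio=a_min / a_mean,
        dp_max=dp_max,
        dp_na=dps["nasopharynx"],
        dp_or=dps["oropharynx"],
        dp_hy=dps["hypopharynx"],
        r_na=resistance(dps["nasopharynx"]),
        r_or=resistance(dps["oropharynx"]),
        r_hy=resistance(dps["hypopharynx"]),
        min_pressure_z=float(z[i_pmin]),
        min_pressure_region=_region_of(float(z[i_pmin]), boundaries),
        max_velocity_z=float(z[i_vmax]),
        max_velocity_region=_region_of(float(z[i_vmax]), boundaries),
        q=q_ml_s,
    )


def profiles_to_csv(profiles: list[SliceProfile], path) -> None:
    data = np.array([[s.z, s.area, s.mean_pressure, s.mean_velocity] for s in profiles])
    np.savetxt(
        path, data, delimiter=",", header="z_mm,area_cm2,mean_pressure_pa,mean_velocity_m_s", comments=""
    )
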