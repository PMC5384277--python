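"""Structured body-fitted axisymmetric grids and the grid-independence protocol.

The grid lives on a mapped rectangle: axial stations z_i (uniform) and a
normalized radial coordinate eta in [0, 1] (geometrically graded toward the
wall), with physical radius r = eta * R(z). All metric quantities carry the
axisymmetric volume element 2*pi*r dr dz.

Internally the grid stores SI coordinates (metres); phantom input is mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pharynxflow.synthetic_anatomy import AirwayPhantom
from pharynxflow.units import MM_TO_M


@dataclass(frozen=True)
class AxiGrid:
    """Body-fitted axisymmetric structured grid.

    Attributes
    ----------
    z_faces : (nz+1,) axial face coordinates, m
    eta_faces : (nr+1,) normalized radial face coordinates in [0, 1]
    wall_radius : (nz+1,) R at axial faces, m
    wall_radius_c : (nz,) R at axial cell centres, m
    wall_slope_c : (nz,) dR/dz at cell centres
    volumes : (nz, nr) cell volumes, m^3
    """

    phantom: AirwayPhantom
    nz: int
    nr: int
    grading: float
    z_faces: np.ndarray
    eta_faces: np.ndarray
    wall_radius: np.ndarray
    wall_radius_c: np.ndarray
    wall_slope_c: np.ndarray
    wall_slope_f: np.ndarray
    volumes: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.nz * self.nr

    @property
    def dz(self) -> float:
        return float(self.z_faces[1] - self.z_faces[0])

    @property
    def eta_centers(self) -> np.ndarray:
        return 0.5 * (self.eta_faces[:-1] + self.eta_faces[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_faces[:-1] + self.z_faces[1:])

    def node_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(z, r) node arrays of shape (nz+1, nr+1), metres."""
        zz = np.repeat(self.z_faces[:, None], self.nr + 1, axis=1)
        rr = self.eta_faces[None, :] * self.wall_radius[:, None]
        return zz, rr

    def axial_face_areas(self) -> np.ndarray:
        """Annular areas of z = const faces, shape (nz+1, nr), m^2."""
        ring = self.eta_faces[1:] ** 2 - self.eta_faces[:-1] ** 2
        return np.pi * self.wall_radius[:, None] ** 2 * ring[None, :]

    def slice_area(self, i_face: int) -> float:
        """Total cross-sectional area at an axial face, m^2."""
        return float(self.axial_face_areas()[i_face].sum())

    def total_volume(self) -> float:
        """Sum of cell volumes, m^3."""
        return float(self.volumes.sum())


def _graded_eta(nr: int, grading: float) -> np.ndarray:
    """Radial faces in [0, 1], spacing shrinking by ``grading`` toward the wall."""
    if grading <= 0:
        raise ValueError("grading must be positive")
    widths = (1.0 / grading) ** np.arange(nr)
    widths = widths / widths.sum()
    return np.concatenate([[0.0], np.cumsum(widths)])


def generate_grid(
    phantom: AirwayPhantom,
    nz: int = 200,
    nr: int = 32,
    grading: float = 1.15,
) -> AxiGrid:
    """Mesh a phantom with a structured axisymmetric body-fitted grid.

    Cell volumes use the midpoint wall radius per axial cell, so the summed
    grid volume converges to the analytic profile volume at O(dz^2).
    """
    if nz < 8 or nr < 4:
        raise ValueError("need nz >= 8 and nr >= 4")
    if grading < 1:
        raise ValueError("grading must be >= 1 (finer toward the wall)")

    length_m = phantom.length * MM_TO_M
    z_faces = np.linspace(0.0, length_m, nz + 1)
    eta_faces = _graded_eta(nr, grading)

    z_mm_f = phantom.z[0] + z_faces / MM_TO_M
    z_mm_c = phantom.z[0] + (0.5 * (z_faces[:-1] + z_faces[1:])) / MM_TO_M
    wall_radius = phantom.radius_at(z_mm_f) * MM_TO_M
    wall_radius_c = phantom.radius_at(z_mm_c) * MM_TO_M

    min_r = float(wall_radius.min())
    dr_min = min_r * float(np.min(np.diff(eta_faces)))
    if dr_min <= 0 or min_r < 2 * dr_min * 1e-6:
        raise ValueError("phantom radius too small for the requested radial resolution")

    # dR/dz by central differences on the face radii
    wall_slope_c = (wall_radius[1:] - wall_radius[:-1]) / np.diff(z_faces)
    wall_slope_f = np.gradient(wall_radius, z_faces)

    ring = eta_faces[1:] ** 2 - eta_faces[:-1] ** 2  # (nr,)
    dz = np.diff(z_faces)  # (nz,)
    # exact for R constant per cell; midpoint R^2 gives O(dz^2) volume accuracy
    r2_mid = wall_radius_c**2 + (wall_radius[1:] - wall_radius[:-1]) ** 2 / 12.0
    volumes = np.pi * (r2_mid * dz)[:, None] * ring[None, :]
    if np.any(volumes <= 0):
        raise ValueError("non-positive cell volume; degenerate phantom")

    return AxiGrid(
        phantom=phantom,
        nz=nz,
        nr=nr,
        grading=grading,
        z_faces=z_faces,
        eta_faces=eta_faces,
        wall_radius=wall_radius,
        wall_radius_c=wall_radius_c,
        wall_slope_c=wall_slope_c,
        wall_slope_f=wall_slope_f,
        volumes=volumes,
    )


@dataclass(frozen=True)
class GridSeries:
    """Refinement series of grids over one phantom (coarse to fine)."""

    grids: tuple[AxiGrid, ...]
    ratio: float

    def __post_init__(self) -> None:
        counts = [g.n_cells for g in self.grids]
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("grid series must have strictly increasing cell counts")

    def __len__(self) -> int:
        return len(self.grids)

    def __getitem__(self, i: int) -> AxiGrid:
        return self.grids[i]


def refinement_series(
    phantom: AirwayPhantom,
    levels: int = 5,
    base_nz: int = 64,
    base_nr: int = 10,
    ratio: float = np.sqrt(2.0),
    grading: float = 1.15,
) -> GridSeries:
    """Build a series of ``levels`` grids refined by ``ratio`` per level."""
    grids = []
    for k in range(levels):
        nz = int(round(base_nz * ratio**k))
        nr = int(round(base_nr * ratio**k))
        grids.append(generate_grid(phantom, nz=nz, nr=nr, grading=grading))
    return GridSeries(grids=tuple(grids), ratio=ratio)


def grid_independence(
    phantom: AirwayPhantom,
    bc,
    fluid,
    numerics,
    levels: GridSeries,
    probe_z: float | None = None,
    threshold_pct: float = 1.0,
):
    """Run the solver across a refinement series and pick the coarsest
    acceptable level.

    A level is acceptable when the area-weighted mean pressure and mean
    velocity at ``probe_z`` each change by less than ``threshold_pct``
    relative to the next finer level. If no level qualifies, the finest is
    returned with ``converged_series=False``.

    Returns
    -------
    (chosen_index, table) where ``table`` is a list of per-level dicts with
    cells, mean_p, mean_v and percent changes versus the next finer level.
    """
    from pharynxflow.airway_metrics import probe_plane
    from pharynxflow.flow_solver import solve_steady

    if probe_z is None:
        probe_z = phantom.a_min()[1]  # the A_min station

    means = []
    for grid in levels.grids:
        fld = solve_steady(grid, bc, fluid, numerics)
        mp, mv = probe_plane(grid, fld, probe_z)
        means.append((mp, mv))

    table = []
    for k, grid in enumerate(levels.grids):
        row = {
            "level": k,
            "cells": grid.n_cells,
            "mean_pressure": means[k][0],
            "mean_velocity": means[k][1],
            "dp_pct": np.nan,
            "dv_pct": np.nan,
        }
        if k + 1 < len(levels.grids):
            ref_p = abs(means[k + 1][0]) or 1.0
            ref_v = abs(means[k + 1][1]) or 1.0
            row["dp_pct"] = abs(means[k][0] - means[k + 1][0]) / ref_p * 100.0
            row["dv_pct"] = abs(means[k][1] - means[k + 1][1]) / ref_v * 100.0
        table.append(row)

    for row in table[:-1]:
        if row["dp_pct"] < threshold_pct and row["dv_pct"] < threshold_pct:
            row_chosen = row["level"]
            break
    else:
        import warnings

        warnings.warn("grid-independence criterion never met; returning finest level")
        row_chosen = len(levels.grids) - 1
    return row_chosen, table


def write_vtk_structured(grid: AxiGrid, path, field=None) -> None:
    """Write the grid (optionally with a flow field) as legacy VTK ASCII.

    Emits a STRUCTURED_GRID of the meridional (z, r) plane; point data
    carries u_z, u_r, p interpolated to nodes when ``field`` is given.
    """
    zz, rr = grid.node_coordinates()
    npts = zz.size
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("axisymmetric airway grid (meridional plane)\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {grid.nr + 1} {grid.nz + 1} 1\n")
        fh.write(f"POINTS {npts} double\n")
        for i in range(grid.nz + 1):
            for j in range(grid.nr + 1):
                fh.write(f"{zz[i, j]:.9e} {rr[i, j]:.9e} 0.0\n")
        if field is not None:
            uz = field.node_axial_velocity()
            ur = field.node_radial_velocity()
            p = field.node_pressure()
            fh.write(f"POINT_DATA {npts}\n")
            fh.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
            for i in range(grid.nz + 1):
                for j in range(grid.nr + 1):
                    fh.write(f"{p[i, j]:.9e}\n")
            fh.write("VECTORS velocity double\n")
            for i in range(grid.nz + 1):
                for j in range(grid.nr + 1):
                    fh.write(f"{uz[i, j]:.9e} {ur[i, j]:.9e} 0.0\n")
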