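"""Shared fixtures; expensive flow solutions are session-scoped."""

import warnings

import numpy as np
import pytest

from pharynxflow import (
    BoundaryConditions,
    CohortParams,
    FluidProps,
    NumericsConfig,
    build_phantom,
    generate_grid,
    peak_flow_rate,
    solve_steady,
)
from pharynxflow.synthetic_anatomy import mean_spec, uniform_tube_spec


TUBE_RADIUS_MM = 5.0
TUBE_LENGTH_MM = 300.0
POISEUILLE_RE = 100.0


@pytest.fixture(scope="session")
def default_params():
    return CohortParams()


@pytest.fixture(scope="session")
def mean_phantom(default_params):
    """Phantom built from the pre-treatment cohort means."""
    return build_phantom(mean_spec(default_params))


@pytest.fixture(scope="session")
def air():
    return FluidProps(gravity_enabled=False)


@pytest.fixture(scope="session")
def tube_phantom():
    area_cm2 = np.pi * TUBE_RADIUS_MM**2 * 1e-2
    return build_phantom(uniform_tube_spec(area_cm2, TUBE_LENGTH_MM), 4)


@pytest.fixture(scope="session")
def poiseuille_case(tube_phantom, air):
    """Converged laminar tube flow at Re = 100 (L/D = 30)."""
    grid = generate_grid(tube_phantom, nz=120, nr=16, grading=1.15)
    v_mean = POISEUILLE_RE * air.viscosity / (air.density * 2 * TUBE_RADIUS_MM * 1e-3)
    bc = BoundaryConditions(inlet_velocity=v_mean)
    field = solve_steady(grid, bc, air, NumericsConfig(max_iterations=800))
    assert field.converged
    return grid, field, v_mean


@pytest.fixture(scope="session")
def venturi_case(mean_phantom, air):
    """Mean-anatomy phantom at a quarter of the peak flow (Re ~ 600)."""
    grid = generate_grid(mean_phantom, nz=100, nr=14, grading=1.15)
    q = 0.25 * peak_flow_rate(600.0, 4.0, 1.0)
    bc = BoundaryConditions.from_flow(q, mean_phantom.spec.inlet_area)
    field = solve_steady(grid, bc, air, NumericsConfig(max_iterations=2000))
    assert field.converged
    return grid, field, q


@pytest.fixture(scope="session")
def peak_venturi_case(mean_phantom):
    """Mean-anatomy phantom at the full peak inspiratory flow (with gravity)."""
    grid = generate_grid(mean_phantom, nz=100, nr=14, grading=1.15)
    q = peak_flow_rate(600.0, 4.0, 1.0)
    bc = BoundaryConditions.from_flow(q, mean_phantom.spec.inlet_area)
    fluid = FluidProps()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Re above the laminar guard
        field = solve_steady(grid, bc, fluid, NumericsConfig(max_iterations=3000))
    assert field.converged
    return grid, field, q
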