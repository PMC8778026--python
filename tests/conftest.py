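"""Shared fixtures: fitted reference potentials and reusable BD runs."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nanoagg as na

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TEMPERATURE = 310.0


@pytest.fixture(scope="session")
def anatase_fits():
    """radius -> (synthetic curve, piecewise fit) for the reference wells."""
    out = {}
    for R, (depth, gap) in na.ANATASE_PMF_WELLS.items():
        curve = na.make_synthetic_pmf(
            na.SyntheticPMFSpec(radius=R, depth=depth, surface_gap=gap)
        )
        out[R] = (curve, na.fit_pmf(curve))
    return out


@pytest.fixture(scope="session")
def table_r2(anatase_fits):
    _, fit = anatase_fits[2.0]
    return na.tabulate(fit)


@pytest.fixture(scope="session")
def zero_table():
    """Interaction-free table: isolates the integrator thermostat."""
    n = 501
    return na.TabulatedPotential(
        step=2e-3, d_min=2e-3, d_max=2e-3 * n,
        energy=np.zeros(n), force=np.zeros(n),
    )


@pytest.fixture(scope="session")
def free_run(zero_table):
    """300 non-interacting beads, 1.2e5 steps: thermostat statistics."""
    mass = na.nanoparticle_mass(2.0)
    spec = na.ParticleSpec.from_viscosity(2.0, mass, na.WATER_VISCOSITY_310K)
    n, h = 300, 400.0
    rng = np.random.default_rng(2024)
    pos = rng.uniform(0, h, size=(n, 3))
    state = na.SimulationState(
        pos, na.maxwell_velocities(n, TEMPERATURE, mass, 5), h_box=h, seed=77
    )
    cfg = na.BDConfig(table=zero_table, dt=0.1, T=TEMPERATURE,
                      n_steps=120_000, stride=400)
    traj, final = na.run_simulation(cfg, spec, state)
    return traj, spec


@pytest.fixture(scope="session")
def pair_well_run():
    """Two beads bound in a moderate tabulated well, long sampling run."""
    R, depth, gap = 1.0, 30.0, 0.3
    curve = na.make_synthetic_pmf(
        na.SyntheticPMFSpec(radius=R, depth=depth, surface_gap=gap)
    )
    tab = na.tabulate(na.fit_pmf(curve))
    spec = na.ParticleSpec(radius=R, mass=100.0, gamma=0.5)
    h = 20.0
    d0 = 2 * R + gap
    pos = np.array([[5.0, 5.0, 5.0], [5.0 + d0, 5.0, 5.0]])
    state = na.SimulationState(
        pos, na.maxwell_velocities(2, TEMPERATURE, spec.mass, 5), h_box=h, seed=9
    )
    cfg = na.BDConfig(table=tab, dt=0.02, T=TEMPERATURE,
                      n_steps=2_000_000, stride=500)
    traj, _ = na.run_simulation(cfg, spec, state)
    return traj, tab, h


@pytest.fixture(scope="session")
def aggregation_run(anatase_fits):
    """Scaled-down end-to-end study: 200 R=2 nm beads at phi = 0.5%,
    2e6 Langevin steps, clustered into a kinetics trace."""
    R = 2.0
    phi = 0.005
    _, fit = anatase_fits[R]
    tab = na.tabulate(fit)
    mass = na.nanoparticle_mass(R)
    spec = na.ParticleSpec.from_viscosity(R, mass, na.WATER_VISCOSITY_310K)
    n = 200
    h = (n * (4.0 / 3.0) * np.pi * R**3 / phi) ** (1.0 / 3.0)
    pos = na.random_configuration(n, h, R, seed=11)
    state = na.SimulationState(
        pos, na.maxwell_velocities(n, TEMPERATURE, mass, 12), h_box=h, seed=1
    )
    cfg = na.BDConfig(table=tab, dt=0.1, T=TEMPERATURE,
                      n_steps=2_000_000, stride=10_000)
    traj, _ = na.run_simulation(cfg, spec, state)
    trace = na.trace_from_trajectory(traj.frames(), R, h)
    params = na.SuspensionParams(radius=R, phi=phi)
    return trace, params
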