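"""Shared fixtures.

The expensive sampled objects (lattice titration, ideal-gas run, toy-host
apo/holo titrations) are session-scoped: several tests interrogate different
properties of the same ensembles.
"""

import numpy as np
import pytest

from grandgist.energetics import (RigidWaterModel, ROIRegion,
                                  RigidWaterConfiguration, SimulationBox)
from grandgist.sampler import (AdamsParameters, MoveMix, equilibrium_adams,
                               run_gcmc, run_lattice_gcmc)
from grandgist.synth import LatticeGCSystem, ToyHostSpec, make_toy_host
from grandgist.titration import build_titration_curve, free_energy_profile


@pytest.fixture(scope="session")
def tip3p():
    return RigidWaterModel.named("tip3p_like")


@pytest.fixture(scope="session")
def lj_probe():
    return RigidWaterModel.named("lj_probe")


@pytest.fixture(scope="session")
def ideal_model():
    """Non-interacting single-site 'water' (all eps and q zero)."""
    return RigidWaterModel("ideal", [[0.0, 0.0, 0.0]], [0.0], [0.0], [0.0],
                           ("water_oxygen",), 0.0329)


@pytest.fixture
def open_box():
    return SimulationBox(lengths=[50.0, 50.0, 50.0], periodic=False,
                         nonbonded_cutoff=12.0)


@pytest.fixture(scope="session")
def lattice10():
    """10 sites with mixed energies spanning -20..0 kJ/mol."""
    return LatticeGCSystem(energies=np.linspace(-20.0, 0.0, 10), T=300.0)


@pytest.fixture(scope="session")
def lattice10_titration(lattice10):
    """11-point Adams grid sampled at 2e5 moves per point."""
    b_values = np.linspace(-12.0, 2.0, 11)
    tagged = [
        (b, run_lattice_gcmc(lattice10, b, n_moves=200_000, record_every=5,
                             seed=100 + i))
        for i, b in enumerate(b_values)
    ]
    curve = build_titration_curve(tagged, B_equil=-6.0)
    return tagged, curve


@pytest.fixture(scope="session")
def ideal_gas_run(ideal_model):
    """Grand-canonical run of the non-interacting system at B = 1.5."""
    box = SimulationBox([20.0, 20.0, 20.0], True, 9.0)
    roi = ROIRegion("sphere", center=[10.0, 10.0, 10.0], radius=4.0)
    config = RigidWaterConfiguration(box=box, model=ideal_model, roi=roi)
    params = AdamsParameters(B=1.5, T=300.0)
    trace = run_gcmc(config, params, MoveMix(), n_moves=100_000,
                     record_every=10, seed=3)
    return trace, params


@pytest.fixture(scope="session")
def toy_titrations(lj_probe):
    """Apo and holo toy-cavity titrations with free-energy profiles."""
    out = {}
    b_values = np.linspace(-18.0, -2.0, 11)
    for label, blocked, seed0 in (("apo", (), 500), ("holo", (0, 1), 600)):
        config = make_toy_host(ToyHostSpec(blocked_hotspots=blocked), lj_probe)
        b_equil = equilibrium_adams(
            AdamsParameters(B=0.0, T=300.0, mu_ex=-25.9, V_std=30.0), config.roi)
        tagged = [
            (b, run_gcmc(config, AdamsParameters(B=b, T=300.0), MoveMix(),
                         n_moves=30_000, record_every=10, seed=seed0 + i))
            for i, b in enumerate(b_values)
        ]
        curve = build_titration_curve(tagged, B_equil=b_equil)
        out[label] = (config, curve, free_energy_profile(curve))
    return out
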