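"""Shared fixtures: coarse meshes and synthetic records sized for testing.

Estimation-grade discretisation (target_h = 2.5e-4 m, dt = 1 s) is used
throughout; self-convergence tests cover the refinement direction.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from seedwave.fem import Assembly
from seedwave.lensgeom import LensGeometry, generate_mesh
from seedwave.synth import generate_record, make_paper_like_scenarios

EST_H = 2.5e-4
EST_DT = 1.0


@pytest.fixture(scope="session")
def geom() -> LensGeometry:
    return LensGeometry()


@pytest.fixture(scope="session")
def assembly(geom) -> Assembly:
    return Assembly(generate_mesh(geom, EST_H))


@pytest.fixture(scope="session")
def fine_assembly(geom) -> Assembly:
    return Assembly(generate_mesh(geom))


@pytest.fixture(scope="session")
def scenario_50():
    """The 0.70 kW / 50 % d.b. study preset, shortened to a 6-minute record."""
    sc = next(s for s in make_paper_like_scenarios(noise=(0.0, 0.0))
              if s.treatment_id == "0.70kW-50")
    return replace(sc, schedule=np.arange(0.0, 361.0, 15.0))


@pytest.fixture(scope="session")
def record_50(scenario_50):
    """Noise-free synthetic record at estimation discretisation."""
    return generate_record(scenario_50, target_h=EST_H, dt=EST_DT)
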