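import numpy as np
import pytest

from poroscaf import fem, geometry


LUC = 0.637  # default unit-cell edge, mm (2.548 / 4)


@pytest.fixture(scope="session")
def materials():
    return fem.default_materials()


@pytest.fixture(scope="session")
def tiny_scaffold():
    """One-cell scaffold used across FE tests."""
    return geometry.ScaffoldSpec.create(Ds=0.5, Dc=0.2, L=LUC, cells_per_side=1)


@pytest.fixture(scope="session")
def tiny_grid(tiny_scaffold):
    return geometry.assemble_scaffold(tiny_scaffold, resolution=8)


@pytest.fixture(scope="session")
def tiny_result(tiny_grid, materials):
    """Solved compression case on the one-cell scaffold (shared, read-only)."""
    load = fem.LoadCase(mode="compression", F_UA=0.1)
    model = fem.build_fe_model(tiny_grid, materials, load)
    return fem.solve_consolidation(model)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
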