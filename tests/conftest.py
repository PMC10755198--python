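"""Shared fixtures: standard parameter grids, computed once per session."""

import pytest

from frceq import GridSpec, run_grid


@pytest.fixture(scope="session")
def autosomal_grid_c2():
    """Standard autosomal (h, s) grid at C = 2 with simulated C = 1 baselines."""
    return run_grid(GridSpec(C_values=(2.0,), locus_mode="autosomal"))


@pytest.fixture(scope="session")
def sexlinked_grid_c2():
    return run_grid(GridSpec(C_values=(2.0,), locus_mode="sexlinked"))


@pytest.fixture(scope="session")
def sexlinked_grid_c15():
    return run_grid(GridSpec(C_values=(1.5,), locus_mode="sexlinked"))


@pytest.fixture(scope="session")
def dimorphic_grid_c100():
    return run_grid(GridSpec(C_values=(100.0,), locus_mode="dimorphic"))
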