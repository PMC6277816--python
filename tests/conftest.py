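import numpy as np
import pytest

from atriofiber.synthetic import (
    ShellAtriumSpec,
    build_shell_atlas,
    make_shell_atrium,
    make_slab_mesh,
    make_voxel_phantom,
)


@pytest.fixture(scope="session")
def shell_spec():
    return ShellAtriumSpec()


@pytest.fixture(scope="session")
def shell(shell_spec):
    return make_shell_atrium(shell_spec)


@pytest.fixture(scope="session")
def shell_atlases(shell, shell_spec):
    return {
        "endo": build_shell_atlas(shell, shell_spec, "endo"),
        "epi": build_shell_atlas(shell, shell_spec, "epi"),
    }


@pytest.fixture(scope="session")
def closed_shell():
    """Spherical shell with no PV holes and constant thickness (analytic
    transmural solution is radial)."""
    spec = ShellAtriumSpec(
        radii=(10.0, 10.0, 10.0),
        thickness_top=2.0,
        thickness_bottom=2.0,
        n_theta=16,
        n_phi=32,
        n_layers=4,
        theta_top=0.5,
        theta_mv=np.pi - 0.5,
        pv_hole_phi_cells=0,
    )
    return make_shell_atrium(spec), spec


@pytest.fixture(scope="session")
def fine_shell():
    """Refined shell: the fiber field varies slowly enough per triangle for
    discrete winding-number measurement around the PV rims."""
    spec = ShellAtriumSpec(n_theta=32, n_phi=64, pv_hole_phi_cells=4)
    shell = make_shell_atrium(spec)
    atlases = {w: build_shell_atlas(shell, spec, w) for w in ("endo", "epi")}
    return shell, spec, atlases


@pytest.fixture(scope="session")
def small_slab():
    return make_slab_mesh((10.0, 10.0, 2.0), 0.5)


@pytest.fixture(scope="session")
def default_phantom():
    return make_voxel_phantom()


@pytest.fixture(scope="session")
def paced_state():
    """CRN state after a short pacing run; shared by tissue-level tests."""
    from atriofiber.ep import pace_to_steady_state

    state, _ = pace_to_steady_state(4, bcl=500.0)
    return state
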