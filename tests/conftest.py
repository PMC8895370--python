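import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True)
settings.load_profile("det")

from bltmds import forward as fwd
from bltmds import mesh as msh
from bltmds import optics as opt


@pytest.fixture(scope="session")
def small_mesh():
    """4 mm cube at 2 mm spacing: 27 nodes, 48 tets."""
    return msh.generate_box_mesh((4, 4, 4), 2.0)


@pytest.fixture(scope="session")
def medium_mesh():
    """10 mm cube at 2 mm spacing: 216 nodes, 750 tets."""
    return msh.generate_box_mesh((10, 10, 10), 2.0)


@pytest.fixture(scope="session")
def homo_props():
    """Single-region muscle-like table for all four default wavelengths."""
    return opt.single_region_properties("muscle")


@pytest.fixture(scope="session")
def medium_forward(medium_mesh, homo_props):
    """Assembled systems, a centred source, and clean measurements at 4
    wavelengths on the 10 mm phantom (shared across tests for speed)."""
    mesh = medium_mesh
    source = msh.embed_spherical_source(
        mesh, msh.SourceSpec((4.0, 4.0, 6.0), 1.0, 1.0)
    )
    detectors = fwd.DetectorSet.from_boundary(mesh)
    fems = {
        w: fwd.assemble_system(mesh, homo_props, w)
        for w in opt.DEFAULT_WAVELENGTHS
    }
    clean = {
        w: fwd.simulate_measurement(
            mesh, homo_props, w, source, detectors, fem=fems[w]
        )
        for w in opt.DEFAULT_WAVELENGTHS
    }
    return mesh, source, detectors, fems, clean


@pytest.fixture(scope="session")
def system_matrices(medium_forward, homo_props):
    mesh, _, detectors, fems, _ = medium_forward
    perm = np.setdiff1d(np.arange(mesh.n_nodes), mesh.boundary_nodes)
    A = {
        w: fwd.build_system_matrix(
            mesh, homo_props, w, detectors, perm, fem=fems[w]
        ).matrix
        for w in opt.DEFAULT_WAVELENGTHS
    }
    return A, perm
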