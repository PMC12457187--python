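import numpy as np
import pytest

from vbtstim import anatomy, pipeline


@pytest.fixture(scope="session")
def toy_brain():
    """Small deterministic toy brain shared across tests."""
    return anatomy.make_toy_brain(n_vertices=300, n_regions=10, seed=42)


@pytest.fixture(scope="session")
def toy_mesh(toy_brain):
    return toy_brain[0]


@pytest.fixture(scope="session")
def study():
    """One full study (brain + excitability map + coupling)."""
    return pipeline.build_study(n_vertices=300, n_regions=10, seed=42)


@pytest.fixture(scope="session")
def seeg_sim(study):
    """One SEEG-stimulation simulation reused by feature/pipeline tests."""
    return pipeline.run_seeg_stim_simulation(study, seed=42, T=80.0)


def fan_mesh(n_chain=6, spacing=1.0):
    """Chain of collinear vertices closed by a distant apex (edge-graph
    geodesics along the chain are exact multiples of the spacing)."""
    verts = [[i * spacing, 0.0, 0.0] for i in range(n_chain)]
    verts.append([(n_chain - 1) * spacing / 2, 1000.0, 0.0])
    tris = [[i, i + 1, n_chain] for i in range(n_chain - 1)]
    return anatomy.Mesh(vertices=np.array(verts, dtype=float),
                        triangles=np.array(tris, dtype=int))
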