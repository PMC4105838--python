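import numpy as np
import pytest

from rootmetrics import evaluate, rootgen


@pytest.fixture(scope="session")
def bench():
    """The 10-image artificial-root benchmark at the standard seed."""
    return evaluate.run_benchmark(n_systems=10, seed=42)


@pytest.fixture(scope="session")
def straight_root_render():
    """Noiseless render of one straight vertical root of known diameter."""
    d = 0.6
    root = rootgen.Root("A1", 0, [rootgen.RootNode(10.0, 2.0, d), rootgen.RootNode(10.0, 38.0, d)])
    system = rootgen.RootSystem([root], (20.0, 40.0), seed=1)
    image, gt = rootgen.render(system, rootgen.RenderConfig())
    return {"system": system, "image": image, "gt": gt, "diameter": d}


@pytest.fixture(scope="session")
def small_system_render():
    """A small multi-root system rendered noiselessly."""
    system = rootgen.generate_root_system(
        n_axile=2, laterals_per_cm=1.0, extent=(50.0, 60.0), seed=11
    )
    image, gt = rootgen.render(system, rootgen.RenderConfig())
    return {"system": system, "image": image, "gt": gt}


def quarter_circle_root(radius=20.0, n_nodes=5, diameter=0.5):
    """Nodes sampled from a quarter circle of given radius (mm)."""
    angles = np.linspace(0.0, np.pi / 2.0, n_nodes)
    nodes = [
        rootgen.RootNode(
            25.0 + radius * np.cos(a), 25.0 + radius * np.sin(a), diameter
        )
        for a in angles
    ]
    return rootgen.Root("C1", 0, nodes)
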