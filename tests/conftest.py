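import numpy as np
import pytest

from tailatlas.core import PointCloud
from tailatlas.synthetic import TailbudScenario, simulate_tailbud


@pytest.fixture(scope="session")
def tailbud():
    """A mid-sized synthetic tailbud with anchor channels."""
    return simulate_tailbud(TailbudScenario(n_points=400, seed=1))


@pytest.fixture(scope="session")
def tailbud_with_genes():
    """Tailbud carrying two extra anchor-correlated gene channels."""
    return simulate_tailbud(
        TailbudScenario(
            n_points=400,
            seed=2,
            extra_channels={"cdh6": ("sox2", 0.6), "tcf": ("tbxta", 0.5)},
        )
    )


@pytest.fixture()
def toy_cloud():
    rng = np.random.default_rng(7)
    pts = rng.uniform(-10, 10, size=(30, 3))
    return PointCloud(pts, {"sox2": rng.uniform(size=30)}, sample_id="toy")
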