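import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tilescope.synthetic import (
    SyntheticCohortConfig,
    generate_cohort,
    render_objects,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small multi-site cohort with the default class-dependent
    infiltration rates (0.05 vs 0.30), shared across tests."""
    config = SyntheticCohortConfig(
        n_patients=8, n_sites=2, slide_size=(672, 672), seed=7
    )
    records, images, truth = generate_cohort(config)
    return config, records, images, truth


@pytest.fixture()
def planted_tile():
    """One 224x224 tile with 10 lymphocytes and 10 tumor nuclei planted on
    a jittered grid (non-overlapping), plus the object truth table."""
    rng = np.random.default_rng(42)
    tile = np.full((224, 224, 3), 245.0)
    coords = [(28 + 42 * i, 28 + 42 * j) for i in range(5) for j in range(4)]
    rng.shuffle(coords)
    rows, cols = zip(*coords[:20])
    objects = pd.DataFrame(
        {
            "row": np.array(rows, dtype=float) + rng.uniform(-4, 4, 20),
            "col": np.array(cols, dtype=float) + rng.uniform(-4, 4, 20),
            "cell_type": ["lymphocyte"] * 10 + ["tumor_nucleus"] * 10,
            "r_major": np.r_[rng.uniform(3.5, 5.5, 10), rng.uniform(9, 13, 10)],
            "r_minor": np.r_[rng.uniform(3.5, 5.5, 10), rng.uniform(9, 13, 10)],
            "orientation": rng.uniform(0, np.pi, 20),
        }
    )
    lymph_mask, nuclei_mask = render_objects(tile, objects, rng)
    return tile.astype(np.uint8), objects, lymph_mask, nuclei_mask
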