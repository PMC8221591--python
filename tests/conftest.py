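import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_ct_table(
    values: dict[str, list[float]],
    groups: list[str],
    region: str = "CTX",
    fraction: str = "IP",
) -> pd.DataFrame:
    """Long CT table from per-gene sample vectors (one replicate each)."""
    n = len(groups)
    rows = []
    for gene, cts in values.items():
        assert len(cts) == n
        for i, (g, ct) in enumerate(zip(groups, cts)):
            rows.append((gene, f"s{i + 1}", g, region, fraction, 1, float(ct)))
    return pd.DataFrame(
        rows,
        columns=["gene", "sample", "group", "region", "fraction", "replicate", "CT"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dot_scene():
    """One dot-only scene at SNR 3 with its truth (shared across tests)."""
    from ribodots.simulate import SceneParams, simulate_scene

    params = SceneParams(n_dots=200, dot_snr=3.0, n_cells=0)
    return simulate_scene(params, seed=7)


@pytest.fixture(scope="session")
def cell_scene():
    """Scene with Pvalb cells and 30% IEG-positive cells, plus truth."""
    from ribodots.simulate import SceneParams, simulate_scene

    params = SceneParams(
        n_dots=120, dot_snr=4.0, n_cells=10, frac_ieg_positive_cells=0.3
    )
    return simulate_scene(params, seed=11)
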