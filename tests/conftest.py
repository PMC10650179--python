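import numpy as np
import pytest
from hypothesis import settings

from afmtex import AdhesionMap, CohortSpec, SpectralSurfaceSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_map():
    """A constant 16x16 map: the fully degenerate surface."""
    return AdhesionMap(np.full((16, 16), 2.5), dx=1.0, dy=1.0, cell_id="flat")


@pytest.fixture
def plane_map():
    """z = x with unit slope per nm: closed-form Sdr and Sdq."""
    n = 32
    x = np.arange(n, dtype=float)
    return AdhesionMap(np.tile(x, (n, 1)), dx=1.0, dy=1.0, cell_id="plane")


@pytest.fixture
def rough_map():
    """A generic non-flat synthetic surface for invariance checks."""
    from afmtex import generate_map

    return generate_map(SpectralSurfaceSpec(grid_n=128, seed=7), cell_id="rough")


def small_cohort_spec(seed: int = 3, separated: bool = True, n_a: int = 16,
                      n_b: int = 16, grid_n: int = 128) -> CohortSpec:
    """A desk-scale two-class cohort spec.

    grid_n >= 128 keeps the 1/300 nm^-1 band split resolvable inside a
    quadrant of a 10 um scan.
    """
    spec_a = SpectralSurfaceSpec(grid_n=grid_n)
    if separated:
        spec_b = SpectralSurfaceSpec(grid_n=grid_n, b_low=-0.8, b_high=-1.2)
    else:
        spec_b = SpectralSurfaceSpec(grid_n=grid_n)
    return CohortSpec(
        n_class_a=n_a, n_class_b=n_b, spec_a=spec_a, spec_b=spec_b, seed=seed
    )


@pytest.fixture(scope="session")
def separated_table():
    """Feature table of a small well-separated cohort (32 cells)."""
    from afmtex import extract_features, generate_cohort

    maps = generate_cohort(small_cohort_spec(seed=3, separated=True))
    table, _ = extract_features(maps)
    return table


def random_feature_table(rng, n_a=20, n_b=14, shift=0.0):
    """A feature table drawn directly from Gaussians (no maps involved)."""
    import pandas as pd

    from afmtex.surfparams import PARAMETER_NAMES

    n = n_a + n_b
    data = rng.normal(size=(n, len(PARAMETER_NAMES)))
    data[n_a:] += shift
    table = pd.DataFrame(data, columns=list(PARAMETER_NAMES))
    table.insert(0, "cell_id", [f"c{i}" for i in range(n)])
    table["class"] = ["precancerous"] * n_a + ["cancerous"] * n_b
    return table
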