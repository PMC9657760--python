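import numpy as np
import pytest

from planktofuse import StudyDesign, default_templates, generate_dataset


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture
def small_design():
    """Full study geometry on reduced grids, fast enough for unit tests."""
    return StudyDesign(
        libs_grid=(186.0, 1049.0, 2000),
        raman_grid=(450.0, 3150.0, 700),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset():
    design = StudyDesign(
        libs_grid=(186.0, 1049.0, 2000),
        raman_grid=(450.0, 3150.0, 700),
        seed=11,
    )
    return generate_dataset(design)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
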