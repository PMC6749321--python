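import pytest

from aromaprofiler.library import default_sensory, load_library
from aromaprofiler.simulate import default_design, generate_ladder, generate_study


@pytest.fixture(scope="session")
def library():
    return load_library("default")


@pytest.fixture(scope="session")
def by_id(library):
    return {rec.compound_id: rec for rec in library}


@pytest.fixture(scope="session")
def sensory():
    return default_sensory()


@pytest.fixture(scope="session")
def ladder(library):
    return generate_ladder(library)


@pytest.fixture(scope="session")
def noiseless_study(library):
    """22 wines x 3 replicates, zero noise, no decoys: exact ground truth."""
    design = default_design(seed=7)
    return generate_study(design, library=library, noise_cv=0.0)


@pytest.fixture(scope="session")
def noisy_study(library):
    """Default study conditions: 5% multiplicative replicate noise."""
    design = default_design(seed=11)
    return generate_study(design, library=library, noise_cv=0.05)
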