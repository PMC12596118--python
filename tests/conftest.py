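import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracles module

from lysismine.pipeline import build_family_profiles
from lysismine.synth import default_plant_spec, default_vocabulary, generate_dataset


@pytest.fixture(scope="session")
def vocabulary():
    return default_vocabulary()


@pytest.fixture(scope="session")
def small_dataset():
    """12 genomes: covers every subclass cycle at least once."""
    return generate_dataset(default_plant_spec(n_genomes=12, seed=3))


@pytest.fixture(scope="session")
def family_profiles(vocabulary):
    return build_family_profiles(vocabulary, seed=3)
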