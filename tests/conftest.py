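import numpy as np
import pytest

from pestpair import default_cooccurrence, make_default_schema


@pytest.fixture(scope="session")
def schema():
    return make_default_schema()


@pytest.fixture(scope="session")
def cooc(schema):
    return default_cooccurrence(schema)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_dataset(schema, cooc, tmp_path_factory):
    """A small rendered dataset shared across tests (manifest path)."""
    from pestpair import generate_dataset

    out = tmp_path_factory.mktemp("desk_scenes")
    return generate_dataset(80, schema, cooc, seed=2024, out_dir=out, canvas_size=64)
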