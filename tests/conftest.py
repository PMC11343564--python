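import pytest

from loophub import (
    SyntheticSpec,
    derive_catalog,
    generate_annotations,
    generate_loops,
)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def annotations(default_spec):
    return generate_annotations(default_spec)


@pytest.fixture(scope="session")
def catalog(annotations):
    return derive_catalog(
        annotations.genes, annotations.repeats, annotations.histone_peaks
    )


@pytest.fixture(scope="session")
def loop_truth(default_spec, annotations):
    return generate_loops(default_spec, annotations)
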