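import pytest

from minisplice.intake import read_variant_table
from minisplice.model import bundled_path, load_bundled_model
from minisplice.reclassify import read_assay_table


@pytest.fixture(scope="session")
def model():
    return load_bundled_model()


@pytest.fixture(scope="session")
def variants():
    return read_variant_table(bundled_path("rpe65_variants.tsv"))


@pytest.fixture(scope="session")
def assays(model, variants):
    return read_assay_table(bundled_path("rpe65_assays.tsv"), model,
                            variants=variants)
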