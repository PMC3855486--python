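import pytest

from pncc.catalog import load_catalog
from pncc.synth import GeneratorConfig, generate_lineage_sequences


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def clean_panels(catalog):
    """Zero-noise single-lineage panels keyed by lineage (small n)."""
    lineages = [
        "1.1", "1.2", "1.3", "2.1", "2.2.1.1", "2.2.1.2", "2.2.2.1",
        "2.2.2.2", "2.2.2.3", "2.2.3.1", "2.2.3.2", "2.2.3.3", "2.2.3.4",
    ]
    return {
        lin: generate_lineage_sequences(
            GeneratorConfig(lineage=lin, n=3, seed=11, substitution_rate=0.0),
            catalog,
        )
        for lin in lineages
    }
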