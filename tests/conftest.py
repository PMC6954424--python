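import numpy as np
import pytest

from halobc import BarcodeSchema, ProteinIdentifier, generate_identifiers


@pytest.fixture(scope="session")
def toy_schema() -> BarcodeSchema:
    """Five hand-written identifiers, pairwise Hamming distance >= 6."""
    identifiers = (
        ProteinIdentifier("AAAAAAAA", "alpha", "assay"),
        ProteinIdentifier("CCCCCCCC", "beta", "assay"),
        ProteinIdentifier("GGGGGGGG", "halotag_only", "control"),
        ProteinIdentifier("TTTTTTTT", "unused_1", "unused"),
        ProteinIdentifier("ACGTACGT", "unused_2", "unused"),
    )
    return BarcodeSchema(identifiers=identifiers)


@pytest.fixture(scope="session")
def sim_schema() -> BarcodeSchema:
    """Randomly designed identifier panel for simulation tests."""
    roles = ["assay", "assay", "control", "unused", "unused", "unused"]
    return BarcodeSchema(
        identifiers=generate_identifiers(len(roles), rng=12345, roles=roles)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987)
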