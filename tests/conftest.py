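import numpy as np
import pytest

from beepro.io_datasets import AntigenRecord, EpitopeDataset
from beepro.synthetic import SyntheticSpec, generate


def record(rid: str, cased: str) -> AntigenRecord:
    """Build a record from a case-coded string (uppercase = epitope)."""
    mask = np.array([c.isupper() for c in cased])
    return AntigenRecord(rid, cased.upper(), mask)


@pytest.fixture
def toy_record() -> AntigenRecord:
    return record("p1", "ggAAKgg")


@pytest.fixture
def toy_dataset() -> EpitopeDataset:
    return EpitopeDataset(
        [
            record("p1", "ggAAKgg"),
            record("p2", "mklvDEKnsAAmkl"),
            record("p3", "aaaaaaaaaa"),
        ],
        name="toy",
    )


@pytest.fixture(scope="session")
def small_enriched() -> EpitopeDataset:
    """A small labelled dataset with clear compositional enrichment,
    big enough for protein-level 5-fold splitting."""
    spec = SyntheticSpec(
        n_proteins=15,
        length_range=(60, 120),
        epitope_density=0.25,
        enrichment_strength=8.0,
        segment_length_range=(8, 20),
        seed=101,
        name="small-enriched",
    )
    return generate(spec)
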