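import numpy as np
import pytest

from vlamy.features import extract_matrix
from vlamy.io import AnnotatedVL, REGION_ORDER, validate
from vlamy.simulate import SimConfig, simulate


def make_record(
    fr1="DIQMTQSPSSLSASVGDRVTITC",
    cdr1="QASQDISNYL",
    fr2="NWYQQKPGKAPKLLIYD",
    cdr2="ASN",
    fr3="LETGVPSRFSGSGSGTDFTFTISSLQPEDIA",
    cdr3="QQYDNLPL",
    fr4="TFGGGTKVEI",
    seq_id="toy",
    isotype="kappa",
    label="unlabeled",
):
    """Build a valid AnnotatedVL from explicit per-region strings."""
    parts = [fr1, cdr1, fr2, cdr2, fr3, cdr3, fr4]
    regions = {}
    pos = 1
    for name, part in zip(REGION_ORDER, parts):
        regions[name] = (pos, pos + len(part) - 1)
        pos += len(part)
    record = AnnotatedVL(
        id=seq_id,
        sequence="".join(parts),
        regions=regions,
        isotype=isotype,
        label=label,
    )
    validate(record)
    return record


@pytest.fixture
def toy_record():
    return make_record()


@pytest.fixture(scope="session")
def planted_records():
    """Small planted-effect dataset shared across tests (generator defaults)."""
    return simulate(SimConfig(n_pos=60, n_neg=60, seed=7))


@pytest.fixture(scope="session")
def planted_matrix(planted_records):
    return extract_matrix(planted_records)


@pytest.fixture(scope="session")
def null_records():
    """Same size with all-zero deltas: classes exchangeable."""
    return simulate(
        SimConfig(n_pos=60, n_neg=60, delta_hyd=0.0, delta_gk=0.0, delta_dis=0.0, seed=7)
    )


def random_conflict_free(rng, n, d):
    """Random numeric dataset with no duplicate-row label conflicts."""
    X = np.round(rng.normal(size=(n, d)), 3)
    y = rng.integers(0, 2, size=n)
    # resolve conflicts: identical rows get the label of their first copy
    seen = {}
    for i in range(n):
        key = tuple(X[i])
        if key in seen:
            y[i] = y[seen[key]]
        else:
            seen[key] = i
    return X, y
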