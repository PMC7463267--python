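import numpy as np
import pytest

from pssmfold import PSSMProfile


def make_profile(rng, length=30, protein_id="P1", integer=True):
    """Random profile in the typical PSI-BLAST score range."""
    if integer:
        scores = rng.integers(-10, 13, size=(length, 20)).astype(float)
    else:
        scores = rng.normal(0, 3, size=(length, 20))
    letters = np.array(list("ARNDCQEGHILKMFPSTWYV"))
    seq = "".join(rng.choice(letters, size=length))
    return PSSMProfile(protein_id=protein_id, sequence=seq, scores=scores)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def profile(rng):
    return make_profile(rng, length=30)


def profile_from_columns(columns, protein_id="P"):
    """Profile whose first columns are given and the rest are zero."""
    columns = [np.asarray(c, dtype=float) for c in columns]
    length = len(columns[0])
    scores = np.zeros((length, 20))
    for i, col in enumerate(columns):
        scores[:, i] = col
    return PSSMProfile(
        protein_id=protein_id, sequence="A" * length, scores=scores
    )
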