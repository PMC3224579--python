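import numpy as np
import pytest

from sdrcov import DomainAlignment, ProfileSet
from sdrcov.alphabet import AA_TO_INDEX, N_RESIDUES


def make_delta_profiles(ids, residue_columns):
    """ProfileSet whose PWMs are delta distributions.

    ``residue_columns`` is a list of strings, one per PWM site, each giving
    the target residue per sequence (so ``["VVYY"]`` builds one site where
    sequences 1-2 prefer V and 3-4 prefer Y).
    """
    n = len(ids)
    w = len(residue_columns)
    mats = np.zeros((n, w, N_RESIDUES))
    for k, col in enumerate(residue_columns):
        assert len(col) == n
        for i, aa in enumerate(col):
            mats[i, k, AA_TO_INDEX[aa]] = 1.0
    return ProfileSet(ids=list(ids), matrices=mats)


@pytest.fixture
def delta_profiles():
    return make_delta_profiles


@pytest.fixture
def table1_alignment():
    """The four-sequence toy MSA used throughout as a worked example:
    sites 1-2 covary perfectly (A/T with V/Y), sites 3-4 are diverse and
    unrelated."""
    return DomainAlignment(
        ids=["I", "II", "III", "IV"],
        rows=["AVAC", "AVCD", "TYDE", "TYEC"],
    )


@pytest.fixture
def table1_site(table1_alignment):
    """Single-column alignment slice of the toy MSA (1-based site index)."""

    def _slice(j):
        return DomainAlignment(
            ids=table1_alignment.ids,
            rows=[row[j - 1] for row in table1_alignment.rows],
        )

    return _slice
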