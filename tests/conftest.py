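import numpy as np
import pytest

from taxonvet.authority import Authority, AuthorityEntry
from taxonvet.dwc_io import NameRecord
from taxonvet.name_assembly import Rank


def entry(canonical, status="accepted", accepted=None, rank=None):
    tokens = canonical.split()
    if rank is None:
        rank = {1: Rank.GENUS, 2: Rank.SPECIES}.get(len(tokens), Rank.INFRASPECIFIC)
    return AuthorityEntry(
        canonical=canonical,
        rank=rank,
        status=status,
        accepted_canonical=accepted or canonical,
        source="Test Checklist",
        source_url="https://example.org/test",
        source_date="2015-01-01",
    )


@pytest.fixture
def tit_authority():
    """Small authority with an accepted name, a junior synonym, and genera."""
    return Authority(
        [
            entry("Parus"),
            entry("Cyanistes"),
            entry("Parus major"),
            entry("Parus major newtoni"),
            entry("Cyanistes caeruleus"),
            entry("Parus caeruleus", status="synonym", accepted="Cyanistes caeruleus"),
            entry("Motacilla"),
            entry("Motacilla alba"),
            entry("Motacilla alba yarrellii"),
        ]
    )


@pytest.fixture
def clean_binomial_record():
    return NameRecord(
        id="r1",
        scientificName="Parus major",
        genus="Parus",
        specificEpithet="major",
        scientificNameAuthorship="Linnaeus, 1758",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160113)
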