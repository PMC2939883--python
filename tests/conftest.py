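import pytest

from cctpr import (
    default_profiles,
    default_thresholds,
    load_arabidopsis_metadata,
    load_arabidopsis_motifs,
    load_rice_motifs,
)


@pytest.fixture(scope="session")
def at_rows():
    return load_arabidopsis_motifs()


@pytest.fixture(scope="session")
def os_rows():
    return load_rice_motifs()


@pytest.fixture(scope="session")
def meta():
    return load_arabidopsis_metadata()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def thresholds(profiles):
    return default_thresholds(profiles)


@pytest.fixture(scope="session")
def at_triplets(at_rows):
    from cctpr.seqio import group_by_protein

    return group_by_protein(at_rows)


@pytest.fixture(scope="session")
def os_triplets(os_rows):
    from cctpr.seqio import group_by_protein

    return group_by_protein(os_rows)
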