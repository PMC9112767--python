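import pytest

from mitocall.reference import (
    RegionTrack,
    default_reference,
    find_homopolymer_regions,
    load_default_tracks,
)
from mitocall.simulate import default_haplogroup_panel


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture(scope="session")
def hp_track(ref):
    return RegionTrack("HP", intervals=find_homopolymer_regions(ref.seq))


@pytest.fixture(scope="session")
def tracks(ref):
    return load_default_tracks(ref)


@pytest.fixture(scope="session")
def panel(ref):
    return default_haplogroup_panel(ref)
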