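import numpy as np
import pytest

from sdscape import (filter_high_copy, mask_and_excise, place_reads,
                     profile_depth, call_wssd_intervals, self_align)
from sdscape.pipeline import build_fixture


@pytest.fixture(scope="session")
def small_fx():
    """Canonical small fixture (1 Mb, 3 chromosomes, 8 scored events)."""
    return build_fixture("small", seed=1)


@pytest.fixture(scope="session")
def small_products(small_fx):
    """All stage products for the small fixture, computed once."""
    fx = small_fx
    condensed, cmap = mask_and_excise(fx.reference, fx.repeats)
    initial = self_align(condensed, coord_map=cmap)
    cleaned = filter_high_copy(initial)
    placements = place_reads(fx.reads, fx.reference)
    profile = profile_depth(placements, fx.reference, fx.repeats,
                            exclude=cleaned.loci())
    wssd = call_wssd_intervals(profile)
    return {
        "fx": fx,
        "condensed": condensed,
        "cmap": cmap,
        "initial": initial,
        "cleaned": cleaned,
        "placements": placements,
        "profile": profile,
        "wssd": wssd,
        "chrom_lengths": {c: len(a) for c, a in fx.reference.items()},
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
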