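import numpy as np
import pytest

import cocryscreen as cs


@pytest.fixture(scope="session")
def library():
    return cs.fixture_library()


@pytest.fixture(scope="session")
def mc_ranking(library):
    """Full complementarity screen of the fixture library against the
    API, shared across tests (conformer embedding dominates its cost)."""
    lib = dict(library)
    api = lib.pop("cilnidipine")
    api_ens = cs.embed_conformers(api, 10, seed=2025)
    cof_ens = [
        cs.embed_conformers(m, cs.default_conformer_count(m, "coformer"), seed=2025)
        for m in lib.values()
    ]
    return cs.screen_mc(api_ens, cof_ens)


@pytest.fixture(scope="session")
def fig5_profiles():
    return cs.fig5_style_profiles(seed=0)


@pytest.fixture
def toy_conformer(library):
    """Build a bare conformer from explicit elements/coordinates, for
    geometric descriptor tests that do not touch the parent graph."""

    def build(elements, coords):
        return cs.molecules.Conformer(
            coordinates=np.asarray(coords, dtype=float),
            parent=library["p-toluenesulfonamide"],
            elements=tuple(elements),
        )

    return build
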