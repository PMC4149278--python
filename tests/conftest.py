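"""Shared fixtures: small deterministic panels sized for fast tests."""

import numpy as np
import pytest

from ervscreen.synthetic_data import PanelConfig, make_reference_panel


def small_panel_config(**overrides):
    """A compact panel: 12 elements, 6 loci, ~1.1 kb elements."""
    defaults = dict(
        n_elements=12,
        identity_range=(100.0, 90.0),
        ltr_length=120,
        internal_length=900,
        n_loci=6,
        locus_spacing=6000,
        flank=2500,
        guard_protect_k=6,
        n_recent_locus_elements=4,
        seed=11,
    )
    defaults.update(overrides)
    return PanelConfig(**defaults)


@pytest.fixture(scope="session")
def small_panel():
    return make_reference_panel(small_panel_config())


@pytest.fixture(scope="session")
def probe_interval(small_panel):
    """The guard window of the small panel, in element coordinates."""
    ltr_end = small_panel.element(small_panel.reference_id).ltr5[1]
    return (ltr_end + 40, ltr_end + 72)


@pytest.fixture(scope="session")
def probe_seq(small_panel, probe_interval):
    ref = small_panel.element(small_panel.reference_id)
    return ref.seq[probe_interval[0] : probe_interval[1]]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
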