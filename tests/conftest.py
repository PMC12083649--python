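"""Shared fixtures: small synthetic scenes and reference objects.

Everything is generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from spotscreen.chemistry import BarcodeSet, SgRNALibrary, default_pac_profile
from spotscreen.sim import SceneParams, simulate_scene


@pytest.fixture(scope="session")
def tiny_scene():
    """20x20 scene, error-free reads: fast end-to-end oracle."""
    params = SceneParams(
        grid=(20, 20), n_clones=6, clone_mean_size=12, umi_mean=8,
        panel=(80, 20, 10, 10), n_targets=8, n_ntc=1,
    )
    return simulate_scene(params, seed=7)


@pytest.fixture(scope="session")
def small_profile():
    """Deterministic hand-sized PAC profile (4x4 grid)."""
    set_a = BarcodeSet("A", ("AAAAAAAA", "CCCCCCCC", "GGGGGGGG", "TTTTTTTT"))
    set_b = BarcodeSet("B", ("ACACACAC", "CACACACA", "AGAGAGAG", "GAGAGAGA"))
    return default_pac_profile(set_a, set_b)


@pytest.fixture(scope="session")
def small_library():
    return SgRNALibrary(
        names=("sgS100A4", "sgMT1E", "sgNTC1"),
        spacers=(
            "ACGTACGTACGTACGTACGT",
            "TTTTCCCCGGGGAAAATTTT",
            "GACTGACTGACTGACTGACT",
        ),
        targets=("S100A4", "MT1E", ""),
        is_ntc=(False, False, True),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
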