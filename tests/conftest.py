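"""Shared fixtures: layouts, lookup databases, and rendered reference scenes.

Session-scoped where construction is expensive (the default-grid database
takes a few seconds; several rendered scenes are reused across modules).
"""

import numpy as np
import pytest

from bilicam import forward_model as fm
from bilicam import synthetic_scenes as sc
from bilicam import card_processing as cp


@pytest.fixture(scope="session")
def layout():
    return sc.default_layout("v3")


@pytest.fixture(scope="session")
def layout_v1():
    return sc.default_layout("v1")


@pytest.fixture(scope="session")
def small_db():
    """Coarse lookup database for fast unit tests."""
    grid = fm.GridSpec(
        bilirubin_umol_per_L=tuple(np.arange(0.0, 400.1, 25.0)),
        melanin_fraction=tuple(np.linspace(0.01, 0.15, 6)),
        blood_fraction=tuple(np.linspace(0.005, 0.05, 4)),
    )
    return fm.build_lookup(grid)


@pytest.fixture(scope="session")
def full_db():
    """The default-grid database used by the round-trip and QC suites."""
    return fm.build_lookup()


def make_spec(layout, bilirubin=150.0, melanin=0.05, blood=0.02, seed=0, **kw):
    """A scene spec under the canonical condition with sensible defaults."""
    defaults = dict(
        layout=layout,
        skin=fm.ChromophoreState(bilirubin, melanin, blood, 0.7),
        illuminant=fm.flat_illuminant(),
        camera=fm.default_camera(),
        card_id=2741,
        seed=seed,
    )
    defaults.update(kw)
    return sc.SceneSpec(**defaults)


@pytest.fixture(scope="session")
def clean_spec(layout):
    return make_spec(layout)


@pytest.fixture(scope="session")
def clean_scene(clean_spec):
    return sc.render_scene(clean_spec)


@pytest.fixture(scope="session")
def clean_obs(clean_scene, layout):
    return cp.observe_card(clean_scene.raster, layout)
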