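import numpy as np
import pytest

from vapordose.airway_transport import default_tree, simulate_puff
from vapordose.chem_props import thc_defaults
from vapordose.puff_profiles import (
    DEFAULT_POST_PUFF_VOLUME,
    DEFAULT_PUFF_VOLUME,
    build_exhalation,
    build_puff,
    standard_puff_timings,
)


@pytest.fixture(scope="session")
def thc():
    return thc_defaults()


@pytest.fixture(scope="session")
def tree():
    return default_tree()


def _run(kind, volume, shape, thc, tree, **kw):
    t_in, t_ex = standard_puff_timings(kind)
    puff = build_puff(kind, t_in, volume, shape=shape)
    exhale = build_exhalation(volume, t_ex)
    return simulate_puff(tree, thc, puff, exhale, C_inlet=1.0, **kw)


@pytest.fixture(scope="session")
def short_puff_result(thc, tree):
    return _run("short_puff", DEFAULT_PUFF_VOLUME, "half_sine", thc, tree)


@pytest.fixture(scope="session")
def long_puff_result(thc, tree):
    return _run("long_puff", DEFAULT_PUFF_VOLUME, "half_sine", thc, tree)


@pytest.fixture(scope="session")
def post_puff_result(thc, tree):
    return _run("post_puff", DEFAULT_POST_PUFF_VOLUME, "triangular", thc, tree)
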