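import warnings

import numpy as np
import pytest

import statewalk as sw


@pytest.fixture(scope="session")
def fixture_suite():
    """The standard 20-fixture ground-truth batch at a fixed seed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sw.synth.make_fixture_suite(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def two_domain_ensemble():
    """Two-state ensemble with a planted 16° / 3.5 Å axial inchworm step."""
    base, reg, _ = sw.synth.make_multidomain(2, 80, seed=7)
    moved, _ = sw.synth.apply_motion(
        base, reg, "dom2", 16.0, [1.0, 0.0, 0.0], [0.0, 0.0, 3.5], new_id="B"
    )
    return sw.synth.make_ensemble([("A", base, "ATP"), ("B", moved, "ADP")], reg)


@pytest.fixture()
def straight_duplex():
    model, regmap, _ = sw.synth.make_bdna("ACGTACGTACGTACGTACGTACGT", start_register=-14)
    return model, regmap
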