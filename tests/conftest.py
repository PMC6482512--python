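import math

import pytest

import rnadesign as rd
from rnadesign.oracle import toy_basepair_params, toy_stacking_params


@pytest.fixture(scope="session")
def bp_params():
    return toy_basepair_params()


@pytest.fixture(scope="session")
def st_params():
    return toy_stacking_params()


def boltzmann_instance(structures, n, gc_weight=1.0, energy_weights=(),
                       model=None, params=None):
    """Assemble the standard feature stack: GC + validity (+ energies)."""
    feats = [rd.gc_feature(n, weight=gc_weight), rd.validity_feature(structures)]
    for ell, (s, w) in enumerate(zip(structures, energy_weights), start=1):
        if model == "basepair":
            feats.append(rd.basepair_feature(s, params, f"E{ell}", weight=w))
        elif model == "stacking":
            feats.append(rd.stacking_feature(s, params, f"E{ell}", weight=w))
    return feats


@pytest.fixture(scope="session")
def e():
    return math.e
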