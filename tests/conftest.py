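import numpy as np
import pytest

import spinenano as sn


@pytest.fixture(scope="session")
def wt_model():
    return sn.wt_reference_model()


@pytest.fixture(scope="session")
def cs_model():
    return sn.cs_reference_model()


@pytest.fixture(scope="session")
def synapse_field():
    """One seeded two-channel synapse field with planted clusters."""
    params = sn.SmlmSimParams(seed=101)
    psd, target, truth = sn.gen_smlm_synapse(params)
    return params, psd, target, truth


@pytest.fixture(scope="session")
def wt_spine():
    """One seeded annotated spine at the wild-type zone models."""
    params = sn.EmSimParams(seed=202)
    annotation, truth = sn.gen_em_spine(params)
    return params, annotation, truth


@pytest.fixture(scope="session")
def wt_tracks(wt_model):
    """3000 seeded wild-type trajectories with ground-truth states."""
    params = sn.TrackSimParams(
        seed=303, D=wt_model["D"], A=wt_model["A"], n_tracks=3000
    )
    tracks, states = sn.gen_tracks(params)
    return params, tracks, states
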