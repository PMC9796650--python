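import numpy as np
import pytest

from resqa import synthdata


@pytest.fixture(scope="session")
def small_spec():
    return synthdata.SynthSpec(seed=7, length=40, n_decoys=8,
                               target_id="T0001")


@pytest.fixture(scope="session")
def small_native(small_spec):
    return synthdata.make_native(small_spec)


@pytest.fixture(scope="session")
def small_pool(small_spec, small_native):
    return synthdata.make_decoys(small_native, small_spec)


@pytest.fixture(scope="session")
def feature_dir(tmp_path_factory, small_spec, small_native, small_pool):
    """Companion feature files for every decoy of the small pool."""
    root = tmp_path_factory.mktemp("features")
    for decoy, profile in small_pool:
        synthdata.make_companions(small_native, decoy, profile, root,
                                  small_spec)
    return root


@pytest.fixture(scope="session")
def featurized_small(small_pool, feature_dir):
    """(mass2 inputs, graphs, true deviations) for the small pool."""
    from resqa import pipeline

    X_m, X_l, y = [], [], []
    for decoy, profile in small_pool:
        X_m.append(pipeline.featurize_model(decoy, feature_dir, "MASS2"))
        X_l.append(pipeline.featurize_model(decoy, feature_dir, "LAW"))
        y.append(profile.deviations)
    return X_m, X_l, y
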