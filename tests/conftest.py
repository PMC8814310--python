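"""Shared fixtures: synthetic sessions and a trained motion classifier."""

import numpy as np
import pytest

import armsmooth as am
from armsmooth import segmentation as seg


@pytest.fixture(scope="session")
def bilateral_spec():
    return am.MOVEMENT_CATALOGUE[0]  # sagittal bilateral elevation


@pytest.fixture(scope="session")
def bilateral_session(bilateral_spec):
    return am.simulate_session([bilateral_spec], rng_seed=3)


@pytest.fixture(scope="session")
def bilateral_kinematics(bilateral_session):
    mov = bilateral_session.movements[0]
    fs = bilateral_session.fs
    rest = slice(0, int(fs))
    subject = am.build_subject_frame(
        mov.sensors["head"].orient[rest], mov.sensors["back"].orient[rest]
    )
    kin_l = am.compute_kinematics(mov.sensors["left"], subject)
    kin_r = am.compute_kinematics(mov.sensors["right"], subject)
    return mov, kin_l, kin_r


@pytest.fixture(scope="session")
def motion_classifier(bilateral_kinematics):
    mov, kin_l, kin_r = bilateral_kinematics
    feats = seg.extract_features(kin_l, kin_r)
    labels = mov.ground_truth.binary_labels()
    clf, acc = seg.train_motion_classifier([feats], [labels], rng_seed=0)
    return clf, acc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
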