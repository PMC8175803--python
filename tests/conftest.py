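"""Shared fixtures: synthetic sessions are generated once per test run."""
from __future__ import annotations

import warnings

import numpy as np
import pytest

from gaitcmi import gait_events, sigprep, synth


@pytest.fixture(scope="session")
def default_config():
    return synth.SynthConfig(
        duration_s=30.0, speed_label=2.0, seed=1,
        coupling=[synth.Coupling("Cz", "Rt. TA", "LR", 0.8)],
    )


@pytest.fixture(scope="session")
def session(default_config):
    """One coupled 30 s session: (markers, recording, ground truth)."""
    return synth.generate_session(default_config)


@pytest.fixture(scope="session")
def prepped(session):
    """The default session through the full preprocessing chain."""
    markers, rec, gt = session
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, pmark, report = sigprep.preprocess(rec, markers, seed=0)
    return prec, pmark, report, gt


@pytest.fixture(scope="session")
def segmented(prepped):
    """Segmentations plus per-sample phase labels on the 1 kHz clock."""
    prec, pmark, _, gt = prepped
    segs = gait_events.segment_session(pmark)
    labels = gait_events.label_biosignal(segs, prec, pmark.rate)
    return segs, labels


def match_cycle(seg, gt, rate):
    """Ground-truth cycle index whose start is nearest a detected cycle."""
    start_t = seg.cycle.start / rate
    k = int(round(start_t * gt.cadence_hz))
    return k if 0 <= k < gt.n_cycles else None


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
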