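import warnings

import numpy as np
import pytest

from phagoscope import detect_eval, tracker
from phagoscope.synthgen import SynthConfig, generate_sequence


@pytest.fixture(scope="session")
def default_sequence():
    """One starved default-config sequence with ground truth (seed 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_sequence(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def fed_sequence():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_sequence(SynthConfig(seed=100, condition="fed", n_cells=12))


def truth_tracking_inputs(seq):
    """Per-frame truth detections, embeddings, and refs for the tracker."""
    dets, feats, refs = [], [], []
    for frame in seq.frames:
        d, r = tracker.truth_detections(frame.cells)
        rgb = frame.merged_rgb()
        f = [tracker.embed_cell(detect_eval.apply_mask(rgb, det.mask), det.mask) for det in d]
        dets.append(d)
        feats.append(f)
        refs.append(r)
    return dets, feats, refs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260917)
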