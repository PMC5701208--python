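import numpy as np
import pytest

from pfl import SynthParams, make_sample


@pytest.fixture(scope="session")
def default_samples():
    """Twenty synthetic samples under the standard study conditions."""
    return [make_sample(SynthParams(seed=s)) for s in range(1, 21)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def best_iou(truth_mask, candidates):
    """Highest IoU of a ground-truth island over recovered masks."""
    best = 0.0
    for m in candidates:
        inter = np.logical_and(truth_mask, m).sum()
        union = np.logical_or(truth_mask, m).sum()
        if union:
            best = max(best, inter / union)
    return best


def greedy_match(detected, truths, radius=1.5):
    """One-to-one nearest matching; returns number of true positives."""
    pairs = sorted(
        (np.hypot(d[0] - t[0], d[1] - t[1]), i, j)
        for i, d in enumerate(detected)
        for j, t in enumerate(truths)
    )
    used_d, used_t = set(), set()
    for dist, i, j in pairs:
        if dist > radius:
            break
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
    return len(used_t)
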