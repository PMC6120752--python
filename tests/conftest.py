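import numpy as np
import pytest

from dendroca import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_session():
    """A 120 s noiseless single-ROI session with default event statistics."""
    cfg = syn.SimConfig(duration=120.0, seed=1, noise_sigma=0.0)
    return syn.simulate_session(cfg)


@pytest.fixture(scope="session")
def snr5_sessions():
    """Sessions at the benchmark noise level (noise SD = mean amplitude / 5)."""
    out = []
    for seed in range(4):
        cfg = syn.SimConfig(duration=120.0, seed=seed, noise_sigma=0.223 / 5)
        out.append(syn.simulate_session(cfg))
    return out


def match_events(detected, truth, tol):
    """Greedy one-to-one matching of detected to true event times."""
    used = set()
    tp = 0
    for t in np.asarray(detected):
        d = np.abs(np.asarray(truth) - t)
        if d.size == 0:
            break
        j = int(np.argmin(d))
        if d[j] <= tol and j not in used:
            tp += 1
            used.add(j)
    return tp


def precision_recall(detected, truth, tol):
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.size == 0:
        return 0.0, 0.0
    tp = match_events(detected, truth, tol)
    return tp / detected.size, tp / truth.size
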