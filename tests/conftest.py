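import numpy as np
import pytest

import spectsync as ss

LATERAL_WALL = (5, 6, 11, 12, 16)  # basal+mid inferolateral/anterolateral + apical lateral


@pytest.fixture(scope="session")
def sync_spec():
    """Synchronous, noise-free default phantom."""
    return ss.PhantomSpec(poisson=False)


@pytest.fixture(scope="session")
def sync_study(sync_spec):
    return ss.generate_study(sync_spec)


@pytest.fixture(scope="session")
def lateral_spec():
    """Noise-free phantom with the lateral wall delayed by +36 degrees."""
    delay = [0.0] * 17
    for s in LATERAL_WALL:
        delay[s - 1] = 36.0
    return ss.PhantomSpec(poisson=False, delay_deg=tuple(delay))


@pytest.fixture(scope="session")
def lateral_study(lateral_spec):
    return ss.generate_study(lateral_spec)


@pytest.fixture(scope="session")
def noisy_study():
    return ss.generate_study(ss.PhantomSpec(seed=7))


def lstsq_harmonics(values, order):
    """Independent least-squares oracle for the cosine-series fit."""
    v = np.asarray(values, dtype=float)
    n = v.size
    k = np.arange(n)
    cols = [np.ones(n)]
    for h in range(1, order + 1):
        cols += [np.cos(2 * np.pi * h * k / n), np.sin(2 * np.pi * h * k / n)]
    beta, *_ = np.linalg.lstsq(np.stack(cols, axis=1), v, rcond=None)
    out = {"a0": beta[0]}
    for h in range(1, order + 1):
        c, s = beta[2 * h - 1], beta[2 * h]
        out[f"a{h}"] = float(np.hypot(c, s))
        out[f"phi{h}"] = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return out
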