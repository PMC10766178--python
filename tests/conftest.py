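import numpy as np
import pytest

import lfpmatch as lm


@pytest.fixture(scope="session")
def whorl_field():
    """Analytic whorl orientation field, 256 px, per-pixel resolution."""
    return lm.make_orientation_field("whorl", core=(128, 128), size=256, block_size=1)


@pytest.fixture(scope="session")
def rendered_whorl(whorl_field):
    """Clean rendered whorl pattern (gray + exact ridge mask), seed 0."""
    return lm.render_ridge_image(
        whorl_field, ridge_period=9.0, seed=0, pattern="whorl", core=(128, 128)
    )


@pytest.fixture(scope="session")
def synth_pair():
    """One default synthetic control/sample pair with ground truth."""
    return lm.generate_pair(lm.SynthParams(seed=7))


def greedy_match(found, truth, tol=5.0):
    """Location-based one-to-one matching; returns (recall, precision)."""
    F = found.coords()
    T = truth.coords()
    if len(F) == 0 or len(T) == 0:
        return 0.0, 0.0
    d = np.hypot(F[:, 0, None] - T[None, :, 0], F[:, 1, None] - T[None, :, 1])
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_f, used_t, hits = set(), set(), 0
    for i, j in order:
        if d[i, j] > tol:
            break
        if i in used_f or j in used_t:
            continue
        used_f.add(i)
        used_t.add(j)
        hits += 1
    return hits / len(T), hits / len(F)
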