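import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---- independent brute-force oracles for the moving-window indices ----

def naive_pf(mask, valid, window):
    """Per-pixel double-loop forest density: N_f / N_w over the clipped window."""
    k = window // 2
    nr, nc = mask.shape
    out = np.full((nr, nc), np.nan)
    for i in range(nr):
        for j in range(nc):
            nf = nw = 0
            for r in range(max(0, i - k), min(nr, i + k + 1)):
                for c in range(max(0, j - k), min(nc, j + k + 1)):
                    if valid[r, c]:
                        nw += 1
                        nf += int(mask[r, c] == 1)
            if nw:
                out[i, j] = nf / nw
    return out


def naive_pff(mask, valid, window):
    """Per-pixel pair enumeration: both-forest / (≥1-forest) valid cardinal pairs."""
    k = window // 2
    nr, nc = mask.shape
    out = np.full((nr, nc), np.nan)
    for i in range(nr):
        for j in range(nc):
            r0, r1 = max(0, i - k), min(nr, i + k + 1)
            c0, c1 = max(0, j - k), min(nc, j + k + 1)
            both = any_ = 0
            for r in range(r0, r1):
                for c in range(c0, c1):
                    for dr, dc in ((0, 1), (1, 0)):
                        r2, c2 = r + dr, c + dc
                        if r2 >= r1 or c2 >= c1:
                            continue
                        if not (valid[r, c] and valid[r2, c2]):
                            continue
                        f1, f2 = mask[r, c] == 1, mask[r2, c2] == 1
                        if f1 and f2:
                            both += 1
                        if f1 or f2:
                            any_ += 1
            if any_:
                out[i, j] = both / any_
    return out


@pytest.fixture
def naive_pf_oracle():
    return naive_pf


@pytest.fixture
def naive_pff_oracle():
    return naive_pff
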