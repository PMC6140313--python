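"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from thermolimit.simulate import SimParams, calibration_params


def brute_moving_median(
    x: np.ndarray, w: int, alignment: str, max_missing_frac: float = 0.5
) -> np.ndarray:
    """Independent per-window median: explicit loop, no rolling machinery.

    Mirrors the contract: window [i - floor(w/2), i + ceil(w/2) - 1]
    (centered) or [i - w + 1, i] (trailing) clipped to the valid range;
    median over present values; missing output when more than
    max_missing_frac of the w slots hold a missing in-range sample.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.empty(n)
    for i in range(n):
        if alignment == "centered":
            lo, hi = i - w // 2, i + (w + 1) // 2 - 1
        else:
            lo, hi = i - w + 1, i
        window = x[max(lo, 0) : min(hi, n - 1) + 1]
        n_miss = int(np.isnan(window).sum())
        present = window[~np.isnan(window)]
        if n_miss / w > max_missing_frac or present.size == 0:
            out[i] = np.nan
        else:
            out[i] = float(np.median(present))
    return out


def random_series_with_missing(
    rng: np.random.Generator, max_len: int = 50, missing_frac: float = 0.2
) -> np.ndarray:
    n = int(rng.integers(1, max_len + 1))
    x = rng.random(n)
    x[rng.random(n) < missing_frac] = np.nan
    return x


def fast_sim(seed: int = 0, **overrides) -> SimParams:
    """Small, short calibration-design parameters for quick unit tests.

    Scaled-down immobilisation times and sample counts; the velocity process
    itself keeps the default structure.
    """
    defaults = dict(
        n_per_treatment=8,
        t_star_base=400.0,
        treatments={"17": 0.0, "22": 150.0},
        sigma_t=60.0,
        tail_s=60.0,
        intro_spacing_s=2.0,
    )
    defaults.update(overrides)
    return calibration_params(seed=seed, **defaults)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
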