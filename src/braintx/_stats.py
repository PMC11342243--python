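"""Small shared statistical helpers."""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


def two_sample_t(
    a: np.ndarray,
    b: np.ndarray,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sided two-sample t-test of ``a`` (rows=samples) vs ``b``.

    Degenerate columns where both groups have zero variance are resolved by
    the mean difference: p = 0 (t signed infinite) if the means differ,
    p = 1 (t = 0) otherwise.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if degenerate.any():
        log.warning("%d zero-variance columns resolved by mean comparison", int(degenerate.sum()))
        diff = a.mean(axis=0) - b.mean(axis=0)
        t = np.where(degenerate, np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0)), t)
        p = np.where(degenerate, np.where(diff != 0, 0.0, 1.0), p)
    # Welch with one degenerate group can still yield nan; fall back likewise.
    bad = ~np.isfinite(p)
    if bad.any():
        diff = a.mean(axis=0) - b.mean(axis=0)
        t = np.where(bad, np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0)), t)
        p = np.where(bad, np.where(diff != 0, 0.0, 1.0), p)
    return t, p


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of a single root seed.

    Every stochastic stage draws from its own substream so stages can be
    re-run independently without perturbing each other.
    """
    import zlib

    if seed < 0:
        raise ValueError("seed must be nonnegative")
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
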