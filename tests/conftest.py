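"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity from first principles
(grid marking, clause-by-clause scans, exhaustive enumeration) without
touching the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def grid_coverage(event_times, window_s=1800, duration_s=86400, wrap=True) -> float:
    """Brute-force coverage on a 1-second grid.

    Marks every integer second lying in some [t, t + window) and counts.
    Exact for integer event times and window length.
    """
    d = int(duration_s)
    covered = np.zeros(d, dtype=bool)
    for t in event_times:
        a = int(np.ceil(t))
        b = int(np.ceil(t + window_s))
        if b <= d:
            covered[a:b] = True
        elif wrap:
            covered[a:d] = True
            covered[0 : b - d] = True
        else:
            covered[a:d] = True
    return covered.sum() / d


def bruteforce_detect(rr, reduction_threshold=0.20, baseline_len=10, baseline_tolerance=0.10):
    """Clause-by-clause re-evaluation of the detection rule, plain Python.

    Returns the list of candidate interval indices.
    """
    import statistics

    L = baseline_len
    out = []
    for i in range(L + 1, len(rr)):
        if not rr[i] < (1 - reduction_threshold) * rr[i - 1]:
            continue
        window = [float(v) for v in rr[i - L : i]]
        med = statistics.median(window)
        if all(abs(r - med) <= baseline_tolerance * med for r in window):
            out.append(i)
    return out


def random_rr_series(rng, n) -> np.ndarray:
    """RR series with sinus runs, jitter, and sporadic premature drops."""
    base = rng.uniform(0.5, 1.1)
    rr = base * (1.0 + rng.normal(0.0, rng.uniform(0.0, 0.08), size=n))
    rr = np.clip(rr, 0.25, None)
    # sprinkle premature beats (short interval, then a pause)
    n_ect = rng.poisson(max(1, n // 80))
    for i in rng.integers(12, n - 1, size=n_ect) if n > 13 else []:
        rr[i] = rr[i - 1] * rng.uniform(0.45, 0.85)
        rr[i + 1] = rr[i - 1] * rng.uniform(1.0, 1.5)
    return rr


def enumerate_bootstrap_quantiles(values, alpha=0.05):
    """Exhaustive bootstrap of the mean: all n^n resamples, tiny n only."""
    import itertools

    values = np.asarray(values, dtype=float)
    n = len(values)
    means = [
        np.mean(values[list(tup)]) for tup in itertools.product(range(n), repeat=n)
    ]
    return tuple(np.quantile(means, [alpha / 2, 1 - alpha / 2]))


def analytic_kappa(p_true, confusion_a, confusion_b) -> float:
    """Cohen's kappa implied by the joint label distribution of two raters."""
    p_true = np.asarray(p_true, dtype=float)
    A = np.asarray(confusion_a, dtype=float)
    B = np.asarray(confusion_b, dtype=float)
    joint = np.einsum("k,ki,kj->ij", p_true, A, B)
    p_o = np.trace(joint)
    p_e = joint.sum(axis=1) @ joint.sum(axis=0)
    return (p_o - p_e) / (1 - p_e)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
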