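"""Shared fixtures: phantoms are rendered once per session."""

import numpy as np
import pytest

from rootcell import PhantomSpec, PipelineParams, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Default noiseless circular phantom (root radius 120, 512x512)."""
    spec = PhantomSpec(noise_sigma=0.0)
    img, truth = generate_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(noise_sigma=10.0, rng_seed=5)
    img, truth = generate_phantom(spec)
    return spec, img, truth


@pytest.fixture()
def params():
    return PipelineParams()


def brute_force_otsu(pixels) -> int:
    """Independent exhaustive Otsu: try all 256 splits with a plain loop.

    Tied thresholds (identical class partitions) resolve to the middle of
    the tied range.
    """
    v = np.asarray(pixels).ravel().astype(np.float64)
    variances = {}
    for t in range(256):
        lo, hi = v[v <= t], v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / v.size, hi.size / v.size
        variances[t] = w0 * w1 * (lo.mean() - hi.mean()) ** 2
    if not variances:
        return int(v[0])
    best = max(variances.values())
    ties = sorted(t for t, var in variances.items() if var == best)
    return ties[len(ties) // 2]


def _plateau_runs(x, periodic):
    """Maximal equal-value runs as (start, length), circular if periodic."""
    n = len(x)
    if periodic:
        starts = [i for i in range(n) if x[i] != x[(i - 1) % n]]
        if not starts:
            return []
        runs = []
        for k, s in enumerate(starts):
            e = starts[(k + 1) % len(starts)]
            length = (e - s) % n or n
            runs.append((s, length))
        return runs
    runs, s = [], 0
    for i in range(1, n + 1):
        if i == n or x[i] != x[s]:
            runs.append((s, i - s))
            s = i
    return runs


def brute_force_prominence_maxima(profile, tol, periodic=False):
    """O(n^2) oracle: local maxima with prominence >= tol.

    A plateau is a maximum when both circular/linear neighbors are lower
    (boundary plateaus are not maxima in the non-periodic case); its
    position is start + (len-1)//2.  Prominence = height minus the higher
    of the two bounding minima reachable without crossing a larger value.
    """
    x = [float(v) for v in profile]
    n = len(x)
    out = []
    for (s, length) in _plateau_runs(x, periodic):
        e = (s + length - 1) % n if periodic else s + length - 1
        if periodic:
            if length == n:
                continue
            left_nb, right_nb = x[(s - 1) % n], x[(e + 1) % n]
        else:
            if s == 0 or e == n - 1:
                continue
            left_nb, right_nb = x[s - 1], x[e + 1]
        peak = x[s]
        if left_nb >= peak or right_nb >= peak:
            continue
        bases = []
        for step in (-1, +1):
            i = s if step < 0 else e
            lowest = peak
            for _ in range(n):
                i = (i + step) % n if periodic else i + step
                if not periodic and not (0 <= i < n):
                    break
                if x[i] > peak:
                    break
                lowest = min(lowest, x[i])
            bases.append(lowest)
        prom = peak - max(bases)
        if prom >= tol:
            out.append((s + (length - 1) // 2) % n if periodic else s + (length - 1) // 2)
    return sorted(out)
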