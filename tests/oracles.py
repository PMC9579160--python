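"""Independent reference implementations used to check the package.

These are deliberately naive (exhaustive enumeration, closed forms, direct
Monte Carlo) and share no code with the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def exhaustive_segmentation(
    x: np.ndarray,
    max_steps: int = 2,
    min_seg: int = 5,
    tol: float = 1e-9,
) -> tuple[int, ...]:
    """Least-squares segmentation by brute force over boundary placements.

    Returns the boundary set of the fewest steps whose piecewise-constant
    fit has (numerically) zero residual; intended for noiseless inputs with
    a known maximum number of steps.
    """
    x = np.asarray(x, dtype=float)
    n = x.size

    def rss(seg: np.ndarray) -> float:
        return float(np.sum((seg - seg.mean()) ** 2))

    last_best: tuple[float, tuple[int, ...]] | None = None
    for k in range(0, max_steps + 1):
        candidates = []
        for bs in itertools.combinations(range(min_seg, n - min_seg + 1), k):
            if any(b2 - b1 < min_seg for b1, b2 in zip(bs, bs[1:])):
                continue
            edges = (0,) + bs + (n,)
            total = sum(rss(x[a:b]) for a, b in zip(edges, edges[1:]))
            candidates.append((total, bs))
        if not candidates:
            continue
        total, bs = min(candidates)
        last_best = (total, bs)
        if total < tol:
            return bs
    assert last_best is not None
    return last_best[1]


def sphere_pofr_mc(radius: float, r_grid: np.ndarray, n_samples: int = 200_000,
                   seed: int = 0) -> np.ndarray:
    """Pair-distance density of a uniform solid sphere by direct Monte Carlo."""
    rng = np.random.default_rng(seed)

    def uniform_ball(n):
        pts = rng.uniform(-radius, radius, size=(int(2.5 * n), 3))
        pts = pts[np.sum(pts**2, axis=1) <= radius**2]
        return pts[:n]

    a = uniform_ball(n_samples)
    b = uniform_ball(n_samples)
    d = np.linalg.norm(a - b, axis=1)
    width = r_grid[1] - r_grid[0]
    edges = np.concatenate([r_grid - width / 2, [r_grid[-1] + width / 2]])
    dens, _ = np.histogram(d, bins=edges, density=True)
    return dens


def truncated_exp_mean(tau: float, window: float) -> float:
    """Mean of Exponential(tau) conditioned on [0, window] (closed form)."""
    z = window / tau
    return tau - window * np.exp(-z) / (1.0 - np.exp(-z))
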