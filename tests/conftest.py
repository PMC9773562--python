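"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: thresholds
are re-derived by exhaustive criterion search over all 256 levels, Feret
diameters by a rotation sweep over raw boundary pixels (no convex hull),
connected components by an explicit flood fill, and the convex-hull area by
gift wrapping plus polygon rasterization.
"""

from __future__ import annotations

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# synthetic blobs
# ---------------------------------------------------------------------------

def random_blob(rng: np.random.Generator, canvas: int = 90) -> np.ndarray:
    """A random filled blob: union of 1-3 overlapping rotated ellipses."""
    rr, cc = np.mgrid[0:canvas, 0:canvas]
    mask = np.zeros((canvas, canvas), bool)
    n_lobes = rng.integers(1, 4)
    cy0, cx0 = canvas / 2, canvas / 2
    for _ in range(n_lobes):
        a = rng.uniform(10, canvas * 0.4)
        b = rng.uniform(5, a)
        th = rng.uniform(0, np.pi)
        cy = cy0 + rng.uniform(-canvas * 0.08, canvas * 0.08)
        cx = cx0 + rng.uniform(-canvas * 0.08, canvas * 0.08)
        u = (cc - cx) * np.cos(th) + (rr - cy) * np.sin(th)
        v = -(cc - cx) * np.sin(th) + (rr - cy) * np.cos(th)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


# ---------------------------------------------------------------------------
# threshold oracles: exhaustive search of the published criteria
# ---------------------------------------------------------------------------

def kapur_criterion(hist: np.ndarray, t: int) -> float:
    p = hist / hist.sum()
    p0, p1 = p[: t + 1].sum(), p[t + 1 :].sum()
    if p0 <= 0 or p1 <= 0:
        return -np.inf
    lo = p[: t + 1][p[: t + 1] > 0] / p0
    hi = p[t + 1 :][p[t + 1 :] > 0] / p1
    return float(-(lo * np.log(lo)).sum() - (hi * np.log(hi)).sum())


def brute_force_max_entropy(hist: np.ndarray) -> int:
    crits = [kapur_criterion(hist, t) for t in range(256)]
    return int(np.argmax(crits))


def huang_fuzziness(hist: np.ndarray, t: int) -> float:
    g = np.arange(256.0)
    nz = np.flatnonzero(hist)
    c = float(nz[-1] - nz[0])
    n0 = hist[: t + 1].sum()
    n1 = hist[t + 1 :].sum()
    if n0 <= 0 or n1 <= 0:
        return np.inf
    mu0 = (hist[: t + 1] * g[: t + 1]).sum() / n0
    mu1 = (hist[t + 1 :] * g[t + 1 :]).sum() / n1
    total = 0.0
    for gv in nz:
        mu = mu0 if gv <= t else mu1
        u = 1.0 / (1.0 + abs(gv - mu) / c)
        if 0 < u < 1:
            total += hist[gv] * (-(u * np.log(u) + (1 - u) * np.log(1 - u)))
    return float(total)


def brute_force_huang(hist: np.ndarray) -> int:
    fuzz = [huang_fuzziness(hist, t) for t in range(256)]
    return int(np.argmin(fuzz))


def two_gaussian_image(rng: np.random.Generator, n: int = 10_000) -> np.ndarray:
    a = rng.normal(60, 15, n // 2)
    b = rng.normal(180, 15, n - n // 2)
    img = np.clip(np.round(np.concatenate([a, b])), 0, 255)
    return img.reshape(100, -1)


# ---------------------------------------------------------------------------
# Feret oracle: raw boundary pixels, dense rotation sweep, no hull shortcut
# ---------------------------------------------------------------------------

def feret_sweep_oracle(mask: np.ndarray, step_deg: float = 0.1):
    pts = np.argwhere(mask).astype(float)
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = pts @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    # the max caliper over a half-turn sweep underestimates the true max
    # pairwise distance by at most the angular discretization; refine by
    # the exact pairwise maximum on the sweep's extreme points
    extremes = np.unique(
        np.concatenate([proj.argmax(axis=0), proj.argmin(axis=0)])
    )
    ep = pts[extremes]
    diff = ep[:, None, :] - ep[None, :, :]
    feret = float(np.sqrt((diff**2).sum(-1)).max())
    return feret, float(widths.min())


# ---------------------------------------------------------------------------
# connected components oracle: iterative flood fill (8-connectivity)
# ---------------------------------------------------------------------------

def flood_fill_count(mask: np.ndarray, min_area: int = 1) -> int:
    mask = mask.copy()
    h, w = mask.shape
    count = 0
    for start in zip(*np.nonzero(mask)):
        if not mask[start]:
            continue
        stack, size = [start], 0
        mask[start] = False
        while stack:
            r, c = stack.pop()
            size += 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        mask[rr, cc] = False
                        stack.append((rr, cc))
        if size >= min_area:
            count += 1
    return count


# ---------------------------------------------------------------------------
# convex hull area oracle: gift wrapping + shoelace + pixel-count convention
# ---------------------------------------------------------------------------

def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    pts = [tuple(p) for p in np.unique(points, axis=0)]
    if len(pts) < 3:
        return np.asarray(pts, float)
    start = min(pts)
    hull = [start]
    current = start
    while True:
        candidate = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = (candidate[0] - current[0]) * (p[1] - current[1]) - (
                candidate[1] - current[1]
            ) * (p[0] - current[0])
            if cross < 0 or (
                cross == 0
                and np.hypot(p[0] - current[0], p[1] - current[1])
                > np.hypot(candidate[0] - current[0], candidate[1] - current[1])
            ):
                candidate = p
        if candidate == start:
            break
        hull.append(candidate)
        current = candidate
    return np.asarray(hull, float)


def hull_pixel_area_oracle(mask: np.ndarray) -> float:
    """Lattice-point count of the filled convex hull, via gift wrapping,
    the shoelace formula and Pick's theorem (interior + boundary lattice
    points of a lattice polygon = A + B/2 + 1)."""
    from math import gcd

    hull = gift_wrap_hull(np.argwhere(mask))
    if hull.shape[0] < 3:
        return float(np.asarray(mask).sum())
    x, y = hull[:, 0], hull[:, 1]
    area2 = abs(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )
    boundary = sum(
        gcd(int(abs(x[i] - x[(i + 1) % len(x)])), int(abs(y[i] - y[(i + 1) % len(y)])))
        for i in range(len(x))
    )
    return area2 / 2.0 + boundary / 2.0 + 1.0
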