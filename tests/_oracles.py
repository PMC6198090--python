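"""Independent brute-force / first-principles oracles used across tests.

These deliberately avoid the library code paths (and the libraries they
delegate to) so each check is a genuine dual route.
"""

from __future__ import annotations

import numpy as np


def crossing_number_inside(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd ray casting, vectorised over points; boundary not special-cased."""
    pts = np.atleast_2d(points)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xint)
    return inside


def mc_polygon_area(vertices: np.ndarray, n_samples: int, seed: int) -> float:
    """Rejection-sampling area estimate against the bounding box."""
    rng = np.random.default_rng(seed)
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_samples, 2))
    frac = crossing_number_inside(pts, vertices).mean()
    return float(frac * np.prod(hi - lo))


def fan_triangulation_area(vertices: np.ndarray) -> float:
    """Signed triangle fan from the centroid; valid for any simple polygon."""
    c = vertices.mean(axis=0)
    total = 0.0
    n = len(vertices)
    for i in range(n):
        a = vertices[i] - c
        b = vertices[(i + 1) % n] - c
        total += 0.5 * (a[0] * b[1] - a[1] * b[0])
    return abs(total)


def brute_force_feret(vertices: np.ndarray) -> float:
    """Max distance over every vertex pair (not only hull vertices)."""
    best = 0.0
    for i in range(len(vertices)):
        for j in range(i + 1, len(vertices)):
            d = float(np.hypot(*(vertices[i] - vertices[j])))
            best = max(best, d)
    return best


def sample_sd(values) -> float:
    v = np.asarray(values, dtype=float)
    m = v.mean()
    return float(np.sqrt(((v - m) ** 2).sum() / (len(v) - 1)))


def zscores(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return (v - v.mean()) / sample_sd(v)


def paired_t(a, b) -> tuple[float, float]:
    """Paired t from first principles (mean/SD of differences)."""
    from scipy.stats import t as t_dist

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    t = d.mean() / (sample_sd(d) / np.sqrt(n))
    p = 2 * t_dist.sf(abs(t), n - 1)
    return float(t), float(p)


def anova_f(groups) -> tuple[float, float]:
    """One-way ANOVA from explicit sums of squares."""
    from scipy.stats import f as f_dist

    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), float(f_dist.sf(f, df1, df2))


def bh_stepup_significant(p: np.ndarray, q: float) -> np.ndarray:
    """Definition-level BH: largest k with p_(k) <= k*q/m, reject those."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    sig = np.zeros(m, dtype=bool)
    sig[order[:k_star]] = True
    return sig


def mannwhitney_u(a, b) -> float:
    """U statistic by exhaustive pair comparison (ties counted 0.5)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def star_polygon(n_vertices: int, seed: int,
                 r_min: float = 1.0, r_max: float = 3.0) -> np.ndarray:
    """Random simple (star-shaped) polygon around the origin."""
    rng = np.random.default_rng(seed)
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # enforce distinct angles so edges never degenerate
    while np.any(np.diff(angles) < 1e-3):
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(r_min, r_max, n_vertices)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
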