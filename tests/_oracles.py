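"""Independent brute-force oracles used to verify the package's statistics
and kinematics. Deliberately naive: explicit loops and defining sums, no
shared code with the implementation under test."""

from __future__ import annotations

import itertools
import math

import numpy as np


def mk_s_brute(y) -> int:
    """Mann–Kendall S by explicit pair enumeration."""
    y = list(map(float, y))
    s = 0
    for i in range(len(y)):
        for j in range(i + 1, len(y)):
            if y[j] > y[i]:
                s += 1
            elif y[j] < y[i]:
                s -= 1
    return s


def mk_exact_distribution(n: int) -> dict[int, int]:
    """Counts of S over all n! orderings of n distinct values."""
    counts: dict[int, int] = {}
    for perm in itertools.permutations(range(n)):
        s = mk_s_brute(perm)
        counts[s] = counts.get(s, 0) + 1
    return counts


def mk_exact_p(y, dist: dict[int, int] | None = None) -> float:
    """Exact two-sided permutation p-value P(|S| >= |S_obs|) for tie-free y."""
    n = len(y)
    if dist is None:
        dist = mk_exact_distribution(n)
    s_obs = abs(mk_s_brute(y))
    total = sum(dist.values())
    hits = sum(c for s, c in dist.items() if abs(s) >= s_obs)
    return hits / total


def pairwise_slope_list(t, y) -> list[float]:
    out = []
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            if t[j] != t[i]:
                out.append((y[j] - y[i]) / (t[j] - t[i]))
    return out


def theil_sen_brute(t, y) -> float:
    slopes = sorted(pairwise_slope_list(t, y))
    n = len(slopes)
    mid = n // 2
    return slopes[mid] if n % 2 else 0.5 * (slopes[mid - 1] + slopes[mid])


def pettitt_brute(y) -> tuple[int, int, list[int]]:
    """(K, tau_index_1based, U list) by the defining double sum."""
    n = len(y)
    U = []
    for t in range(1, n):
        u = 0
        for i in range(t):
            for j in range(t, n):
                if y[j] > y[i]:
                    u += 1
                elif y[j] < y[i]:
                    u -= 1
        U.append(u)
    K = max(abs(u) for u in U)
    tau = next(t for t, u in enumerate(U, start=1) if abs(u) == K)
    return K, tau, U


def rankdata_avg(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(t, y) -> float:
    """rho as Pearson correlation of average ranks, by definition."""
    rt, ry = rankdata_avg(list(t)), rankdata_avg(list(y))
    n = len(rt)
    mt, my = sum(rt) / n, sum(ry) / n
    num = sum((a - mt) * (b - my) for a, b in zip(rt, ry))
    den = math.sqrt(sum((a - mt) ** 2 for a in rt) * sum((b - my) ** 2 for b in ry))
    return num / den


def convex_hull_area_brute(points) -> float:
    """Monotone-chain hull + shoelace, on unique points."""
    pts = sorted(set((float(x), float(y)) for x, y in points))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        return 0.0
    area = 0.0
    for (x1, y1), (x2, y2) in zip(hull, hull[1:] + hull[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def path_length_brute(segments_xy) -> float:
    total = 0.0
    for xy in segments_xy:
        for a, b in zip(xy[:-1], xy[1:]):
            total += math.hypot(b[0] - a[0], b[1] - a[1])
    return total


def finite_diff_metrics_brute(segments_xy, fps: float) -> dict[str, float]:
    """Per-step speed/acceleration/jerk magnitudes by explicit differencing
    within each segment; returns their means (RMS for jerk)."""
    speeds, accs, jerks = [], [], []
    for xy in segments_xy:
        xy = np.asarray(xy, float)
        if len(xy) >= 2:
            v = np.diff(xy, axis=0) * fps
            speeds.extend(np.hypot(v[:, 0], v[:, 1]))
            if len(v) >= 2:
                a = np.diff(v, axis=0) * fps
                accs.extend(np.hypot(a[:, 0], a[:, 1]))
                if len(a) >= 2:
                    j = np.diff(a, axis=0) * fps
                    jerks.extend(np.hypot(j[:, 0], j[:, 1]))
    out = {}
    out["avg_velocity"] = float(np.mean(speeds)) if speeds else math.nan
    out["avg_acceleration"] = float(np.mean(accs)) if accs else math.nan
    out["rms_jerk"] = (
        float(np.sqrt(np.mean(np.square(jerks)))) if jerks else math.nan
    )
    return out
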