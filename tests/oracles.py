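"""Independent brute-force re-implementations used as test oracles.

Everything here is written as plain loops over points, deliberately sharing
no code with the package, so agreement is evidence and not tautology.
"""

from __future__ import annotations

import math
from itertools import combinations


def speeds_loop(times, positions):
    """Per-interval speeds in μm/min by explicit loops."""
    out = []
    for i in range(len(times) - 1):
        d = math.sqrt(sum((positions[i + 1][k] - positions[i][k]) ** 2
                          for k in range(3)))
        out.append(d / (times[i + 1] - times[i]) * 60.0)
    return out


def mean_velocity_loop(times, positions):
    s = speeds_loop(times, positions)
    return sum(s) / len(s)


def path_length_loop(positions):
    total = 0.0
    for i in range(len(positions) - 1):
        total += math.sqrt(sum((positions[i + 1][k] - positions[i][k]) ** 2
                               for k in range(3)))
    return total


def net_displacement_loop(positions):
    return math.sqrt(sum((positions[-1][k] - positions[0][k]) ** 2
                         for k in range(3)))


def meandering_loop(positions):
    pl = path_length_loop(positions)
    if pl == 0.0:
        return 0.0
    return net_displacement_loop(positions) / pl


def arrest_index_loop(times, positions, threshold=2.0):
    s = speeds_loop(times, positions)
    num = den = 0.0
    for i, sp in enumerate(s):
        dt = times[i + 1] - times[i]
        den += dt
        if sp <= threshold:
            num += dt
    return num / den


def arrest_episodes_loop(times, positions, threshold=2.0):
    s = speeds_loop(times, positions)
    count = 0
    prev_below = False
    for sp in s:
        below = sp <= threshold
        if below and not prev_below:
            count += 1
        prev_below = below
    return count


def vessel_distance_dense(point, centerline, radius, n_samples=20001):
    """Distance to a vessel surface by densely sampling the polyline."""
    best = float("inf")
    for a, b in zip(centerline[:-1], centerline[1:]):
        for j in range(n_samples):
            t = j / (n_samples - 1)
            q = [a[k] + t * (b[k] - a[k]) for k in range(3)]
            d = math.sqrt(sum((point[k] - q[k]) ** 2 for k in range(3)))
            best = min(best, d)
    return max(best - radius, 0.0)


def mann_whitney_exact_enumeration(a, b):
    """Two-sided exact Mann–Whitney p by enumerating every split of the
    pooled sample into groups of sizes |a| and |b| (tie-free data only)."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs no ties"
    n_a = len(a)

    def u_stat(sample_a, sample_b):
        u = 0
        for x in sample_a:
            for y in sample_b:
                if x > y:
                    u += 1
        return u

    u_obs = u_stat(a, b)
    n_ab = n_a * len(b)
    # two-sided: P(min(U, n_ab - U) <= min(u_obs, n_ab - u_obs))
    crit = min(u_obs, n_ab - u_obs)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = u_stat(sa, sb)
        if min(u, n_ab - u) <= crit:
            count += 1
        total += 1
    return count / total


def kruskal_h_by_ranks(groups):
    """H statistic from explicit rank sums (no ties assumed)."""
    pooled = sorted(x for g in groups for x in g)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(pooled)
    h = 0.0
    for g in groups:
        r = sum(rank[x] for x in g)
        h += r * r / len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
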