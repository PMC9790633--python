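"""Shared test utilities: truth matching and independent oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np

TWO_PI = 2 * math.pi


def angdist(a: float, b: float) -> float:
    d = abs(a - b) % TWO_PI
    return min(d, TWO_PI - d)


def match_measurements_to_truth(measurements, truth_vessels):
    """Pair each measurement with the closest-angle truth vessel.

    Measured anchor angles sit slightly outward of the disc-edge truth
    angle for oblique vessels, so matching is by minimum angular distance
    (must be unique for clean layouts).
    """
    pairs = []
    used = set()
    for m in measurements:
        best = min((t for t in truth_vessels if t.vessel_id not in used),
                   key=lambda t: angdist(m.anchor_angle, t.angle))
        used.add(best.vessel_id)
        pairs.append((m, best))
    return pairs


# ---------------------------------------------------------------------------
# Independent statistical oracles
# ---------------------------------------------------------------------------

def pooled_t_pvalue(a, b) -> tuple[float, float]:
    """Two-tailed pooled-variance two-sample t-test from the closed form."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
           / (na + nb - 2))
    tstat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return tstat, 2 * t_dist.sf(abs(tstat), df)


def mannwhitney_exact_pvalue(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group
    assignments to the pooled sample (valid with or without ties; with ties
    it enumerates the permutation distribution of U)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    na = len(a)
    n = len(pooled)

    def u_stat(group_a_idx):
        ga = [pooled[i] for i in group_a_idx]
        gb = [pooled[i] for i in range(n) if i not in group_a_idx]
        u = 0.0
        for x in ga:
            for y in gb:
                u += (x > y) + 0.5 * (x == y)
        return u

    observed = u_stat(frozenset(range(na)))
    nb = n - na
    mean_u = na * nb / 2.0
    dev = abs(observed - mean_u)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), na):
        total += 1
        if abs(u_stat(frozenset(comb)) - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


def brute_force_min_distances(start_points, end_points):
    """Plain nested-loop shortest start-to-end distances (oracle)."""
    out = []
    for sr, sc in start_points:
        best = math.inf
        for er, ec in end_points:
            d = math.hypot(sr - er, sc - ec)
            if d < best:
                best = d
        out.append(best)
    return out
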