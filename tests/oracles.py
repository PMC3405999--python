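"""Independent reference implementations used to check the package.

Each oracle computes its quantity by a route deliberately different from
the implementation under test: exhaustive enumeration, brute-force loops,
closed forms, or a least-squares histogram fit instead of EM.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import curve_fit


def histogram_mixture_fit(values, n_bins: int = 100):
    """Least-squares fit of a two-Gaussian density to a binned histogram.

    The literal "histogram approximated by two Gaussians" reading: bin the
    values, fit w*N(m1,s1) + (1-w)*N(m2,s2) to the bin densities with
    non-linear least squares. Returns (w_low, m_low, s_low, m_high, s_high)
    labelled by mean.
    """
    values = np.asarray(values, dtype=float)
    density, edges = np.histogram(values, bins=n_bins, density=True)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def model(x, w, m1, s1, m2, s2):
        s1, s2 = abs(s1), abs(s2)
        g1 = np.exp(-0.5 * ((x - m1) / s1) ** 2) / (s1 * math.sqrt(2 * math.pi))
        g2 = np.exp(-0.5 * ((x - m2) / s2) ** 2) / (s2 * math.sqrt(2 * math.pi))
        return w * g1 + (1 - w) * g2

    sd = float(np.std(values))
    p0 = [0.85, float(np.median(values)), sd / 2, float(np.percentile(values, 95)), sd / 2]
    popt, _ = curve_fit(model, centers, density, p0=p0, maxfev=20000)
    w, m1, s1, m2, s2 = popt
    s1, s2 = abs(s1), abs(s2)
    if m1 <= m2:
        return w, m1, s1, m2, s2
    return 1 - w, m2, s2, m1, s1


def hypergeom_overlap_p(n_universe: int, set_a: frozenset, set_b: frozenset) -> float:
    """P(overlap >= observed) by exhaustive enumeration of all |A|-draws."""
    universe = list(range(n_universe))
    observed = len(set_a & set_b)
    hits = total = 0
    for draw in itertools.combinations(universe, len(set_a)):
        total += 1
        if len(set(draw) & set_b) >= observed:
            hits += 1
    return hits / total


def term_two_sided_p(n_universe: int, term_members: frozenset, subset: frozenset) -> float:
    """Doubled-smaller-tail two-sided p by enumeration over all subsets."""
    universe = list(range(n_universe))
    k_obs = len(subset & term_members)
    n_sub = len(subset)
    upper = lower = total = 0
    for draw in itertools.combinations(universe, n_sub):
        total += 1
        k = len(set(draw) & term_members)
        if k >= k_obs:
            upper += 1
        if k <= k_obs:
            lower += 1
    return min(1.0, 2.0 * min(upper / total, lower / total))


def mann_whitney_exact_p(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    Returns (U_of_x, p). Two-sided p doubles the smaller tail of the exact
    permutation distribution of U, capped at 1.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    combined = x + y
    n_x = len(x)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    us = []
    idx = range(len(combined))
    for pick in itertools.combinations(idx, n_x):
        xs = [combined[i] for i in pick]
        ys = [combined[i] for i in idx if i not in pick]
        us.append(u_stat(xs, ys))
    us = np.asarray(us)
    upper = float(np.mean(us >= u_obs))
    lower = float(np.mean(us <= u_obs))
    return u_obs, min(1.0, 2.0 * min(upper, lower))


def brute_force_gene_score(probe_rows, gene_tss: int, window: int) -> float | None:
    """Gene score by plain loops: replicate-average per probe, then window mean.

    ``probe_rows`` is an iterable of (start, end, log2_ratio) tuples for one
    mark and condition; duplicates of the same interval are replicates.
    """
    by_probe: dict = {}
    for start, end, ratio in probe_rows:
        mid = (start + end) // 2
        if gene_tss - window <= mid <= gene_tss + window:
            by_probe.setdefault((start, end), []).append(ratio)
    if not by_probe:
        return None
    probe_means = [sum(v) / len(v) for v in by_probe.values()]
    return sum(probe_means) / len(probe_means)


def brute_force_nearest(positions) -> list:
    """All-pairs nearest-neighbour distances on one chromosome."""
    out = []
    for i, p in enumerate(positions):
        best = None
        for j, q in enumerate(positions):
            if i != j:
                d = abs(p - q)
                best = d if best is None else min(best, d)
        out.append(best)
    return out


def pearson_by_hand(x, y) -> float:
    """Textbook Pearson formula with explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
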