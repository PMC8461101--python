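"""Independent brute-force oracles used by the test suite.

These re-derive expected values with plain loops and closed forms,
deliberately sharing no code with the package's implementation paths.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Single-sample enrichment, re-derived with loops
# ---------------------------------------------------------------------------

def gaussian_kcdf(values: list[float]) -> list[float]:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1) if n > 1 else 0.0
    h = math.sqrt(var) / 4.0
    if h == 0:
        return [0.5] * n
    out = []
    for v in values:
        acc = 0.0
        for w in values:
            acc += 0.5 * (1.0 + math.erf((v - w) / (h * math.sqrt(2.0))))
        out.append(acc / n)
    return out


def ecdf_scaled(values: list[float]) -> list[float]:
    n = len(values)
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        rank = less + (equal + 1) / 2.0
        out.append(rank / (n + 1))
    return out


def rank_genes(values: list[float], symbols: list[str]) -> list[int]:
    """Indices sorted by descending value, ties by symbol (ascending)."""
    return sorted(range(len(values)), key=lambda i: (-values[i], symbols[i]))


def walk_es(
    ordered_in_set: list[bool], weights: list[float], tau: float, es_mode: str
) -> float:
    n = len(ordered_in_set)
    m = sum(ordered_in_set)
    if m == n:
        return 1.0
    wt = [abs(w) ** tau for w in weights]
    in_total = sum(w for w, s in zip(wt, ordered_in_set) if s)
    running = 0.0
    path = []
    for w, in_set in zip(wt, ordered_in_set):
        if in_set:
            running += (w / in_total) if in_total > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        path.append(running)
    if es_mode == "diff":
        return max(max(path), 0.0) + min(min(path), 0.0)
    best = 0.0
    for v in path:
        if abs(v) > abs(best):
            best = v
    return best


def walk_area(ordered_in_set: list[bool], weights: list[float]) -> float:
    n = len(ordered_in_set)
    m = sum(ordered_in_set)
    in_total = sum(w for w, s in zip(weights, ordered_in_set) if s)
    running = 0.0
    area = 0.0
    for w, in_set in zip(weights, ordered_in_set):
        if in_set:
            running += (w / in_total) if in_total > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        area += running
    return area


def gsva_scores(
    matrix: np.ndarray,
    symbols: list[str],
    set_genes: list[str],
    kernel: str,
    tau: float,
    es_mode: str,
) -> list[float]:
    """Full brute-force GSVA path: transform -> rank -> walk, per observation."""
    n_genes, n_obs = matrix.shape
    transform = np.zeros_like(matrix, dtype=float)
    for g in range(n_genes):
        row = list(matrix[g])
        transform[g] = gaussian_kcdf(row) if kernel == "gaussian" else ecdf_scaled(row)
    member = [s in set(set_genes) for s in symbols]
    out = []
    for j in range(n_obs):
        order = rank_genes(list(transform[:, j]), symbols)
        ordered_mask = [member[i] for i in order]
        weights = [n_genes - pos for pos in range(n_genes)]  # top gene weight n
        out.append(walk_es(ordered_mask, weights, tau, es_mode))
    return out


def ssgsea_scores(
    matrix: np.ndarray, symbols: list[str], set_genes: list[str], tau: float
) -> list[float]:
    """Brute-force ssGSEA: raw-expression ranks, area statistic, attainable-max
    normalization (in-set weights relocated to the top / bottom of the ranking)."""
    n_genes, n_obs = matrix.shape
    member = [s in set(set_genes) for s in symbols]
    m = sum(member)
    out = []
    for j in range(n_obs):
        order = rank_genes(list(matrix[:, j]), symbols)
        ordered_mask = [member[i] for i in order]
        weights = [float(n_genes - pos) ** tau for pos in range(n_genes)]
        area = walk_area(ordered_mask, weights)
        in_w = sorted((w for w, s in zip(weights, ordered_mask) if s), reverse=True)
        top_mask = [True] * m + [False] * (n_genes - m)
        top_w = in_w + [0.0] * (n_genes - m)
        bottom_mask = [False] * (n_genes - m) + [True] * m
        bottom_w = [0.0] * (n_genes - m) + list(reversed(in_w))
        amax = walk_area(top_mask, top_w)
        amin = walk_area(bottom_mask, bottom_w)
        scale = max(amax, -amin)
        out.append(area / scale if scale > 0 else 0.0)
    return out


# ---------------------------------------------------------------------------
# Survival oracles
# ---------------------------------------------------------------------------

def logrank_z(times, events, in_group_a) -> float:
    """Signed standardized log-rank (O-E)/sqrt(V), plain loops."""
    times = list(times)
    events = list(events)
    in_a = list(in_group_a)
    event_times = sorted({t for t, e in zip(times, events) if e == 1})
    oe = 0.0
    var = 0.0
    for tau in event_times:
        risk = [i for i, t in enumerate(times) if t >= tau]
        n_tot = len(risk)
        n_a = sum(1 for i in risk if in_a[i])
        dead = [i for i, (t, e) in enumerate(zip(times, events)) if t == tau and e == 1]
        d_tot = len(dead)
        d_a = sum(1 for i in dead if in_a[i])
        oe += d_a - d_tot * n_a / n_tot
        if n_tot > 1:
            var += d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    return oe / math.sqrt(var) if var > 0 else 0.0


def maxstat_scan(times, events, scores, q_low=0.1, q_high=0.9):
    """Naive maxstat scan: loop over midpoint candidates, pick max |z|."""
    scores = np.asarray(scores, dtype=float)
    lo, hi = np.quantile(scores, [q_low, q_high])
    distinct = np.unique(scores)
    window = [s for s in distinct if lo <= s <= hi]
    cands = [(a + b) / 2.0 for a, b in zip(window[:-1], window[1:])]
    best_c, best_z = None, 0.0
    zs = []
    for c in cands:
        z = logrank_z(times, events, [s <= c for s in scores])
        zs.append(z)
        if abs(z) > abs(best_z):
            best_c, best_z = c, z
    return best_c, best_z, np.array(cands), np.array(zs)
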