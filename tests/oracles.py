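"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as naive enumeration, deliberately sharing
no code path with the package.
"""

from __future__ import annotations

import numpy as np


def brute_position_energies(records, n):
    """O(n * records) per-position mean REU and coverage by enumeration."""
    energy = np.full(n, np.nan)
    coverage = np.zeros(n, dtype=int)
    for pos in range(1, n + 1):  # 1-based
        vals = [
            r.reu
            for r in records
            if r.window_start <= pos <= r.window_start + r.window_length - 1
        ]
        coverage[pos - 1] = len(vals)
        if vals:
            energy[pos - 1] = sum(vals) / len(vals)
    return energy, coverage


def brute_window_scores(p, mask, L):
    """Masked window means by explicit per-window looping."""
    n = len(p)
    out = []
    for start in range(n - L + 1):
        vals = [p[i] for i in range(start, start + L) if mask[i]]
        out.append(sum(vals) / len(vals) if vals else np.nan)
    return np.array(out)


def brute_local_maxima(scores):
    """1-based plateau-aware local maxima, NaN treated as -inf."""
    vals = [(-np.inf if np.isnan(v) else v) for v in scores]
    n = len(vals)
    maxima = []
    for i in range(n):
        if np.isnan(scores[i]):
            continue
        if i > 0 and vals[i - 1] == vals[i]:
            continue  # not the leftmost index of its plateau
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        left_ok = i == 0 or vals[i - 1] < vals[i]
        right_ok = j == n - 1 or vals[j + 1] < vals[i]
        if left_ok and right_ok:
            maxima.append(i + 1)
    return maxima


def brute_select(p, mask, residues, L, top_n, allow_overlap):
    """Enumerate, filter to maxima, sort, greedy non-overlap, truncate."""
    scores = brute_window_scores(p, mask, L)
    candidates = [(s, float(scores[s - 1])) for s in brute_local_maxima(scores)]
    candidates.sort(key=lambda c: (-c[1], c[0]))
    kept = []
    used = set()
    for start, score in candidates:
        if len(kept) == top_n:
            break
        span = set(range(start, start + L))
        if not allow_overlap and span & used:
            continue
        kept.append((start, score, residues[start - 1 : start - 1 + L]))
        used |= span
    return kept


def brute_auroc(labels, scores):
    """Exhaustive positive-negative pair counting with half credit for ties."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def average_ranks(values):
    """1-based average ranks with ties sharing the mean rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def brute_spearman(x, y):
    """Pearson correlation of average ranks."""
    rx = np.array(average_ranks(list(x)))
    ry = np.array(average_ranks(list(y)))
    return float(np.corrcoef(rx, ry)[0, 1])
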