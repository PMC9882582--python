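"""Independent reference implementations used only to check the package.

Each oracle is deliberately written the slow, obvious way — quadratic
dynamic programs and exhaustive enumeration — and shares no code with the
implementation it validates.
"""

from __future__ import annotations

import itertools

import numpy as np


def dp_edit_distance(a: str, b: str) -> int:
    """Plain quadratic Levenshtein, row-vectorized with the prefix-min
    trick for the insertion recurrence."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.arange(len(b) + 1)
    idx = np.arange(len(b) + 1)
    for i, ca in enumerate(a.encode()):
        cost = (bb != ca).astype(int)
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i + 1
        cur[1:] = np.minimum(prev[1:] + 1, prev[:-1] + cost)
        # left-to-right dependency resolved via min-prefix of (cur - j)
        cur = np.minimum(cur, np.minimum.accumulate(cur - idx) + idx + 0)
        # one more pass to propagate +1 per step exactly
        cur = np.minimum(cur, np.minimum.accumulate(cur - idx) + idx)
        prev = cur
    return int(prev[-1])


def chain_score(anchors, order, k, gap_gamma, gap_open, gap_open_thresh, max_gap):
    """Score of one candidate chain (list of indices, already increasing)."""
    score = float(k)
    for j, i in zip(order, order[1:]):
        dt = anchors[i][0] - anchors[j][0]
        dq = anchors[i][1] - anchors[j][1]
        if dt <= 0 or dq <= 0 or max(dt, dq) > max_gap:
            return None
        shift = abs(dt - dq)
        score += min(k, dt, dq) - gap_gamma * shift - gap_open * (shift > gap_open_thresh)
    return score


def best_chain_exhaustive(anchors, k, gap_gamma, gap_open, gap_open_thresh, max_gap):
    """Best chain score over all increasing anchor subsequences, by DFS."""
    n = len(anchors)
    order = sorted(range(n), key=lambda i: (anchors[i][0], anchors[i][1]))
    best = 0.0

    def extend(path_score, last):
        nonlocal best
        best = max(best, path_score)
        for nxt in order:
            i, j = anchors[nxt], anchors[last]
            dt, dq = i[0] - j[0], i[1] - j[1]
            if dt <= 0 or dq <= 0 or max(dt, dq) > max_gap:
                continue
            shift = abs(dt - dq)
            step = (
                min(k, dt, dq)
                - gap_gamma * shift
                - gap_open * (shift > gap_open_thresh)
            )
            extend(path_score + step, nxt)

    for start in order:
        extend(float(k), start)
    return best


def best_matching_tp(calls, truths, refdist, pctsize):
    """Maximum-cardinality one-to-one matching under the pairing rules,
    by exhaustive search over injective assignments."""
    m, n = len(calls), len(truths)
    compat = [
        [
            c[0] == t[0]  # svtype
            and (abs(c[1] - t[1]) + abs(c[2] - t[2])) / 2 <= refdist
            and min(c[3], t[3]) / max(c[3], t[3]) >= pctsize
            for t in truths
        ]
        for c in calls
    ]
    best = 0
    for r in range(min(m, n), 0, -1):
        for call_subset in itertools.combinations(range(m), r):
            for perm in itertools.permutations(range(n), r):
                if all(compat[c][t] for c, t in zip(call_subset, perm)):
                    return r
    return best


def ols_fit(xs, ys):
    """Closed-form normal-equations OLS."""
    x = np.asarray(xs, float)
    y = np.asarray(ys, float)
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return slope, ym - slope * xm
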