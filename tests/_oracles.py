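"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — explicit loops and direct
formulas — and shares no code with the production paths it verifies.
"""

from __future__ import annotations

import math

import numpy as np


def pcc_direct(x, y) -> float:
    """Pearson correlation from the raw covariance formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    vx = sum((x[i] - mx) ** 2 for i in range(n))
    vy = sum((y[i] - my) ** 2 for i in range(n))
    if vx == 0 or vy == 0:
        return 0.0
    return cov / math.sqrt(vx * vy)


def sym_normalize_elementwise(M):
    """M[i,j] / sqrt(d_i * d_j), entry by entry, 0/0 := 0."""
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    d = [sum(M[i]) for i in range(n)]
    out = np.zeros_like(M)
    for i in range(n):
        for j in range(n):
            if d[i] > 0 and d[j] > 0:
                out[i, j] = M[i, j] / math.sqrt(d[i] * d[j])
    return out


def birw_dense(L_N, P_N, A, alpha, l, r):
    """Naive dense recurrence for the bi-random walk.

    Seeds with A / sum(A); runs the left update while t <= l and the right
    update while t <= r, averaging active states each step.
    """
    L_N = np.asarray(L_N, dtype=float)
    P_N = np.asarray(P_N, dtype=float)
    A = np.asarray(A, dtype=float)
    A0 = A / A.sum()
    R = A0.copy()
    for t in range(1, max(l, r) + 1):
        states = []
        if t <= l:
            states.append(alpha * (L_N @ R) + (1 - alpha) * A0)
        if t <= r:
            states.append(alpha * (R @ P_N) + (1 - alpha) * A0)
        R = sum(states) / len(states)
    return R


def aggregate_direct(values):
    """1 - prod(1 - C_k) over the positive scores only; None if none."""
    pos = [c for c in values if c > 0]
    if not pos:
        return None
    prod = 1.0
    for c in pos:
        prod *= 1.0 - c
    return 1.0 - prod


def term_scores_direct(neighbors, partner_terms):
    """Direct summation of normalized neighbour weights per term."""
    total = sum(s for _, s in neighbors)
    if total <= 0:
        return {}
    all_terms = set()
    for p, _ in neighbors:
        all_terms |= set(partner_terms.get(p, set()))
    out = {}
    for term in all_terms:
        acc = 0.0
        for p, s in neighbors:
            if term in partner_terms.get(p, set()):
                acc += s / total
        if acc > 0:
            out[term] = min(acc, 1.0)
    return out


def pr_rc_direct(per_entity, truth, t):
    """Averaged precision/recall straight from the definitions."""
    pr_vals = []
    rc_vals = []
    for entity, T in truth.items():
        preds = per_entity.get(entity, {})
        P = {f for f, s in preds.items() if s >= t}
        hits = len(P & T)
        if P:
            pr_vals.append(hits / len(P))
        rc_vals.append(hits / len(T))
    pr = sum(pr_vals) / len(pr_vals) if pr_vals else 0.0
    rc = sum(rc_vals) / len(truth)
    return pr, rc, len(pr_vals)


def fmax_bruteforce(per_entity, truth):
    """Exhaustive maximum of F over every distinct predicted score (plus
    the endpoints) as candidate thresholds."""
    thresholds = {0.0, 1.0}
    for preds in per_entity.values():
        thresholds.update(preds.values())
    best = 0.0
    for t in sorted(thresholds):
        pr, rc, _ = pr_rc_direct(per_entity, truth, t)
        if pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best


def auc_mann_whitney(pos, neg):
    """AUROC via the rank-sum identity with midrank ties."""
    pos = list(map(float, pos))
    neg = list(map(float, neg))
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))
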