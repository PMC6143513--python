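"""Independent brute-force reference implementations used as test oracles.

Each routine here computes its quantity from first principles (explicit
formulas, exhaustive enumeration, naive O(n^3) recursions, direct objective
maximisation) without touching the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize


def pearson_r_formula(x, y) -> float:
    """Direct evaluation of sum((x-xbar)(y-ybar)) / sqrt(...) in pure loops."""
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    num = sum((x[i] - xbar) * (y[i] - ybar) for i in range(n))
    den = math.sqrt(
        sum((x[i] - xbar) ** 2 for i in range(n))
        * sum((y[i] - ybar) ** 2 for i in range(n))
    )
    return num / den


def midranks(values) -> list[float]:
    """Mid-ranks (ties averaged), built by explicit sorting and grouping."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho_formula(x, y) -> float:
    """Pearson correlation of mid-ranks."""
    return pearson_r_formula(midranks(list(x)), midranks(list(y)))


def ward_linkage_naive(d: np.ndarray) -> np.ndarray:
    """Naive O(n^3) Ward.D2 Lance-Williams agglomeration on a distance matrix.

    Returns an (n-1, 4) linkage array in the scipy encoding (cluster ids,
    merge height, merged size). Ties are broken by the smallest pair of
    cluster ids.
    """
    n = d.shape[0]
    sizes = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d[i, j])
    active = list(range(n))
    next_id = n
    out = []
    while len(active) > 1:
        best = min(
            ((dist[tuple(sorted((a, b)))], a, b)
             for i, a in enumerate(active) for b in active[i + 1 :]),
            key=lambda t: (t[0], min(t[1], t[2]), max(t[1], t[2])),
        )
        h, a, b = best
        a, b = min(a, b), max(a, b)
        na, nb = sizes[a], sizes[b]
        out.append([a, b, h, na + nb])
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            dac = dist[tuple(sorted((a, c)))]
            dbc = dist[tuple(sorted((b, c)))]
            dab = h
            new = math.sqrt(
                ((na + nc) * dac**2 + (nb + nc) * dbc**2 - nc * dab**2)
                / (na + nb + nc)
            )
            dist[tuple(sorted((next_id, c)))] = new
        active = [c for c in active if c not in (a, b)] + [next_id]
        sizes[next_id] = na + nb
        next_id += 1
    return np.array(out)


def combined_score_enumeration(values_by_subject, cutpoints) -> dict:
    """Exhaustive indicator-sum per subject by explicit iteration."""
    out = {}
    for sid, vals in values_by_subject.items():
        s = 0
        for marker, cut in cutpoints.items():
            if vals[marker] >= cut:
                s += 1
        out[sid] = s
    return out


def auc_pair_counting(scores, labels) -> float:
    """AUC by enumerating every case-control pair (ties get half credit)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def efron_negative_partial_loglik(beta: float, intervals) -> float:
    """Hand-written Efron-tie-corrected negative Cox partial log-likelihood.

    ``intervals`` is an iterable of (subject, start, stop, event, value)
    rows in counting-process form.
    """
    rows = list(intervals)
    event_times = sorted({r[2] for r in rows if r[3] == 1})
    ll = 0.0
    for t in event_times:
        at_risk = [r for r in rows if r[1] < t <= r[2]]
        tied = [r for r in at_risk if r[2] == t and r[3] == 1]
        d = len(tied)
        risk_sum = sum(math.exp(beta * r[4]) for r in at_risk)
        tied_sum = sum(math.exp(beta * r[4]) for r in tied)
        ll += beta * sum(r[4] for r in tied)
        for el in range(d):
            ll -= math.log(risk_sum - el / d * tied_sum)
    return -ll


def cox_beta_direct(intervals) -> float:
    """Maximise the hand-written partial likelihood by bounded scalar search."""
    res = optimize.minimize_scalar(
        efron_negative_partial_loglik,
        args=(intervals,),
        bounds=(-20, 20),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def ridge_logistic_direct(X, y, lam) -> np.ndarray:
    """Derivative-free maximisation of the slope-penalised log-likelihood.

    Works on the standardised design (matching the implementation contract);
    returns [intercept, slopes...].
    """
    X = np.asarray(X, float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    Z1 = np.column_stack([np.ones(len(Z)), Z])

    def negobj(b):
        eta = Z1 @ b
        return -np.sum(y * eta - np.logaddexp(0.0, eta)) + 0.5 * lam * np.sum(b[1:] ** 2)

    res = optimize.minimize(
        negobj,
        np.zeros(Z1.shape[1]),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000, "maxfev": 50000},
    )
    return res.x


def prefix_max(values: dict[int, float], update_days) -> dict[int, float]:
    """Brute-force running maximum over every prefix of available days."""
    out = {}
    for d in update_days:
        out[d] = max(v for day, v in values.items() if day <= d)
    return out
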