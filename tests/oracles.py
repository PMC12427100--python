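"""Independent brute-force oracles used by the test-suite.

Each routine recomputes a statistic straight from its definition with
none of the package's shortcuts, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import permutations

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-rational enumeration of fixed-margin tables."""
    n = a + b + c + d
    k_cat = a + b  # category margin
    k_sel = a + c  # selected margin

    def prob(x: int) -> Fraction:
        return Fraction(
            math.comb(k_cat, x) * math.comb(n - k_cat, k_sel - x), math.comb(n, k_sel)
        )

    lo = max(0, k_sel - (n - k_cat))
    hi = min(k_cat, k_sel)
    p_obs = prob(a)
    cutoff = p_obs * Fraction(10_000_001, 10_000_000)  # same (1+1e-7) convention
    total = sum((prob(x) for x in range(lo, hi + 1) if prob(x) <= cutoff), Fraction(0))
    return float(min(total, Fraction(1)))


def bh_oracle(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q[i] = min(1.0, running_min)
    return q


def efron_loglik_oracle(beta: float, time, event, x) -> float:
    """Efron partial log-likelihood from the definition (explicit loops)."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    x = np.asarray(x, float)
    ll = 0.0
    for t in sorted(set(time[event])):
        deaths = [i for i in range(len(time)) if event[i] and time[i] == t]
        risk = [i for i in range(len(time)) if time[i] >= t]
        d = len(deaths)
        s_risk = sum(math.exp(beta * x[i]) for i in risk)
        s_dead = sum(math.exp(beta * x[i]) for i in deaths)
        ll += sum(beta * x[i] for i in deaths)
        for ell in range(d):
            ll -= math.log(s_risk - (ell / d) * s_dead)
    return ll


def golden_section_max(f, lo: float = -8.0, hi: float = 8.0, tol: float = 1e-8) -> float:
    """Argmax of a unimodal function by coarse grid + golden-section refinement."""
    grid = np.linspace(lo, hi, 401)
    vals = [f(b) for b in grid]
    i = int(np.argmax(vals))
    a, b = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    inv_phi = (math.sqrt(5) - 1) / 2
    c, d = b - inv_phi * (b - a), a + inv_phi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - inv_phi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + inv_phi * (b - a)
            fd = f(d)
    return (a + b) / 2


def spearman_no_ties_oracle(x, y) -> float:
    """rho = 1 - 6*sum(d^2)/(n(n^2-1)); valid only without ties."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    return 1.0 - 6.0 * float(((rx - ry) ** 2).sum()) / (n * (n * n - 1))


def spearman_exact_p_oracle(x, y) -> float:
    """Exact two-sided permutation p for tie-free vectors via the d^2 formula."""
    rho_obs = abs(spearman_no_ties_oracle(x, y))
    n = len(x)
    count = 0
    for perm in permutations(range(len(y))):
        if abs(spearman_no_ties_oracle(x, [y[i] for i in perm])) >= rho_obs - 1e-12:
            count += 1
    return count / math.factorial(n)


def km_oracle(time, event) -> list[tuple[float, float]]:
    """Product-limit estimate from the definition; one (t, S(t)) per event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    s = 1.0
    out = []
    for t in sorted(set(time[event])):
        n_at = int((time >= t).sum())
        d = int(((time == t) & event).sum())
        s *= 1.0 - d / n_at
        out.append((t, s))
    return out
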