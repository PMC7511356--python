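"""Shared fixtures and independent oracles used across the suite.

The oracles here are deliberately naive re-derivations (sliding-window
string comparison, exact rational hypergeometric enumeration, rank
enumeration, hand BH step-up) kept independent of the package code paths
they check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from ripcpe import GeneratorConfig, generate_utr_set, motif_catalog, scan_utrs
from ripcpe.io import profiles_to_frame


# ---------------------------------------------------------------- oracles


def brute_scan(sequence: str, catalog=None) -> dict:
    """Character-by-character sliding-window scan: class -> sorted 1-based starts."""
    if catalog is None:
        catalog = motif_catalog()
    out = {}
    for cls in catalog:
        pats = sorted(cls.patterns)
        starts = []
        for i in range(len(sequence)):
            window_hit = False
            for p in pats:
                if sequence[i : i + len(p)] == p:
                    window_hit = True
            if window_hit:
                starts.append(i + 1)
        out[cls.name] = starts
    return out


def fisher_enumeration_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration in exact rationals.

    Minimum-likelihood rule: sum the probabilities of every table with the
    observed margins whose probability does not exceed the observed one.
    """
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)
    def pmf(k):
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum((pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs), Fraction(0))
    return float(total)


def ranksum_enumeration_p(x, y) -> tuple:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Only valid for untied pooled samples. Returns (U_x, p) with the
    doubled-smaller-tail convention (equal to the symmetric-tail rule for
    the untied, symmetric null distribution of U).
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    nx, ny = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    idx = range(len(pooled))
    for x_pos in combinations(idx, nx):
        x_set = set(x_pos)
        u = sum(1 for i in x_pos for j in idx if j not in x_set and pooled[i] > pooled[j])
        us.append(u)
    us = np.array(us)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return float(u_obs), float(min(1.0, p))


def bh_stepup(p) -> np.ndarray:
    """Hand BH: q_(i) = min_{j >= i} p_(j) * n / j over the sorted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def catalog():
    return motif_catalog()


@pytest.fixture(scope="session")
def planted_dataset():
    """One 2,000-transcript UTR set at the default study conditions, with
    truth labels and the scanned profile table (shared read-only)."""
    cfg = GeneratorConfig(n_transcripts=2000, seed=101)
    utrs, truth = generate_utr_set(cfg)
    profiles = profiles_to_frame(scan_utrs(utrs))
    return utrs, truth, profiles
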