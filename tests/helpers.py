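"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths (KD-trees, vectorised
math) so they can certify them: plain O(n^2) pair loops and textbook
formulas only.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_clashes(probe, environment, threshold, exclusions=frozenset()):
    out = set()
    for i, a in enumerate(probe):
        for j, b in enumerate(environment):
            if (i, j) in exclusions or a.is_hydrogen or b.is_hydrogen:
                continue
            d = math.dist(tuple(a.position), tuple(b.position))
            if a.vdw_radius + b.vdw_radius - d > threshold:
                out.add((i, j))
    return out


def brute_contacts(probe, environment, shell, clash_threshold, exclusions=frozenset()):
    out = set()
    for i, a in enumerate(probe):
        for j, b in enumerate(environment):
            if (i, j) in exclusions or a.is_hydrogen or b.is_hydrogen:
                continue
            d = math.dist(tuple(a.position), tuple(b.position))
            rsum = a.vdw_radius + b.vdw_radius
            if rsum - clash_threshold < d <= rsum + shell:
                out.add((i, j))
    return out


def brute_hbonds(donors, acceptors, max_dist, min_angle):
    """(donor_label, acceptor_label) pairs from plain geometry."""
    out = set()
    for dlab, datom, dante in donors:
        for alab, aatom, _ in acceptors:
            if datom is aatom:
                continue
            d = math.dist(tuple(datom.position), tuple(aatom.position))
            if d < 1e-6 or d > max_dist:
                continue
            v1 = dante.position - datom.position
            v2 = aatom.position - datom.position
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if ang >= min_angle:
                out.add((dlab, alab))
    return out


def brute_rmsd(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration over
    all 2x2 tables with the observed margins."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def log_comb(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    def prob(x):
        # P(X = x) for X ~ Hypergeom(n, row1, col1)
        return math.exp(
            log_comb(row1, x) + log_comb(row2, col1 - x) - log_comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(1.0, total)


def random_atoms(rng, n, box=10.0, radius_choices=(1.52, 1.55, 1.70, 1.80)):
    from sodscan.structure import Atom

    elements = {1.52: "O", 1.55: "N", 1.70: "C", 1.80: "S"}
    out = []
    for k in range(n):
        r = float(rng.choice(radius_choices))
        out.append(
            Atom(
                name=f"X{k}",
                element=elements[r],
                position=rng.uniform(0, box, size=3),
                vdw_radius=r,
            )
        )
    return out
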