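"""Shared fixtures: seeded random valid LC factors and tiny LP oracles.

The coupling construction here is deliberately independent of the package's
solver internals (plain iterative proportional fitting), so feasibility
properties are checked against objects the solver never produced.
"""

import numpy as np
import pytest

from hmot.core import LatentCoupling, LatentRepresentation


def random_measure_weights(rng, n):
    return rng.dirichlet(np.ones(n) * 5)


def random_Q(rng, n, r, a=None):
    """Random valid latent representation with rows summing to ``a``."""
    if a is None:
        a = random_measure_weights(rng, n)
    G = rng.gamma(2.0, size=(n, r)) + 1e-3
    Q = a[:, None] * (G / G.sum(axis=1, keepdims=True))
    return LatentRepresentation(Q)


def random_T(rng, g1, g2):
    """Random valid coupling of (g1, g2) by IPF of a positive matrix."""
    K = rng.gamma(2.0, size=(g1.shape[0], g2.shape[0])) + 1e-3
    for _ in range(2000):
        K *= (g1 / K.sum(axis=1))[:, None]
        K *= (g2 / K.sum(axis=0))[None, :]
        if np.max(np.abs(K.sum(axis=1) - g1)) < 1e-15:
            break
    return LatentCoupling(K, K.sum(axis=1), K.sum(axis=0))


def random_chain(rng, ns, rs):
    """Random valid (Qs, couplings) chain across len(ns) timepoints."""
    from hmot.core import DifferentiationMap

    Qs = [random_Q(rng, n, r) for n, r in zip(ns, rs)]
    cps = [random_T(rng, Qs[t].g, Qs[t + 1].g) for t in range(len(ns) - 1)]
    dmap = DifferentiationMap(tuple(cps), tuple(Q.g for Q in Qs))
    return Qs, dmap


def lp_ot_reference(M, g1, g2):
    """Dense-formulation LP oracle for small OT instances (test-side)."""
    from scipy.optimize import linprog

    r1, r2 = M.shape
    A = np.zeros((r1 + r2, r1 * r2))
    for i in range(r1):
        A[i, i * r2 : (i + 1) * r2] = 1.0
    for j in range(r2):
        A[r1 + j, j::r2] = 1.0
    b = np.concatenate([g1, g2])
    res = linprog(M.ravel(), A_eq=A[:-1], b_eq=b[:-1], bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
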