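"""Exact-arithmetic cross-check for the controllability computations.

This module recomputes the minimum driver count N_D of an integer adjacency
matrix without floating point, serving as an independent verification tool
for the SVD-based production path in :mod:`contarget.controllability`.
It is never used inside the pipeline itself.

The trick avoids symbolic eigenvalues entirely.  Factor the characteristic
polynomial chi_A over the rationals into irreducible factors f_1, ..., f_k.
For any root alpha of an irreducible factor f, the geometric multiplicity of
alpha equals

    mu(alpha) = dim ker f(A) / deg f = (n - rank f(A)) / deg f,

because conjugate roots of an irreducible factor carry isomorphic Jordan
structures, and ker f(A) is the direct sum of the eigenspaces of all deg(f)
roots of f.  Both f(A) (by Horner evaluation with integer matrices) and its
rank are exact rational computations, so

    N_D = max_i (n - rank f_i(A)) / deg f_i

is exact.  The eigenvalue lambda_M itself is not materialized; only the
multiplicity is needed for the cross-check.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

from .errors import ValidationError


def exact_nd(adjacency) -> int:
    """Exact minimum driver count of an integer 0/1 adjacency matrix."""
    A = np.asarray(adjacency)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    n = A.shape[0]
    if n == 0:
        raise ValidationError("empty adjacency")
    M = sp.Matrix(n, n, lambda i, j: sp.Integer(int(A[i, j])))
    x = sp.Symbol("x")
    chi = M.charpoly(x)
    factors = sp.factor_list(chi.as_expr(), x)[1]
    best = 0
    identity = sp.eye(n)
    for factor, _mult in factors:
        poly = sp.Poly(factor, x)
        coeffs = poly.all_coeffs()  # highest degree first
        # Horner evaluation of factor(M) in exact rational arithmetic
        FA = sp.zeros(n, n)
        for c in coeffs:
            FA = FA * M + sp.Rational(c) * identity
        mu = sp.Rational(n - FA.rank(), poly.degree())
        if mu.q != 1:
            raise ValidationError("non-integer multiplicity; factorization bug")
        best = max(best, int(mu))
    return best


def exact_nd_network(net) -> int:
    """Exact N_D of a :class:`DirectedNetwork`."""
    return exact_nd(net.adjacency().astype(int))
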