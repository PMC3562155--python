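"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they are checking: maximum
matching by exhaustive recursion, flux variability by vertex
enumeration of the constraint polytope, steady states by long-time ODE
integration (the latter lives in the relay module itself and is treated
as the oracle because it shares nothing with the algebraic solver).
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_structural_rank(pattern) -> int:
    """Maximum set of nonzeros sharing no row/column, by recursion."""
    A = (np.asarray(pattern) != 0)
    n_rows, n_cols = A.shape

    def best(row: int, used_cols: frozenset) -> int:
        if row == n_rows:
            return 0
        # skip this row
        out = best(row + 1, used_cols)
        for col in range(n_cols):
            if A[row, col] and col not in used_cols:
                out = max(out, 1 + best(row + 1, used_cols | {col}))
        return out

    return best(0, frozenset())


def enumerate_polytope_vertices(A_eq, b_eq, bounds, tol=1e-9):
    """All vertices of {x : A_eq x = b_eq, lb <= x <= ub} by enumeration.

    Fixes every subset of n - rank(A_eq) variables at a bound, solves the
    resulting square system for the rest and keeps feasible solutions.
    """
    A_eq = np.asarray(A_eq, float)
    b_eq = np.asarray(b_eq, float).ravel()
    n = A_eq.shape[1]
    rank = np.linalg.matrix_rank(A_eq, tol=1e-10)
    n_fix = n - rank
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    vertices = []
    for fixed_vars in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed_vars]
        A_free = A_eq[:, free]
        if np.linalg.matrix_rank(A_free, tol=1e-10) < len(free):
            continue
        for sides in itertools.product((0, 1), repeat=n_fix):
            x = np.full(n, np.nan)
            for j, s in zip(fixed_vars, sides):
                x[j] = lb[j] if s == 0 else ub[j]
            rhs = b_eq - A_eq[:, list(fixed_vars)] @ x[list(fixed_vars)]
            sol, res, _, _ = np.linalg.lstsq(A_free, rhs, rcond=None)
            x[free] = sol
            if np.max(np.abs(A_eq @ x - b_eq)) > tol:
                continue
            if np.all(x >= lb - tol) and np.all(x <= ub + tol):
                vertices.append(np.clip(x, lb, ub))
    return np.array(vertices)


def fva_by_vertex_enumeration(network, objective_reaction, objective_value):
    """Per-reaction flux min/max over the enumerated optimal vertices."""
    S, _, rids = network.stoichiometric_matrix()
    j_obj = rids.index(objective_reaction)
    row = np.zeros(len(rids))
    row[j_obj] = 1.0
    A_eq = np.vstack([S, row])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [objective_value]])
    verts = enumerate_polytope_vertices(A_eq, b_eq, network.bounds())
    assert len(verts), "no vertices found: polytope empty or degenerate"
    return verts.min(axis=0), verts.max(axis=0), rids
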