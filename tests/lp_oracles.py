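"""Brute-force LP oracles, independent of the cobra/optlang solver path.

Vertices of the flux polytope {v : S v = 0, lb <= v <= ub} are
enumerated as basic feasible solutions: every subset of n - rank(S)
variables is fixed at one of its bounds and the remaining square system
is solved directly with numpy.  Only practical for tiny networks.
"""

from __future__ import annotations

import itertools

import numpy as np


def stoichiometric_matrix(cobra_model) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mets = {m.id: i for i, m in enumerate(cobra_model.metabolites)}
    n = len(cobra_model.reactions)
    S = np.zeros((len(mets), n))
    lb = np.zeros(n)
    ub = np.zeros(n)
    for j, rxn in enumerate(cobra_model.reactions):
        lb[j], ub[j] = rxn.bounds
        for met, coeff in rxn.metabolites.items():
            S[mets[met.id], j] = coeff
    return S, lb, ub


def enumerate_vertices(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub} (basic solutions)."""
    n = S.shape[1]
    r = np.linalg.matrix_rank(S) if S.size else 0
    free = r  # variables solved from the equality system
    vertices: list[np.ndarray] = []
    for basis in itertools.combinations(range(n), free):
        nonbasis = [j for j in range(n) if j not in basis]
        B = S[:, basis]
        if free and np.linalg.matrix_rank(B) < free:
            continue
        for bounds_choice in itertools.product((0, 1), repeat=len(nonbasis)):
            v = np.empty(n)
            for j, pick in zip(nonbasis, bounds_choice):
                v[j] = lb[j] if pick == 0 else ub[j]
            if free:
                rhs = -S[:, nonbasis] @ v[nonbasis]
                sol, residual, *_ = np.linalg.lstsq(B, rhs, rcond=None)
                if np.linalg.norm(S[:, basis] @ sol + S[:, nonbasis] @ v[nonbasis]) > tol:
                    continue
                v[np.array(basis)] = sol
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(np.clip(v, lb, ub))
    if not vertices:
        return np.empty((0, n))
    arr = np.array(vertices)
    # deduplicate
    _, idx = np.unique(np.round(arr, 7), axis=0, return_index=True)
    return arr[sorted(idx)]


def brute_force_fba(
    cobra_model, objective_id: str, direction: str = "max"
) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal objective over all enumerated vertices.

    Returns (optimum, vertices attaining it, all vertices).  Valid for
    bounded feasible models only.
    """
    S, lb, ub = stoichiometric_matrix(cobra_model)
    idx = [r.id for r in cobra_model.reactions].index(objective_id)
    verts = enumerate_vertices(S, lb, ub)
    if verts.shape[0] == 0:
        raise ValueError("no vertices found; model infeasible or degenerate")
    values = verts[:, idx]
    opt = values.max() if direction == "max" else values.min()
    attaining = verts[np.abs(values - opt) <= 1e-6]
    return float(opt), attaining, verts
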