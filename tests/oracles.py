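"""Independent oracles used only by the test suite.

These deliberately avoid the code paths under test: LP optima are found
by brute-force vertex enumeration (optimum of a linear objective over a
bounded polyhedron is attained at a vertex), weighted-L1 minima by
enumerating sign orthants and running vertex enumeration inside each,
and Mann-Whitney p-values by enumerating all group labelings.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from contextflux.network import MetabolicNetwork
from contextflux.gpr import Gene


# -- vertex-enumeration linear programming --------------------------------


def enumerate_vertices(A_eq, b_eq, A_ub, b_ub, tol=1e-8):
    """All vertices of {v : A_eq v = b_eq, A_ub v <= b_ub} (bounded sets).

    A vertex activates enough inequality rows to make the total active
    system rank n. Intended for tiny systems only.
    """
    A_eq = np.atleast_2d(np.asarray(A_eq, dtype=float))
    A_ub = np.atleast_2d(np.asarray(A_ub, dtype=float))
    b_eq = np.asarray(b_eq, dtype=float)
    b_ub = np.asarray(b_ub, dtype=float)
    n = A_eq.shape[1] if A_eq.size else A_ub.shape[1]
    rank_eq = np.linalg.matrix_rank(A_eq) if A_eq.size else 0
    need = n - rank_eq
    vertices = []
    for active in itertools.combinations(range(A_ub.shape[0]), need):
        M = np.vstack([A_eq, A_ub[list(active)]]) if A_eq.size else A_ub[list(active)]
        rhs = np.concatenate([b_eq, b_ub[list(active)]]) if A_eq.size else b_ub[list(active)]
        if np.linalg.matrix_rank(M) < n:
            continue
        v, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        if np.max(np.abs(M @ v - rhs)) > tol:
            continue
        if A_ub.size and np.max(A_ub @ v - b_ub) > tol:
            continue
        if A_eq.size and np.max(np.abs(A_eq @ v - b_eq)) > tol:
            continue
        vertices.append(v)
    return vertices


def polytope_rows(network: MetabolicNetwork, extra_ub=None):
    """(A_eq, b_eq, A_ub, b_ub) of the steady-state polytope with bounds
    written as inequality rows; ``extra_ub`` is a list of (row, rhs)."""
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    n = network.n_reactions
    eye = np.eye(n)
    A_ub = [eye, -eye]
    b_ub = [ub, -lb]
    for row, rhs in extra_ub or []:
        A_ub.append(np.atleast_2d(row))
        b_ub.append(np.atleast_1d(rhs))
    return S, np.zeros(S.shape[0]), np.vstack(A_ub), np.concatenate(b_ub)


def brute_force_fba(network: MetabolicNetwork):
    """Max objective flux by vertex enumeration."""
    A_eq, b_eq, A_ub, b_ub = polytope_rows(network)
    j = network.reaction_ids.index(network.objective_id)
    vertices = enumerate_vertices(A_eq, b_eq, A_ub, b_ub)
    assert vertices, "oracle polytope has no vertices (unexpected for bounded nets)"
    return max(v[j] for v in vertices)


def brute_force_weighted_l1_min(network: MetabolicNetwork, weights, floor):
    """Min sum_r w_r |v_r| subject to the polytope and v_obj >= floor.

    Enumerates sign orthants for reversible reactions; inside an orthant
    the objective is linear, so the minimum over that piece is attained
    at a vertex of the orthant-restricted polytope.
    """
    lb, ub = network.bounds_arrays()
    n = network.n_reactions
    j_obj = network.reaction_ids.index(network.objective_id)
    w = np.array([weights[r] for r in network.reaction_ids])
    reversible = [i for i in range(n) if lb[i] < 0 and ub[i] > 0]
    best = math.inf
    obj_row = np.zeros(n)
    obj_row[j_obj] = -1.0
    for signs in itertools.product([1.0, -1.0], repeat=len(reversible)):
        lo, hi = lb.copy(), ub.copy()
        for i, s in zip(reversible, signs):
            if s > 0:
                lo[i] = 0.0
            else:
                hi[i] = 0.0
        sigma = np.ones(n)
        sigma[lb < 0] = np.where(ub[lb < 0] <= 0, -1.0, 1.0)
        for i, s in zip(reversible, signs):
            sigma[i] = s
        restricted = network.copy()
        for i, rid in enumerate(network.reaction_ids):
            restricted.lower_bound[rid] = lo[i]
            restricted.upper_bound[rid] = hi[i]
        A_eq, b_eq, A_ub, b_ub = polytope_rows(restricted, [(obj_row, -floor)])
        for v in enumerate_vertices(A_eq, b_eq, A_ub, b_ub):
            val = float(np.sum(w * sigma * v))
            best = min(best, val)
    return best


# -- random small networks for the LP oracles -----------------------------


def random_network(rng, n_reactions=None, freedom=2) -> MetabolicNetwork:
    """A random bounded network with a controlled feasible-set dimension.

    The stoichiometric matrix has full row rank m = n - freedom, all
    bounds are finite rationals with 0 inside the box (so v = 0 is
    always feasible), and the objective is the first reaction.
    """
    n = int(n_reactions if n_reactions is not None else rng.integers(4, 9))
    freedom = min(freedom, n - 1)
    m = n - freedom
    for _ in range(100):
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        if np.linalg.matrix_rank(S) == m:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a full-rank stoichiometric matrix")
    rids = [f"R{i}" for i in range(n)]
    mids = [f"M{i}" for i in range(m)]
    stoich = {
        rids[j]: {mids[i]: float(S[i, j]) for i in range(m) if S[i, j] != 0}
        for j in range(n)
    }
    lb, ub = {}, {}
    for j, rid in enumerate(rids):
        hi = float(rng.integers(1, 11))
        lo = float(-rng.integers(0, 11)) if rng.random() < 0.5 else 0.0
        lb[rid], ub[rid] = lo, hi
    return MetabolicNetwork(
        metabolite_ids=mids,
        reaction_ids=rids,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gpr={r: Gene(f"g{j}") if j % 2 else None for j, r in enumerate(rids)},
        subsystem={r: "" for r in rids},
        objective_id=rids[0],
        model_id="random",
    )


# -- cobra conversion (independent implementation cross-checks) -----------


def to_cobra(network: MetabolicNetwork):
    import cobra
    from contextflux.gpr import gpr_to_string

    model = cobra.Model(network.model_id)
    model.add_metabolites(
        [cobra.Metabolite(m, compartment="c") for m in network.metabolite_ids]
    )
    rxns = []
    for rid in network.reaction_ids:
        rx = cobra.Reaction(
            rid,
            lower_bound=network.lower_bound[rid],
            upper_bound=network.upper_bound[rid],
        )
        rxns.append(rx)
    model.add_reactions(rxns)
    for rid in network.reaction_ids:
        rx = model.reactions.get_by_id(rid)
        rx.add_metabolites(
            {model.metabolites.get_by_id(m): c for m, c in network.stoichiometry[rid].items()}
        )
        rule = gpr_to_string(network.gpr.get(rid))
        if rule:
            rx.gene_reaction_rule = rule
    model.objective = network.objective_id
    return model


# -- Mann-Whitney enumeration ---------------------------------------------


def mwu_enumeration(x, y):
    """Exact two-sided Mann-Whitney (U for x, p) by labeling enumeration."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_stat(xs, ys):
        return sum(
            (1.0 if a > b else 0.5 if a == b else 0.0) for a in xs for b in ys
        )

    u_obs = u_stat(x, y)
    center = n1 * n2 / 2.0
    dev = abs(u_obs - center)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n1 + n2) if i not in combo]
        if abs(u_stat(xs, ys) - center) >= dev - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total
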