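"""Linear-programming core: FBA, FVA and transcript-weighted pFBA.

All three operate on the steady-state polytope

    P = { v : S v = 0,  lb <= v <= ub }

FBA maximizes the objective (biomass) flux over P. Weighted pFBA then
minimizes the transcript-weighted total flux  sum_r w_r |v_r|  subject
to retaining at least ``fraction`` of the FBA optimum; the absolute
values are linearized exactly by splitting every reaction into
non-negative forward/backward parts. FVA reports the attainable flux
range of each reaction, optionally under extra linear constraints and
under a cap on the weighted total flux (the parsimony cap used for
pruning).

The solver is scipy's HiGHS interface: deterministic, single-threaded,
no licensing. Alternate optima are possible in any LP; downstream
pruning therefore never depends on which optimal vertex is returned,
only on FVA ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import FluxDistribution, MetabolicNetwork
from .transcripts import ReactionWeights

__all__ = [
    "LPSettings",
    "LinearConstraint",
    "AbsFluxCap",
    "InfeasibleModelError",
    "UnboundedModelError",
    "fba",
    "fva",
    "weighted_pfba",
]


@dataclass
class LPSettings:
    """Numerical tolerances for the LP layer.

    feasibility_tolerance is passed to HiGHS; mass_balance_tolerance is
    used when verifying returned flux vectors; parsimony_slack is the
    relative slack applied to the minimized parsimony value when it is
    re-used as a cap. The slack only absorbs solver round-off: it must
    stay well below pruning_tolerance / parsimony_value, otherwise the
    cap lets every zero-weight-path reaction carry flux above the
    pruning threshold and pruning becomes vacuous.
    """

    feasibility_tolerance: float = 1e-9
    mass_balance_tolerance: float = 1e-6
    parsimony_slack: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("feasibility_tolerance", "mass_balance_tolerance", "parsimony_slack"):
            v = getattr(self, name)
            if not (0 < v < 1e-3):
                raise ValueError(f"{name} must lie in (0, 1e-3), got {v}")


@dataclass
class LinearConstraint:
    """sum_r coefs[r] * v_r  (sense)  rhs, with sense in {<=, >=, ==}."""

    coefs: dict[str, float]
    sense: str
    rhs: float

    def __post_init__(self) -> None:
        if self.sense not in ("<=", ">=", "=="):
            raise ValueError(f"bad sense {self.sense!r}")


@dataclass
class AbsFluxCap:
    """sum_r weights[r] * |v_r| <= cap  (the parsimony cap)."""

    weights: dict[str, float]
    cap: float


class InfeasibleModelError(RuntimeError):
    pass


class UnboundedModelError(RuntimeError):
    pass


def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds, settings: LPSettings):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": settings.feasibility_tolerance,
            "dual_feasibility_tolerance": settings.feasibility_tolerance,
        },
    )
    if res.status == 2:
        raise InfeasibleModelError("LP infeasible")
    if res.status == 3:
        raise UnboundedModelError("LP unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return res


def fba(network: MetabolicNetwork, settings: LPSettings | None = None) -> FluxDistribution:
    """Maximize the objective flux over the steady-state polytope."""
    settings = settings or LPSettings()
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds_arrays()
    n = network.n_reactions
    c = np.zeros(n)
    c[network._rxn_index[network.objective_id]] = -1.0
    try:
        res = _solve(c, None, None, S, np.zeros(S.shape[0]), list(zip(lb, ub)), settings)
    except InfeasibleModelError:
        raise InfeasibleModelError(
            f"model {network.model_id!r} has no steady-state flux distribution"
        ) from None
    except UnboundedModelError:
        raise UnboundedModelError(
            f"objective {network.objective_id!r} of model {network.model_id!r} "
            "is unbounded"
        ) from None
    flux = {r: float(res.x[i]) for i, r in enumerate(network.reaction_ids)}
    return FluxDistribution(flux=flux, objective_value=-float(res.fun))


# -- split-variable machinery --------------------------------------------


@dataclass
class _SplitLP:
    """Forward/backward split of P plus compiled extra constraints.

    Variables are x = [p_1..p_R, n_1..n_R] with v_r = p_r - n_r,
    p_r in [max(lb,0), max(ub,0)], n_r in [max(-ub,0), max(-lb,0)].
    The projection onto v of the feasible set equals the original
    polytope intersected with the extra constraints, including any
    AbsFluxCap (a point satisfying the cap always has a complementary
    split with p_r * n_r = 0).
    """

    network: MetabolicNetwork
    A_ub: list = field(default_factory=list)
    b_ub: list = field(default_factory=list)
    A_eq: list = field(default_factory=list)
    b_eq: list = field(default_factory=list)
    bounds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        net = self.network
        S = net.stoichiometric_matrix()
        lb, ub = net.bounds_arrays()
        m, R = S.shape
        self.R = R
        self.A_eq = [np.hstack([S, -S])]
        self.b_eq = [np.zeros(m)]
        p_lo, p_hi = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
        n_lo, n_hi = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
        self.bounds = list(zip(p_lo, p_hi)) + list(zip(n_lo, n_hi))

    def _row(self, coefs: dict[str, float]) -> np.ndarray:
        row = np.zeros(2 * self.R)
        for rid, coef in coefs.items():
            j = self.network._rxn_index[rid]
            row[j] = coef
            row[self.R + j] = -coef
        return row

    def add(self, constraint: LinearConstraint | AbsFluxCap) -> None:
        if isinstance(constraint, AbsFluxCap):
            row = np.zeros(2 * self.R)
            for rid, w in constraint.weights.items():
                j = self.network._rxn_index[rid]
                row[j] = w
                row[self.R + j] = w
            self.A_ub.append(row)
            self.b_ub.append(constraint.cap)
            return
        row = self._row(constraint.coefs)
        if constraint.sense == "==":
            self.A_eq.append(row)
            self.b_eq.append(np.atleast_1d(constraint.rhs))
        elif constraint.sense == "<=":
            self.A_ub.append(row)
            self.b_ub.append(constraint.rhs)
        else:
            self.A_ub.append(-row)
            self.b_ub.append(-constraint.rhs)

    def solve(self, c: np.ndarray, settings: LPSettings):
        A_ub = np.vstack(self.A_ub) if self.A_ub else None
        b_ub = np.array(self.b_ub) if self.A_ub else None
        return _solve(
            c, A_ub, b_ub, np.vstack(self.A_eq), np.concatenate(self.b_eq),
            self.bounds, settings,
        )

    def flux_vector(self, x: np.ndarray) -> np.ndarray:
        return x[: self.R] - x[self.R :]


def fva(
    network: MetabolicNetwork,
    extra_constraints: list[LinearConstraint | AbsFluxCap] | None = None,
    reactions: list[str] | None = None,
    settings: LPSettings | None = None,
    keep_vertices: bool = False,
):
    """Per-reaction (min, max) attainable flux under optional constraints.

    With ``keep_vertices`` also returns the full flux vectors realizing
    each extreme, which double as warmup points for the sampler.
    """
    settings = settings or LPSettings()
    reactions = list(reactions) if reactions is not None else list(network.reaction_ids)
    lp = _SplitLP(network)
    for con in extra_constraints or []:
        lp.add(con)
    ranges: dict[str, tuple[float, float]] = {}
    vertices: list[np.ndarray] = []
    for rid in reactions:
        j = network._rxn_index[rid]
        extremes = []
        for sign in (1.0, -1.0):
            c = np.zeros(2 * lp.R)
            c[j] = sign
            c[lp.R + j] = -sign
            res = lp.solve(c, settings)
            v = lp.flux_vector(res.x)
            extremes.append(float(v[j]))
            if keep_vertices:
                vertices.append(v)
        lo, hi = min(extremes), max(extremes)
        ranges[rid] = (lo, hi)
    if keep_vertices:
        return ranges, vertices
    return ranges


def weighted_pfba(
    network: MetabolicNetwork,
    weights: ReactionWeights,
    fraction: float = 1.0,
    settings: LPSettings | None = None,
) -> tuple[FluxDistribution, float]:
    """Transcript-weighted parsimonious FBA.

    Minimizes  sum_r w_r (v_r^+ + v_r^-)  subject to S v = 0, bounds,
    and v_objective >= fraction * Z where Z is the FBA optimum. With all
    weights equal to 1 this is classical pFBA (total-flux minimization).
    Returns the optimal flux vector and the minimized weighted sum.
    """
    settings = settings or LPSettings()
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    z = fba(network, settings).objective_value
    if z <= 0:
        raise InfeasibleModelError(
            f"objective optimum must be positive for parsimonious analysis, got {z}"
        )
    lp = _SplitLP(network)
    lp.add(LinearConstraint({network.objective_id: 1.0}, ">=", fraction * z))
    c = np.zeros(2 * lp.R)
    for rid, w in weights.weight.items():
        j = network._rxn_index[rid]
        c[j] += w
        c[lp.R + j] += w
    try:
        res = lp.solve(c, settings)
    except InfeasibleModelError:
        raise InfeasibleModelError(
            f"no flux distribution attains {fraction:.3f} of the optimum"
        ) from None
    v = lp.flux_vector(res.x)
    flux = {r: float(v[i]) for i, r in enumerate(network.reaction_ids)}
    obj = flux[network.objective_id]
    return FluxDistribution(flux=flux, objective_value=obj), float(res.fun)
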