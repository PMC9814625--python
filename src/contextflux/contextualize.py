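"""Per-patient context-specific model extraction and flux sampling.

For one patient the pipeline is:

1. project the patient's transcript abundances onto reactions and turn
   them into parsimony weights (high expression -> cheap flux);
2. transcript-weighted pFBA at a required fraction of the FBA optimum
   gives the minimal weighted total flux (the parsimony value);
3. FVA under both constraints — objective >= fraction * Z and weighted
   total flux <= (1 + slack) * parsimony value — yields the flux range
   each reaction can carry in any near-parsimonious optimal state;
4. reactions whose range collapses to ~0 are pruned: the patient's
   transcriptome gives the model no parsimonious reason to use them.

The surviving polytope is then explored with artificial-centering
hit-and-run sampling to produce the per-patient flux points consumed by
the downstream classifier. The number of points scales with the mean
permissible flux range, clamped to [50, 500].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lp import (
    AbsFluxCap,
    LinearConstraint,
    LPSettings,
    fba,
    fva,
    weighted_pfba,
)
from .network import MetabolicNetwork, remove_reactions
from .transcripts import (
    ReactionWeights,
    TranscriptProfile,
    abundance_to_weights,
    reaction_abundance,
)

__all__ = [
    "ContextualizedModel",
    "FluxSampleSet",
    "contextualize",
    "choose_sample_count",
    "sample_fluxes",
    "PRUNING_TOLERANCE",
]

logger = logging.getLogger(__name__)

#: absolute flux below which a reaction counts as unable to carry flux
PRUNING_TOLERANCE = 1e-6

MIN_SAMPLES = 50
MAX_SAMPLES = 500


@dataclass
class ContextualizedModel:
    """Result of pruning one patient's network."""

    patient_id: str
    group: str
    retained: list[str]
    pruned: list[str]
    flux_ranges: dict[str, tuple[float, float]]
    parsimony_value: float
    objective_value: float
    fraction: float

    def to_json_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "group": self.group,
            "retained": self.retained,
            "pruned": self.pruned,
            "flux_ranges": {r: list(v) for r, v in self.flux_ranges.items()},
            "parsimony_value": self.parsimony_value,
            "objective_value": self.objective_value,
            "fraction": self.fraction,
        }

    @classmethod
    def from_json_dict(cls, doc: dict) -> "ContextualizedModel":
        return cls(
            patient_id=doc["patient_id"],
            group=doc["group"],
            retained=list(doc["retained"]),
            pruned=list(doc["pruned"]),
            flux_ranges={r: tuple(v) for r, v in doc["flux_ranges"].items()},
            parsimony_value=doc["parsimony_value"],
            objective_value=doc["objective_value"],
            fraction=doc["fraction"],
        )


@dataclass
class FluxSampleSet:
    """Feasible flux vectors sampled from one patient's pruned polytope."""

    patient_id: str
    group: str
    reaction_ids: list[str]
    samples: np.ndarray  # n_samples x n_reactions
    seed: int

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    def write(self, prefix: str | Path) -> None:
        """Write ``<prefix>.tsv`` (flux matrix) and ``<prefix>.json`` (metadata)."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".tsv"), "w") as fh:
            fh.write("\t".join(self.reaction_ids) + "\n")
            for row in self.samples:
                fh.write("\t".join(format(v, ".10g") for v in row) + "\n")
        meta = {
            "patient_id": self.patient_id,
            "group": self.group,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")


def contextualize(
    network: MetabolicNetwork,
    profile: TranscriptProfile,
    fraction: float = 1.0,
    settings: LPSettings | None = None,
    pruning_tolerance: float = PRUNING_TOLERANCE,
) -> ContextualizedModel:
    """Prune one patient's network to its parsimony-consistent core.

    ``network`` must already be restricted to genes shared with the data
    (the gene overlay); ``fraction`` is the required fraction of the FBA
    optimum (1.0 by default: only exactly-optimal states count).
    """
    settings = settings or LPSettings()
    abund = reaction_abundance(network, profile)
    weights = abundance_to_weights(abund)
    z = fba(network, settings).objective_value
    _, parsimony_value = weighted_pfba(network, weights, fraction, settings)
    cap = (1.0 + settings.parsimony_slack) * parsimony_value + settings.feasibility_tolerance
    constraints = [
        LinearConstraint({network.objective_id: 1.0}, ">=", fraction * z),
        AbsFluxCap(weights.weight, cap),
    ]
    ranges = fva(network, constraints, settings=settings)
    retained, pruned = [], []
    flux_ranges = {}
    for rid in network.reaction_ids:
        lo, hi = ranges[rid]
        if max(abs(lo), abs(hi)) <= pruning_tolerance:
            pruned.append(rid)
        else:
            retained.append(rid)
            flux_ranges[rid] = (lo, hi)
    if network.objective_id in pruned:
        raise RuntimeError(
            f"pruning removed the objective reaction for patient "
            f"{profile.sample_id!r}; fraction={fraction} leaves no optimal flux"
        )
    return ContextualizedModel(
        patient_id=profile.sample_id,
        group=profile.group,
        retained=retained,
        pruned=pruned,
        flux_ranges=flux_ranges,
        parsimony_value=parsimony_value,
        objective_value=z,
        fraction=fraction,
    )


def choose_sample_count(flux_ranges: dict[str, tuple[float, float]]) -> int:
    """Sample count from the mean permissible range width, clamped to [50, 500]."""
    if not flux_ranges:
        return MIN_SAMPLES
    widths = [hi - lo for lo, hi in flux_ranges.values()]
    n = round(float(np.mean(widths)))
    return int(min(MAX_SAMPLES, max(MIN_SAMPLES, n)))


def _cap_interval(
    x: np.ndarray, d: np.ndarray, w: np.ndarray, cap: float, t_lo: float, t_hi: float
) -> tuple[float, float]:
    """Restrict [t_lo, t_hi] to {t : sum w|x + t d| <= cap}.

    g(t) is convex piecewise-linear and g(0) <= cap, so the feasible set
    is an interval around 0; each endpoint is found by bisection.
    """

    def g(t: float) -> float:
        return float(w @ np.abs(x + t * d))

    def shrink(t_end: float) -> float:
        if g(t_end) <= cap:
            return t_end
        lo, hi = 0.0, t_end  # g(lo) <= cap < g(hi) along this side
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if g(mid) <= cap:
                lo = mid
            else:
                hi = mid
        return lo

    return shrink(t_lo), shrink(t_hi)


def sample_fluxes(
    ctx: ContextualizedModel,
    network: MetabolicNetwork,
    weights: ReactionWeights,
    n: int,
    seed: int,
    settings: LPSettings | None = None,
    burn_in: int = 100,
    thinning: int = 10,
) -> FluxSampleSet:
    """Artificial-centering hit-and-run over the pruned patient polytope.

    The polytope is {S v = 0, bounds, v_obj >= fraction * Z, weighted
    total flux <= parsimony cap} restricted to the retained reactions.
    Warmup points are the FVA extreme vertices; directions are drawn
    from warmup-minus-center (so steps stay inside the null space of S);
    chords are clipped against bounds, the objective floor, and the
    convex parsimony cap. A zero-volume polytope yields n copies of the
    weighted-pFBA vertex with a warning.
    """
    settings = settings or LPSettings()
    if not (MIN_SAMPLES <= n <= MAX_SAMPLES):
        raise ValueError(f"n must lie in [{MIN_SAMPLES}, {MAX_SAMPLES}], got {n}")
    reduced = remove_reactions(network, ctx.pruned) if ctx.pruned else network
    rids = reduced.reaction_ids
    w_map = {r: weights.weight[r] for r in rids}
    w_vec = np.array([w_map[r] for r in rids])
    cap = (
        (1.0 + settings.parsimony_slack) * ctx.parsimony_value
        + settings.feasibility_tolerance
    )
    obj_floor = ctx.fraction * ctx.objective_value
    constraints = [
        LinearConstraint({reduced.objective_id: 1.0}, ">=", obj_floor),
        AbsFluxCap(w_map, cap),
    ]
    ranges, warmup = fva(reduced, constraints, settings=settings, keep_vertices=True)
    widths = np.array([hi - lo for lo, hi in ranges.values()])
    if np.all(widths <= 1e-9):
        logger.warning(
            "patient %s: zero-volume flux polytope; returning %d copies of the "
            "parsimonious optimum", ctx.patient_id, n,
        )
        dist, _ = weighted_pfba(reduced, ReactionWeights(w_map), ctx.fraction, settings)
        row = dist.as_array(rids)
        return FluxSampleSet(
            patient_id=ctx.patient_id,
            group=ctx.group,
            reaction_ids=list(rids),
            samples=np.tile(row, (n, 1)),
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    W = np.array(warmup)
    lb, ub = reduced.bounds_arrays()
    j_obj = reduced._rxn_index[reduced.objective_id]
    center = W.mean(axis=0)
    x = center.copy()
    count = W.shape[0]
    rows: list[np.ndarray] = []
    it = 0
    target_iters = burn_in + thinning * n
    while len(rows) < n:
        d = W[rng.integers(W.shape[0])] - center
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            it += 1
            if it > 100 * target_iters:  # pathological; fall back to the center
                rows.append(x.copy())
            continue
        # chord limits from the box bounds
        with np.errstate(divide="ignore", invalid="ignore"):
            t_up = np.where(d > 1e-11, (ub - x) / d, np.inf)
            t_up = np.minimum(t_up, np.where(d < -1e-11, (lb - x) / d, np.inf))
            t_dn = np.where(d > 1e-11, (lb - x) / d, -np.inf)
            t_dn = np.maximum(t_dn, np.where(d < -1e-11, (ub - x) / d, -np.inf))
        t_hi = float(np.min(t_up))
        t_lo = float(np.max(t_dn))
        # objective floor: x_obj + t d_obj >= obj_floor
        if d[j_obj] > 1e-11:
            t_lo = max(t_lo, (obj_floor - x[j_obj]) / d[j_obj])
        elif d[j_obj] < -1e-11:
            t_hi = min(t_hi, (obj_floor - x[j_obj]) / d[j_obj])
        t_lo, t_hi = _cap_interval(x, d, w_vec, cap, t_lo, t_hi)
        if t_hi <= t_lo:
            it += 1
            continue
        t = rng.uniform(t_lo, t_hi)
        x = x + t * d
        center = (center * count + x) / (count + 1)
        count += 1
        it += 1
        if it > burn_in and (it - burn_in) % thinning == 0:
            rows.append(x.copy())
    return FluxSampleSet(
        patient_id=ctx.patient_id,
        group=ctx.group,
        reaction_ids=list(rids),
        samples=np.array(rows),
        seed=seed,
    )
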