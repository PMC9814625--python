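"""Stoichiometric model container and file I/O.

The central object is :class:`MetabolicNetwork`, a minimal immutable-ish
view of a genome-scale metabolic network reconstruction (GENRE): the
stoichiometric matrix S as per-reaction metabolite coefficient maps,
flux bounds, GPR rules, subsystem labels and a declared (biomass)
objective reaction. Flux units are arbitrary but consistent across the
model (conventionally mmol/gDW/h).

COBRA-JSON is the canonical on-disk dialect (read and write, with
byte-stable output so round-trips are testable); SBML Level 3 FBC is
supported read-only through cobrapy/libsbml.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gpr import GPRExpression, gpr_genes, gpr_to_string, parse_gpr

__all__ = [
    "MetabolicNetwork",
    "FluxDistribution",
    "ModelValidationError",
    "load_model",
    "write_model",
    "remove_reactions",
]

#: default bounds applied when a file omits them
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)


class ModelValidationError(ValueError):
    """A network violates a structural invariant."""


@dataclass
class MetabolicNetwork:
    """A validated stoichiometric network.

    Attributes
    ----------
    metabolite_ids, reaction_ids:
        Unique identifier lists; order is meaningful (it fixes the row
        and column order of the stoichiometric matrix).
    stoichiometry:
        reaction id -> {metabolite id -> signed coefficient}; negative
        coefficients consume, positive produce.
    lower_bound, upper_bound:
        reaction id -> flux bound.
    gpr:
        reaction id -> GPR tree, or None for gene-less reactions.
    subsystem:
        reaction id -> pathway label ("" when unannotated).
    objective_id:
        id of the reaction whose flux is maximized (biomass).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    stoichiometry: dict[str, dict[str, float]]
    lower_bound: dict[str, float]
    upper_bound: dict[str, float]
    gpr: dict[str, GPRExpression | None]
    subsystem: dict[str, str]
    objective_id: str
    model_id: str = "model"
    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}

    def validate(self) -> None:
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ModelValidationError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise ModelValidationError("duplicate reaction ids")
        met_set = set(self.metabolite_ids)
        for rid in self.reaction_ids:
            for mid in self.stoichiometry.get(rid, {}):
                if mid not in met_set:
                    raise ModelValidationError(
                        f"reaction {rid!r} references unknown metabolite {mid!r}"
                    )
            lb, ub = self.lower_bound[rid], self.upper_bound[rid]
            if lb > ub:
                raise ModelValidationError(
                    f"reaction {rid!r} has lower_bound {lb} > upper_bound {ub}"
                )
        if self.objective_id not in set(self.reaction_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in the network"
            )

    # -- convenience ----------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def genes(self) -> set[str]:
        """All gene ids referenced by any GPR rule."""
        out: set[str] = set()
        for rid in self.reaction_ids:
            out |= gpr_genes(self.gpr.get(rid))
        return out

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions) in id-list order."""
        met_index = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((self.n_metabolites, self.n_reactions))
        for j, rid in enumerate(self.reaction_ids):
            for mid, coef in self.stoichiometry.get(rid, {}).items():
                S[met_index[mid], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([self.lower_bound[r] for r in self.reaction_ids])
        ub = np.array([self.upper_bound[r] for r in self.reaction_ids])
        return lb, ub

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            stoichiometry={r: dict(c) for r, c in self.stoichiometry.items()},
            lower_bound=dict(self.lower_bound),
            upper_bound=dict(self.upper_bound),
            gpr=dict(self.gpr),
            subsystem=dict(self.subsystem),
            objective_id=self.objective_id,
            model_id=self.model_id,
        )


@dataclass
class FluxDistribution:
    """One steady-state flux vector with its objective value."""

    flux: dict[str, float]
    objective_value: float

    def as_array(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.flux[r] for r in reaction_ids])


# -- COBRA-JSON I/O ------------------------------------------------------


def _network_from_json_dict(doc: dict, source: str) -> MetabolicNetwork:
    try:
        mets = [m["id"] for m in doc["metabolites"]]
        rxns = doc["reactions"]
    except KeyError as exc:
        raise ModelValidationError(f"{source}: missing element {exc}") from exc

    reaction_ids: list[str] = []
    stoich: dict[str, dict[str, float]] = {}
    lb: dict[str, float] = {}
    ub: dict[str, float] = {}
    gpr: dict[str, GPRExpression | None] = {}
    subsystem: dict[str, str] = {}
    objective: str | None = None
    for rx in rxns:
        try:
            rid = rx["id"]
        except KeyError as exc:
            raise ModelValidationError(f"{source}: reaction without id") from exc
        reaction_ids.append(rid)
        stoich[rid] = {m: float(c) for m, c in rx.get("metabolites", {}).items()}
        if "lower_bound" in rx or "upper_bound" in rx:
            lb[rid] = float(rx.get("lower_bound", DEFAULT_REVERSIBLE_BOUNDS[0]))
            ub[rid] = float(rx.get("upper_bound", DEFAULT_REVERSIBLE_BOUNDS[1]))
        elif rx.get("reversibility", True):
            lb[rid], ub[rid] = DEFAULT_REVERSIBLE_BOUNDS
        else:
            lb[rid], ub[rid] = DEFAULT_IRREVERSIBLE_BOUNDS
        try:
            gpr[rid] = parse_gpr(rx.get("gene_reaction_rule", ""))
        except ValueError as exc:
            raise ModelValidationError(
                f"{source}: bad GPR on reaction {rid!r}: {exc}"
            ) from exc
        subsystem[rid] = rx.get("subsystem") or ""
        if float(rx.get("objective_coefficient", 0.0)) != 0.0:
            objective = rid
    if objective is None:
        raise ModelValidationError(f"{source}: no objective declared")
    return MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=reaction_ids,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gpr=gpr,
        subsystem=subsystem,
        objective_id=objective,
        model_id=doc.get("id", "model"),
    )


def _network_from_sbml(path: Path) -> MetabolicNetwork:
    # cobrapy handles the SBML L3 FBC dialect; convert to our container.
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    objective = None
    reaction_ids, stoich, lb, ub, gpr, subsystem = [], {}, {}, {}, {}, {}
    obj_coefs = cobra.util.solver.linear_reaction_coefficients(model)
    for rx in model.reactions:
        reaction_ids.append(rx.id)
        stoich[rx.id] = {m.id: float(c) for m, c in rx.metabolites.items()}
        lb[rx.id], ub[rx.id] = float(rx.lower_bound), float(rx.upper_bound)
        gpr[rx.id] = parse_gpr(rx.gene_reaction_rule)
        subsystem[rx.id] = rx.subsystem or ""
        if rx in obj_coefs and obj_coefs[rx] != 0:
            objective = rx.id
    if objective is None:
        raise ModelValidationError(f"{path}: no objective declared")
    return MetabolicNetwork(
        metabolite_ids=[m.id for m in model.metabolites],
        reaction_ids=reaction_ids,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gpr=gpr,
        subsystem=subsystem,
        objective_id=objective,
        model_id=model.id or "model",
    )


def load_model(path: str | Path, format: str | None = None) -> MetabolicNetwork:
    """Load a network from COBRA-JSON or SBML.

    ``format`` is ``"cobra-json"`` or ``"sbml"``; when None it is
    inferred from the file suffix (.json vs .xml/.sbml).
    """
    path = Path(path)
    if format is None:
        format = "cobra-json" if path.suffix.lower() == ".json" else "sbml"
    if format == "cobra-json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"{path}: not valid JSON: {exc}") from exc
        return _network_from_json_dict(doc, str(path))
    if format == "sbml":
        return _network_from_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def network_to_json_dict(network: MetabolicNetwork) -> dict:
    """The COBRA-JSON document for a network (deterministic ordering)."""
    genes = sorted(network.genes())
    reactions = []
    for rid in network.reaction_ids:
        reactions.append(
            {
                "id": rid,
                "metabolites": {
                    m: network.stoichiometry[rid][m]
                    for m in sorted(network.stoichiometry.get(rid, {}))
                },
                "lower_bound": network.lower_bound[rid],
                "upper_bound": network.upper_bound[rid],
                "gene_reaction_rule": gpr_to_string(network.gpr.get(rid)),
                "subsystem": network.subsystem.get(rid, ""),
                "objective_coefficient": 1.0 if rid == network.objective_id else 0.0,
            }
        )
    return {
        "id": network.model_id,
        "metabolites": [{"id": m} for m in network.metabolite_ids],
        "reactions": reactions,
        "genes": [{"id": g} for g in genes],
        "version": "1",
    }


def write_model(network: MetabolicNetwork, path: str | Path) -> None:
    """Write COBRA-JSON with stable key order and newline-terminated output."""
    doc = network_to_json_dict(network)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


# -- structural edits ----------------------------------------------------


def remove_reactions(
    network: MetabolicNetwork, ids: list[str] | set[str]
) -> MetabolicNetwork:
    """A new network without the listed reactions.

    Metabolites no longer referenced by any surviving reaction are
    dropped. The objective cannot be removed.
    """
    ids = set(ids)
    unknown = ids - set(network.reaction_ids)
    if unknown:
        raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
    if network.objective_id in ids:
        raise ModelValidationError(
            f"cannot remove the objective reaction {network.objective_id!r}"
        )
    keep = [r for r in network.reaction_ids if r not in ids]
    referenced = set()
    for rid in keep:
        referenced |= set(network.stoichiometry.get(rid, {}))
    return MetabolicNetwork(
        metabolite_ids=[m for m in network.metabolite_ids if m in referenced],
        reaction_ids=keep,
        stoichiometry={r: dict(network.stoichiometry.get(r, {})) for r in keep},
        lower_bound={r: network.lower_bound[r] for r in keep},
        upper_bound={r: network.upper_bound[r] for r in keep},
        gpr={r: network.gpr.get(r) for r in keep},
        subsystem={r: network.subsystem.get(r, "") for r in keep},
        objective_id=network.objective_id,
        model_id=network.model_id,
    )
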