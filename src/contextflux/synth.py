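"""Synthetic benchmark: toy networks and two-group transcript cohorts.

The generator emulates the statistical structure the pipeline assumes:
a metabolic network offering *redundant alternative routes* to biomass,
and a two-group cohort whose expression difference is concentrated on
the genes of those routes. Transcript-guided parsimony then selects a
different route per group, which is exactly what makes the route
reactions discriminative downstream.

The toy network is one bounded substrate uptake feeding several
parallel linear pathways into a biomass precursor, plus gene-bearing
background reactions (paired import/export loops) that are flux-neutral
with respect to biomass. Abundances are log-normal around a positive
baseline, with a configurable fold-change planted on pathway genes:
case samples over-express pathway 1 and under-express pathway 2,
control samples the reverse. ``effect_fold = 1`` produces an
exchangeable null cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._rng import TAG_COHORT, derive_seed
from .network import MetabolicNetwork, write_model
from .transcripts import TranscriptProfile
from .gpr import Gene

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_toy_network",
    "simulate_cohort",
    "write_fixture_bundle",
]


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic benchmark (defaults define the standard cohort)."""

    n_linear_pathways: int = 2
    pathway_length: int = 3
    n_background_reactions: int = 10
    n_case: int = 20
    n_control: int = 20
    effect_fold: float = 4.0  # fold-change planted on pathway genes
    noise_sigma: float = 0.5  # log-normal scale of abundance noise
    base_abundance: float = 10.0  # RPKM-like baseline
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_linear_pathways", "pathway_length", "n_background_reactions",
            "n_case", "n_control",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")


@dataclass
class GroundTruth:
    """Which reactions were planted as group-favored."""

    planted_case_reactions: list[str]
    planted_control_reactions: list[str]
    gene_pathway: dict[str, str]
    null_cohort: bool = False


UPTAKE_BOUND = 10.0
BACKGROUND_BOUND = 5.0


def make_toy_network(spec: SyntheticSpec) -> tuple[MetabolicNetwork, GroundTruth]:
    """Build the branched toy network with parallel routes to biomass.

    Structure: uptake 0 -> A bounded [0, 10]; each pathway k is a linear
    chain A -> ... -> B of ``pathway_length`` single-gene reactions;
    biomass B -> 0 is the objective. Background reactions are paired
    import/export loops through dedicated metabolites, each with its own
    gene. Pathway 1 is planted as case-favored, pathway 2 (when present)
    as control-favored.
    """
    metabolites = ["A", "B"]
    reaction_ids: list[str] = []
    stoich: dict[str, dict[str, float]] = {}
    lb: dict[str, float] = {}
    ub: dict[str, float] = {}
    gpr: dict = {}
    subsystem: dict[str, str] = {}
    gene_pathway: dict[str, str] = {}

    def add(rid, coefs, lo, hi, gene, label):
        reaction_ids.append(rid)
        stoich[rid] = coefs
        lb[rid], ub[rid] = lo, hi
        gpr[rid] = Gene(gene) if gene else None
        subsystem[rid] = label

    add("uptake_A", {"A": 1.0}, 0.0, UPTAKE_BOUND, None, "Transport")

    pathway_rxns: dict[int, list[str]] = {}
    for k in range(1, spec.n_linear_pathways + 1):
        chain = ["A"] + [f"P{k}_m{i}" for i in range(1, spec.pathway_length)] + ["B"]
        metabolites.extend(chain[1:-1])
        pathway_rxns[k] = []
        for i in range(spec.pathway_length):
            rid = f"P{k}_r{i + 1}"
            gene = f"g_{rid}"
            add(
                rid,
                {chain[i]: -1.0, chain[i + 1]: 1.0},
                0.0, 1000.0, gene, f"Pathway{k}",
            )
            gene_pathway[gene] = f"Pathway{k}"
            pathway_rxns[k].append(rid)

    add("biomass", {"B": -1.0}, 0.0, 1000.0, None, "Transport")

    for j in range(1, spec.n_background_reactions + 1):
        pair = (j + 1) // 2
        mid = f"C{pair}"
        if mid not in metabolites:
            metabolites.append(mid)
        if j % 2 == 1:
            rid, coefs = f"BG{pair}_in", {mid: 1.0}
        else:
            rid, coefs = f"BG{pair}_out", {mid: -1.0}
        gene = f"g_{rid}"
        add(rid, coefs, 0.0, BACKGROUND_BOUND, gene, "Background")
        gene_pathway[gene] = "Background"

    network = MetabolicNetwork(
        metabolite_ids=metabolites,
        reaction_ids=reaction_ids,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gpr=gpr,
        subsystem=subsystem,
        objective_id="biomass",
        model_id=f"toy_{spec.n_linear_pathways}x{spec.pathway_length}",
    )
    truth = GroundTruth(
        planted_case_reactions=list(pathway_rxns.get(1, [])),
        planted_control_reactions=list(pathway_rxns.get(2, [])),
        gene_pathway=gene_pathway,
        null_cohort=spec.effect_fold == 1.0,
    )
    return network, truth


def simulate_cohort(
    network: MetabolicNetwork, truth: GroundTruth, spec: SyntheticSpec
) -> list[TranscriptProfile]:
    """Draw the two-group abundance cohort for a toy network.

    Per sample and gene: abundance = base * multiplier * exp(N(0, sigma))
    where the multiplier is ``effect_fold`` for the group's favored
    pathway genes, ``1/effect_fold`` for the opposing pathway's genes
    and 1 elsewhere. Fully reproducible from ``spec.seed``.
    """
    genes = sorted(network.genes())
    case_genes = {
        f"g_{r}" for r in truth.planted_case_reactions
    } & set(genes)
    control_genes = {
        f"g_{r}" for r in truth.planted_control_reactions
    } & set(genes)
    rng = np.random.default_rng(derive_seed(spec.seed, TAG_COHORT))
    profiles = []
    for group, count in (("case", spec.n_case), ("control", spec.n_control)):
        favored = case_genes if group == "case" else control_genes
        opposed = control_genes if group == "case" else case_genes
        for i in range(1, count + 1):
            noise = rng.normal(0.0, spec.noise_sigma, size=len(genes))
            abundance = {}
            for g, eps in zip(genes, noise):
                mult = 1.0
                if g in favored:
                    mult = spec.effect_fold
                elif g in opposed:
                    mult = 1.0 / spec.effect_fold
                abundance[g] = spec.base_abundance * mult * float(np.exp(eps))
            profiles.append(
                TranscriptProfile(
                    sample_id=f"{group}_{i:02d}", group=group, abundance=abundance
                )
            )
    return profiles


def write_fixture_bundle(outdir: str | Path, spec: SyntheticSpec) -> dict[str, Path]:
    """Write a complete pipeline input: model, abundances, labels, truth.

    Returns the paths of the four files. Regenerating with the same spec
    produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network, truth = make_toy_network(spec)
    profiles = simulate_cohort(network, truth, spec)

    model_path = outdir / "model.json"
    write_model(network, model_path)

    genes = sorted(network.genes())
    abundance_path = outdir / "abundance.tsv"
    with open(abundance_path, "w") as fh:
        fh.write("gene\t" + "\t".join(p.sample_id for p in profiles) + "\n")
        for g in genes:
            values = "\t".join(format(p.abundance[g], ".10g") for p in profiles)
            fh.write(f"{g}\t{values}\n")

    labels_path = outdir / "labels.csv"
    with open(labels_path, "w") as fh:
        fh.write("sample_id,group\n")
        for p in profiles:
            fh.write(f"{p.sample_id},{p.group}\n")

    truth_path = outdir / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "planted_case_reactions": truth.planted_case_reactions,
                "planted_control_reactions": truth.planted_control_reactions,
                "gene_pathway": truth.gene_pathway,
                "null_cohort": truth.null_cohort,
                "spec": {
                    "n_linear_pathways": spec.n_linear_pathways,
                    "pathway_length": spec.pathway_length,
                    "n_background_reactions": spec.n_background_reactions,
                    "n_case": spec.n_case,
                    "n_control": spec.n_control,
                    "effect_fold": spec.effect_fold,
                    "noise_sigma": spec.noise_sigma,
                    "base_abundance": spec.base_abundance,
                    "seed": spec.seed,
                },
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    return {
        "model": model_path,
        "abundance": abundance_path,
        "labels": labels_path,
        "ground_truth": truth_path,
    }
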