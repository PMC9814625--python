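"""Per-sample gene abundances and their projection onto reactions.

The ingestion contract mirrors how public RNA-seq matrices ship: a
genes-by-samples table of non-negative, RPKM-like values plus a sample
-> group label map. The values are accepted on whatever scale they come
in; no re-normalization is applied.

Contextualization uses abundances in two structural ways:

* the *gene overlay* removes reactions whose GPR cannot be satisfied by
  the genes shared between the model and the data (a gene is "present"
  when it has a row in the table, regardless of value);
* per-reaction abundances (AND=min, OR=max over the GPR) are mapped to
  parsimony weights w_r = 1 - a_r / max(a), so highly expressed
  reactions are cheap to use and silent ones expensive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import median

import pandas as pd

from .gpr import evaluate_gpr_abundance, evaluate_gpr_presence
from .network import MetabolicNetwork, remove_reactions

__all__ = [
    "TranscriptProfile",
    "ReactionWeights",
    "OverlayReport",
    "load_abundance_table",
    "overlay_genes",
    "reaction_abundance",
    "abundance_to_weights",
]

GROUPS = ("case", "control")


@dataclass
class TranscriptProfile:
    """One sample's gene -> abundance map with its group label."""

    sample_id: str
    group: str
    abundance: dict[str, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"sample {self.sample_id!r}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )
        for gene, value in self.abundance.items():
            if value < 0:
                raise ValueError(
                    f"negative abundance {value} for gene {gene!r} "
                    f"in sample {self.sample_id!r}"
                )


@dataclass
class ReactionWeights:
    """Parsimony weights in [0, 1], one per retained reaction."""

    weight: dict[str, float]

    def __post_init__(self) -> None:
        for rid, w in self.weight.items():
            if not (-1e-12 <= w <= 1 + 1e-12):
                raise ValueError(f"weight for {rid!r} outside [0, 1]: {w}")


@dataclass
class OverlayReport:
    """Bookkeeping of the model/data gene overlap and its consequences."""

    n_genes_model: int
    n_genes_data: int
    n_shared: int
    n_data_only: int
    n_model_only: int
    reactions_removed_by_gpr: list[str]


def load_abundance_table(
    path: str | Path, labels: dict[str, str]
) -> list[TranscriptProfile]:
    """Read a genes-by-samples TSV/CSV into one profile per column.

    ``labels`` maps every sample column to "case" or "control". Duplicate
    gene rows, unlabeled samples and negative values are rejected.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, index_col=0)
    dup = table.index[table.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicated gene row(s): {sorted(set(dup))}")
    profiles = []
    for sample in table.columns:
        if sample not in labels:
            raise ValueError(f"sample {sample!r} has no group label")
        col = table[sample]
        neg = col[col < 0]
        if len(neg):
            gene = neg.index[0]
            raise ValueError(
                f"negative abundance {neg.iloc[0]} for gene {gene!r} "
                f"in sample {sample!r}"
            )
        profiles.append(
            TranscriptProfile(
                sample_id=str(sample),
                group=labels[sample],
                abundance={str(g): float(v) for g, v in col.items()},
            )
        )
    return profiles


def load_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) CSV into a label map."""
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ValueError("label file needs columns (sample_id, group)")
    return {
        str(row.iloc[0]): str(row.iloc[1]).strip() for _, row in table.iterrows()
    }


def overlay_genes(
    network: MetabolicNetwork, profiles: list[TranscriptProfile]
) -> tuple[MetabolicNetwork, OverlayReport]:
    """Restrict the network to reactions supported by measured genes.

    Presence is structural: a gene is present iff it appears in the
    data's gene universe (model genes ∩ data genes). Reactions whose GPR
    evaluates false under that set are removed; gene-less reactions are
    always kept.
    """
    if not profiles:
        raise ValueError("need at least one transcript profile")
    gene_universe = set(profiles[0].abundance)
    for p in profiles[1:]:
        if set(p.abundance) != gene_universe:
            raise ValueError(
                f"sample {p.sample_id!r} has a different gene universe than "
                f"{profiles[0].sample_id!r}"
            )
    model_genes = network.genes()
    present = model_genes & gene_universe
    removed = [
        rid
        for rid in network.reaction_ids
        if not evaluate_gpr_presence(network.gpr.get(rid), present)
    ]
    report = OverlayReport(
        n_genes_model=len(model_genes),
        n_genes_data=len(gene_universe),
        n_shared=len(present),
        n_data_only=len(gene_universe - model_genes),
        n_model_only=len(model_genes - gene_universe),
        reactions_removed_by_gpr=removed,
    )
    if network.objective_id in removed:
        raise ValueError(
            "gene overlay would remove the objective reaction; "
            "the model is unusable with this dataset"
        )
    return remove_reactions(network, removed), report


def reaction_abundance(
    network: MetabolicNetwork, profile: TranscriptProfile
) -> dict[str, float]:
    """Project gene abundances onto reactions through the GPR rules.

    AND nodes take the minimum of their children (complex limited by the
    scarcest subunit), OR nodes the maximum (best isozyme). Reactions
    without genes receive the median of the gene-backed reaction scores,
    a neutral value for transport/exchange/biomass pseudo-reactions.
    """
    gene_backed: dict[str, float] = {}
    empty: list[str] = []
    for rid in network.reaction_ids:
        rule = network.gpr.get(rid)
        if rule is None:
            empty.append(rid)
        else:
            gene_backed[rid] = evaluate_gpr_abundance(rule, profile.abundance)
    neutral = median(gene_backed.values()) if gene_backed else 0.0
    out = dict(gene_backed)
    for rid in empty:
        out[rid] = neutral
    return out


def abundance_to_weights(reaction_abund: dict[str, float]) -> ReactionWeights:
    """Map abundances a_r to parsimony weights w_r = 1 - a_r / max(a).

    The most abundant reaction gets weight 0 (free to use), a silent
    reaction weight 1. All-zero abundances carry no transcriptomic
    signal and are rejected.
    """
    if not reaction_abund:
        raise ValueError("no reaction abundances given")
    peak = max(reaction_abund.values())
    if peak <= 0:
        raise ValueError("all reaction abundances are zero: no transcriptomic signal")
    return ReactionWeights(
        weight={rid: 1.0 - a / peak for rid, a in reaction_abund.items()}
    )
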