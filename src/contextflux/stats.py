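"""Group comparison, subsystem grouping and report rendering.

The group test is the two-sided Mann-Whitney U test on pooled flux
points (all sampled flux vectors of a group's patients pooled per
reaction); a per-patient-mean variant is available for sensitivity
analysis. Raw p < alpha is the significance rule; Benjamini-Hochberg
adjusted p-values are reported alongside as a supplementary column.

Discriminative reactions are grouped into "families" by their model
subsystem annotation, with an optional manual override table for
curated labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .classify import AggregatedRanking, FeatureTable
from .network import MetabolicNetwork

__all__ = [
    "ReactionComparison",
    "DiscriminativeReport",
    "mann_whitney_u",
    "compare_groups",
    "group_by_subsystem",
    "render_report",
]

#: largest pooled sample for which the exact permutation null is used
EXACT_MAX_N = 16


@dataclass
class ReactionComparison:
    reaction_id: str
    U: float
    p_value: float
    p_adjusted: float
    median_case: float
    median_control: float
    n_case: int
    n_control: int
    significant: bool


@dataclass
class DiscriminativeReport:
    """Everything the pipeline concludes, plus provenance metadata."""

    ranking: AggregatedRanking
    comparisons: list[ReactionComparison]
    families: dict[str, list[str]]
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact permutation distribution when the pooled sample has
    at most 16 observations and no ties; otherwise the tie-corrected
    normal approximation with continuity correction. Returns (U, p)
    with U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_groups(
    features: FeatureTable,
    reactions: list[str],
    alpha: float = 0.05,
    per_patient_mean: bool = False,
) -> list[ReactionComparison]:
    """Mann-Whitney comparison of case vs control flux for each reaction.

    By default all flux points of a group are pooled; with
    ``per_patient_mean`` each patient is first collapsed to its mean
    flux so the test sees one observation per patient.
    """
    unknown = set(reactions) - set(features.feature_ids)
    if unknown:
        raise KeyError(f"reactions not in the feature table: {sorted(unknown)}")
    col = {r: j for j, r in enumerate(features.feature_ids)}
    groups = np.array(features.row_group)
    case_mask = groups == "case"
    control_mask = groups == "control"
    if per_patient_mean:
        pat = np.array(features.row_patient)
        case_pats = sorted(set(pat[case_mask]))
        control_pats = sorted(set(pat[control_mask]))

    raw_p: list[float] = []
    partial: list[tuple[str, float, np.ndarray, np.ndarray]] = []
    for rid in reactions:
        j = col[rid]
        if per_patient_mean:
            x = np.array([features.X[pat == p, j].mean() for p in case_pats])
            y = np.array([features.X[pat == p, j].mean() for p in control_pats])
        else:
            x = features.X[case_mask, j]
            y = features.X[control_mask, j]
        U, p = mann_whitney_u(x, y)
        raw_p.append(p)
        partial.append((rid, U, x, y))
    adjusted = (
        multipletests(raw_p, method="fdr_bh")[1] if raw_p else np.array([])
    )
    out = []
    for (rid, U, x, y), p, p_adj in zip(partial, raw_p, adjusted):
        out.append(
            ReactionComparison(
                reaction_id=rid,
                U=U,
                p_value=p,
                p_adjusted=float(p_adj),
                median_case=float(np.median(x)),
                median_control=float(np.median(y)),
                n_case=int(x.size),
                n_control=int(y.size),
                significant=bool(p < alpha),
            )
        )
    return out


def group_by_subsystem(
    reactions: list[str],
    network: MetabolicNetwork,
    override: dict[str, str] | None = None,
) -> dict[str, list[str]]:
    """Group reactions into families by subsystem label.

    Precedence: manual override, then the model's subsystem annotation,
    then "Unassigned". Every input reaction lands in exactly one family.
    """
    override = override or {}
    families: dict[str, list[str]] = {}
    for rid in reactions:
        label = override.get(rid) or network.subsystem.get(rid, "") or "Unassigned"
        families.setdefault(label, []).append(rid)
    return families


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    format(v, ".10g") if isinstance(v, float) else str(v) for v in row
                )
                + "\n"
            )


def render_report(
    report: DiscriminativeReport,
    outdir: str | Path,
    features: FeatureTable | None = None,
    plots: bool = True,
) -> list[Path]:
    """Write ranking/comparisons/families TSVs, run metadata JSON and,
    when a feature table is given, one flux-distribution plot per family.

    Output is deterministic: identical reports produce byte-identical
    TSV and JSON files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = outdir / "ranking.tsv"
    _write_tsv(
        path,
        ["rank", "reaction_id", "frequency", "mean_importance"],
        [
            [e.rank, e.reaction_id, e.frequency, e.mean_importance]
            for e in report.ranking.entries
        ],
    )
    written.append(path)

    path = outdir / "comparisons.tsv"
    _write_tsv(
        path,
        [
            "reaction_id", "U", "p_value", "p_adjusted", "median_case",
            "median_control", "n_case", "n_control", "significant",
        ],
        [
            [
                c.reaction_id, c.U, c.p_value, c.p_adjusted, c.median_case,
                c.median_control, c.n_case, c.n_control, c.significant,
            ]
            for c in report.comparisons
        ],
    )
    written.append(path)

    path = outdir / "families.tsv"
    _write_tsv(
        path,
        ["family", "reaction_id"],
        [
            [family, rid]
            for family in sorted(report.families)
            for rid in report.families[family]
        ],
    )
    written.append(path)

    path = outdir / "metadata.json"
    with open(path, "w") as fh:
        json.dump(
            {"metadata": report.metadata, "warnings": report.warnings},
            fh, indent=1, sort_keys=True, default=str,
        )
        fh.write("\n")
    written.append(path)

    if plots and features is not None and report.families:
        written.extend(_plot_families(report, features, outdir))
    return written


def _significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _plot_families(
    report: DiscriminativeReport, features: FeatureTable, outdir: Path
) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pvals = {c.reaction_id: c.p_value for c in report.comparisons}
    col = {r: j for j, r in enumerate(features.feature_ids)}
    groups = np.array(features.row_group)
    written = []
    for family in sorted(report.families):
        rids = [r for r in report.families[family] if r in col]
        if not rids:
            continue
        fig, axes = plt.subplots(
            1, len(rids), figsize=(2.2 * len(rids) + 1, 3.2), squeeze=False
        )
        for ax, rid in zip(axes[0], rids):
            case = features.X[groups == "case", col[rid]]
            control = features.X[groups == "control", col[rid]]
            ax.boxplot(
                [control, case], tick_labels=["control", "case"], showfliers=False
            )
            title = rid
            if rid in pvals:
                title += f" ({_significance_stars(pvals[rid])})"
            ax.set_title(title, fontsize=8)
            ax.tick_params(labelsize=7)
        axes[0][0].set_ylabel("sampled flux")
        fig.suptitle(family, fontsize=10)
        fig.tight_layout()
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in family)
        path = outdir / f"family_{safe}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
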