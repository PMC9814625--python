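"""End-to-end orchestration: load -> overlay -> contextualize -> sample
-> classify -> compare -> report.

One :class:`RunConfig` carries every tunable; all stage seeds (cohort
under-sampling, patient splits, forests, flux samplers) are derived
deterministically from ``master_seed``, so a run is reproducible from
the config alone. Per-patient contextualizations are cached on disk
keyed by (model content, profile content, fraction, tolerances) because
the LP stage dominates runtime and re-runs of the classifier stage
should be cheap.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._rng import TAG_SAMPLER, derive_seed
from .classify import (
    NoQualifyingSplitsError,
    AggregatedRanking,
    SplitResult,
    aggregate_top_reactions,
    assemble_feature_matrix,
    mean_accuracy,
    repeated_validation,
)
from .contextualize import (
    ContextualizedModel,
    choose_sample_count,
    contextualize,
    sample_fluxes,
)
from .lp import LPSettings
from .network import load_model, network_to_json_dict
from .stats import (
    DiscriminativeReport,
    compare_groups,
    group_by_subsystem,
    render_report,
)
from .transcripts import (
    abundance_to_weights,
    load_abundance_table,
    load_label_map,
    overlay_genes,
    reaction_abundance,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ConfigError"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Resolved pipeline configuration (defaults match the reference protocol)."""

    model: str = ""
    abundance: str = ""
    labels: str = ""
    outdir: str = "contextflux_out"
    fraction: float = 1.0
    n_splits: int = 100
    train_frac: float = 0.8
    f1_min: float = 0.70
    top_k: int = 20
    alpha: float = 0.05
    master_seed: int = 0
    pooling: str = "pooled"  # or "per_patient_mean"
    plots: bool = True
    cache: bool = True
    lp: dict = field(default_factory=dict)
    rf: dict = field(default_factory=dict)

    def lp_settings(self) -> LPSettings:
        return LPSettings(**self.lp)

    def check(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ConfigError(f"fraction must lie in (0, 1], got {self.fraction}")
        if not (0 < self.train_frac < 1):
            raise ConfigError(f"train_frac must lie in (0, 1), got {self.train_frac}")
        if not (0 <= self.f1_min < 1):
            raise ConfigError(f"f1_min must lie in [0, 1), got {self.f1_min}")
        if not (0 <= self.alpha <= 1):
            raise ConfigError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.n_splits < 1:
            raise ConfigError(f"n_splits must be >= 1, got {self.n_splits}")
        if self.top_k < 1:
            raise ConfigError(f"top_k must be >= 1, got {self.top_k}")
        if self.pooling not in ("pooled", "per_patient_mean"):
            raise ConfigError(f"pooling must be 'pooled' or 'per_patient_mean'")
        try:
            self.lp_settings()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"lp settings invalid: {exc}") from exc


def validate_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file, fill defaults, and range-check."""
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    doc.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    config = RunConfig(**doc)
    config.check()
    return config


# -- contextualization with on-disk cache --------------------------------


def _cache_key(network, profile, fraction, settings: LPSettings) -> str:
    payload = json.dumps(
        {
            "model": network_to_json_dict(network),
            "abundance": sorted(profile.abundance.items()),
            "group": profile.group,
            "fraction": fraction,
            "tolerances": [
                settings.feasibility_tolerance,
                settings.mass_balance_tolerance,
                settings.parsimony_slack,
            ],
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:24]


def contextualize_cohort(
    network, profiles, config: RunConfig
) -> tuple[list[ContextualizedModel], list]:
    """Contextualize and flux-sample every patient (cached when enabled)."""
    settings = config.lp_settings()
    cache_dir = Path(config.outdir) / "cache"
    ctxs, sample_sets = [], []
    for idx, profile in enumerate(profiles):
        ctx = None
        key = None
        if config.cache:
            key = _cache_key(network, profile, config.fraction, settings)
            cache_file = cache_dir / f"ctx_{profile.sample_id}_{key}.json"
            if cache_file.exists():
                with open(cache_file) as fh:
                    ctx = ContextualizedModel.from_json_dict(json.load(fh))
        if ctx is None:
            ctx = contextualize(network, profile, config.fraction, settings)
            if config.cache:
                cache_dir.mkdir(parents=True, exist_ok=True)
                with open(cache_dir / f"ctx_{profile.sample_id}_{key}.json", "w") as fh:
                    json.dump(ctx.to_json_dict(), fh)
        weights = abundance_to_weights(reaction_abundance(network, profile))
        n = choose_sample_count(ctx.flux_ranges)
        seed = derive_seed(config.master_seed, TAG_SAMPLER, idx)
        sample_sets.append(
            sample_fluxes(ctx, network, weights, n, seed, settings)
        )
        ctxs.append(ctx)
    return ctxs, sample_sets


def run_pipeline(config: RunConfig) -> DiscriminativeReport:
    """Execute every stage and render the report into ``config.outdir``.

    Raises stage-specific errors; the one recoverable condition is "no
    qualifying splits", which produces a report with an empty ranking
    and a prominent warning instead of aborting.
    """
    config.check()
    timings: dict[str, float] = {}
    warnings_list: list[str] = []

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    name = stage("load")
    network = load_model(config.model)
    labels = load_label_map(config.labels)
    profiles = load_abundance_table(config.abundance, labels)
    done(name)

    name = stage("overlay")
    overlaid, overlay_report = overlay_genes(network, profiles)
    done(name)
    logger.info(
        "gene overlay: %d model genes, %d data genes, %d shared; %d reactions removed",
        overlay_report.n_genes_model, overlay_report.n_genes_data,
        overlay_report.n_shared, len(overlay_report.reactions_removed_by_gpr),
    )

    name = stage("contextualize")
    ctxs, sample_sets = contextualize_cohort(overlaid, profiles, config)
    pruned_counts = [len(c.pruned) for c in ctxs]
    done(name)
    logger.info(
        "contextualized %d patients; mean reactions pruned %.1f",
        len(ctxs), float(np.mean(pruned_counts)),
    )

    name = stage("classify")
    features = assemble_feature_matrix(sample_sets)
    results = repeated_validation(
        features,
        n_splits=config.n_splits,
        master_seed=config.master_seed,
        train_frac=config.train_frac,
        rf_params=config.rf or None,
    )
    acc = mean_accuracy(results)
    done(name)
    logger.info("mean test accuracy over %d splits: %.3f", len(results), acc)

    name = stage("aggregate")
    try:
        ranking = aggregate_top_reactions(results, f1_min=config.f1_min, k=config.top_k)
    except NoQualifyingSplitsError as exc:
        msg = (
            f"WARNING: {exc}; the groups are not discriminable at "
            f"F1 > {config.f1_min} and the ranking is empty"
        )
        logger.warning(msg)
        warnings_list.append(msg)
        ranking = AggregatedRanking(qualifying_split_ids=[], entries=[])
    done(name)

    name = stage("compare")
    top = ranking.top(config.top_k)
    comparisons = compare_groups(
        features, top, alpha=config.alpha,
        per_patient_mean=config.pooling == "per_patient_mean",
    )
    families = group_by_subsystem(top, overlaid)
    done(name)

    report = DiscriminativeReport(
        ranking=ranking,
        comparisons=comparisons,
        families=families,
        metadata={
            "config": asdict(config),
            "overlay": {
                "n_genes_model": overlay_report.n_genes_model,
                "n_genes_data": overlay_report.n_genes_data,
                "n_shared": overlay_report.n_shared,
                "n_data_only": overlay_report.n_data_only,
                "n_model_only": overlay_report.n_model_only,
                "n_reactions_removed": len(overlay_report.reactions_removed_by_gpr),
            },
            "n_patients": len(profiles),
            "mean_reactions_pruned": float(np.mean(pruned_counts)),
            "sample_counts": {s.patient_id: s.n_samples for s in sample_sets},
            "mean_accuracy": acc,
            "n_qualifying_splits": len(ranking.qualifying_split_ids),
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        },
        warnings=warnings_list,
    )

    stage("render")
    render_report(report, config.outdir, features=features, plots=config.plots)
    _write_splits_tsv(results, Path(config.outdir) / "splits.tsv")
    done("render")
    return report


def _write_splits_tsv(results: list[SplitResult], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("split_id\taccuracy\tf1\tn_train_patients\tn_test_patients\n")
        for r in results:
            fh.write(
                f"{r.split_id}\t{r.accuracy:.10g}\t{r.f1:.10g}"
                f"\t{len(r.train_patients)}\t{len(r.test_patients)}\n"
            )
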