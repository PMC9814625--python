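"""Discriminative-reaction discovery by repeated random-forest validation.

Each patient contributes a block of sampled flux vectors. Because those
rows are highly correlated within a patient, all splitting happens at
the *patient* level: a patient's rows are either all training or all
test, never both. Class imbalance between groups is handled by random
under-sampling of majority-group patients before every split.

A split trains a random forest (scikit-learn, 100 trees, Gini impurity,
sqrt(p) features per node) on the training patients' rows and evaluates
row-level accuracy and F1 (positive class "case") on the held-out
patients' rows. Splits whose F1 exceeds a threshold contribute their
top-k most important reactions to a consensus ranking ordered by how
often a reaction qualifies, then by mean importance.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score

from ._rng import TAG_FOREST, TAG_SPLIT, TAG_UNDERSAMPLE, derive_seed
from .contextualize import FluxSampleSet

__all__ = [
    "FeatureTable",
    "SplitResult",
    "AggregatedRanking",
    "RankedReaction",
    "NoQualifyingSplitsError",
    "assemble_feature_matrix",
    "undersample_patients",
    "split_patients",
    "run_split",
    "repeated_validation",
    "aggregate_top_reactions",
    "DEFAULT_RF_PARAMS",
]

DEFAULT_RF_PARAMS = {
    "n_estimators": 100,
    "criterion": "gini",
    "max_depth": None,
    "max_features": "sqrt",
    "n_jobs": 1,
}


@dataclass
class FeatureTable:
    """Flux points from all patients as one rows-by-reactions matrix.

    Reactions pruned in a given patient's context are exactly 0 in all
    of that patient's rows (they can carry no flux there).
    """

    feature_ids: list[str]
    X: np.ndarray
    row_patient: list[str]
    row_group: list[str]

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.row_patient:
            seen.setdefault(p)
        return list(seen)

    @property
    def patient_groups(self) -> dict[str, str]:
        return dict(zip(self.row_patient, self.row_group))

    def rows_for(self, patients: set[str]) -> np.ndarray:
        mask = np.array([p in patients for p in self.row_patient])
        return mask


@dataclass
class SplitResult:
    split_id: int
    train_patients: list[str]
    test_patients: list[str]
    accuracy: float
    f1: float
    importances: dict[str, float]
    seed: int


@dataclass
class RankedReaction:
    reaction_id: str
    frequency: int
    mean_importance: float
    rank: int


@dataclass
class AggregatedRanking:
    qualifying_split_ids: list[int]
    entries: list[RankedReaction] = field(default_factory=list)

    def top(self, k: int | None = None) -> list[str]:
        entries = self.entries if k is None else self.entries[:k]
        return [e.reaction_id for e in entries]


class NoQualifyingSplitsError(RuntimeError):
    """No split cleared the F1 threshold; nothing to aggregate."""


def assemble_feature_matrix(sample_sets: list[FluxSampleSet]) -> FeatureTable:
    """Stack per-patient flux samples into one feature table.

    The feature order is the sorted union of retained reactions across
    patients; reactions absent from a patient's context are 0-filled.
    """
    ids = [s.patient_id for s in sample_sets]
    if len(set(ids)) != len(ids):
        dupes = [p for p, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate patient ids: {sorted(dupes)}")
    per_group = Counter(s.group for s in sample_sets)
    if per_group.get("case", 0) < 2 or per_group.get("control", 0) < 2:
        raise ValueError(
            f"need >= 2 patients per group, got {dict(per_group)}"
        )
    feature_ids = sorted(set().union(*(s.reaction_ids for s in sample_sets)))
    col = {r: j for j, r in enumerate(feature_ids)}
    blocks, row_patient, row_group = [], [], []
    for s in sample_sets:
        block = np.zeros((s.n_samples, len(feature_ids)))
        for j_src, rid in enumerate(s.reaction_ids):
            block[:, col[rid]] = s.samples[:, j_src]
        blocks.append(block)
        row_patient.extend([s.patient_id] * s.n_samples)
        row_group.extend([s.group] * s.n_samples)
    return FeatureTable(
        feature_ids=feature_ids,
        X=np.vstack(blocks),
        row_patient=row_patient,
        row_group=row_group,
    )


def undersample_patients(labels: dict[str, str], seed: int) -> list[str]:
    """Balance the groups by randomly dropping majority-group patients.

    All minority-group patients are kept; an equally sized uniform random
    subset of the majority group is kept. Order of the returned list is
    deterministic (sorted within group).
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for pid in sorted(labels):
        groups[labels[pid]].append(pid)
    if not groups.get("case") or not groups.get("control"):
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    n_min = min(len(v) for v in groups.values())
    selected: list[str] = []
    for group in ("case", "control"):
        members = groups[group]
        if len(members) > n_min:
            idx = rng.choice(len(members), size=n_min, replace=False)
            members = [members[i] for i in sorted(idx)]
        selected.extend(members)
    return selected


def split_patients(
    patients: list[str],
    labels: dict[str, str],
    train_frac: float,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Group-stratified patient-level train/test partition.

    floor(train_frac * n) patients per group go to training; at least
    one patient per group must remain on the test side.
    """
    rng = np.random.default_rng(seed)
    train, test = [], []
    for group in ("case", "control"):
        members = [p for p in patients if labels[p] == group]
        if not members:
            raise ValueError(f"group {group!r} has no patients")
        perm = rng.permutation(len(members))
        n_train = int(np.floor(train_frac * len(members)))
        if n_train >= len(members):
            raise ValueError(
                f"train_frac={train_frac} leaves no test patients in group {group!r}"
            )
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


def run_split(
    features: FeatureTable,
    split_id: int,
    seed: int,
    train_frac: float = 0.8,
    rf_params: dict | None = None,
    patients: list[str] | None = None,
) -> SplitResult:
    """One train/evaluate cycle on a patient-level split.

    ``patients`` restricts the split to an (already balanced) subset;
    by default all patients in the table take part. Metrics are row
    level on the held-out patients' flux points.
    """
    labels = features.patient_groups
    pool = patients if patients is not None else features.patients
    train, test = split_patients(pool, labels, train_frac, seed)
    assert not set(train) & set(test), "patient leakage between train and test"
    test_groups = {labels[p] for p in test}
    if test_groups != {"case", "control"}:
        raise ValueError("a group is absent from the test side; re-draw the split")
    train_mask = features.rows_for(set(train))
    test_mask = features.rows_for(set(test))
    y = np.array(features.row_group)
    params = dict(DEFAULT_RF_PARAMS)
    if rf_params:
        params.update(rf_params)
    forest = RandomForestClassifier(random_state=seed, **params)
    forest.fit(features.X[train_mask], y[train_mask])
    pred = forest.predict(features.X[test_mask])
    y_test = y[test_mask]
    accuracy = float(accuracy_score(y_test, pred))
    f1 = float(f1_score(y_test, pred, pos_label="case", zero_division=0.0))
    imp = forest.feature_importances_
    total = imp.sum()
    if total <= 0:  # no split used any feature; fall back to uniform
        imp = np.full_like(imp, 1.0 / len(imp))
    else:
        imp = imp / total
    return SplitResult(
        split_id=split_id,
        train_patients=train,
        test_patients=test,
        accuracy=accuracy,
        f1=f1,
        importances=dict(zip(features.feature_ids, map(float, imp))),
        seed=seed,
    )


def repeated_validation(
    features: FeatureTable,
    n_splits: int = 100,
    master_seed: int = 0,
    train_frac: float = 0.8,
    rf_params: dict | None = None,
) -> list[SplitResult]:
    """n_splits independent under-sample / split / train / evaluate cycles."""
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    labels = features.patient_groups
    results = []
    for i in range(n_splits):
        balanced = undersample_patients(labels, derive_seed(master_seed, TAG_UNDERSAMPLE, i))
        result = run_split(
            features,
            split_id=i,
            seed=derive_seed(master_seed, TAG_SPLIT, i),
            train_frac=train_frac,
            rf_params=rf_params,
            patients=balanced,
        )
        results.append(result)
    return results


def mean_accuracy(results: list[SplitResult]) -> float:
    return float(np.mean([r.accuracy for r in results]))


def aggregate_top_reactions(
    results: list[SplitResult],
    f1_min: float = 0.70,
    k: int = 20,
) -> AggregatedRanking:
    """Consensus ranking over the qualifying splits.

    A split qualifies when its F1 strictly exceeds ``f1_min``; each
    qualifying split contributes its k most important reactions. The
    final order is by descending qualification frequency, then
    descending mean importance (over the splits where the reaction was
    in the top k), then reaction id.
    """
    qualifying = [r for r in results if r.f1 > f1_min]
    if not qualifying:
        raise NoQualifyingSplitsError(
            f"no qualifying splits: no split had F1 > {f1_min}"
        )
    freq: Counter[str] = Counter()
    imp_sums: dict[str, float] = defaultdict(float)
    for res in qualifying:
        order = sorted(res.importances.items(), key=lambda kv: (-kv[1], kv[0]))
        for rid, imp in order[:k]:
            freq[rid] += 1
            imp_sums[rid] += imp
    rows = [
        (rid, count, imp_sums[rid] / count) for rid, count in freq.items()
    ]
    rows.sort(key=lambda row: (-row[1], -row[2], row[0]))
    entries = [
        RankedReaction(reaction_id=rid, frequency=count, mean_importance=mi, rank=i + 1)
        for i, (rid, count, mi) in enumerate(rows)
    ]
    return AggregatedRanking(
        qualifying_split_ids=[r.split_id for r in qualifying],
        entries=entries,
    )
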