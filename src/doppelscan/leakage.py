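"""Dosage experiments quantifying accuracy inflation from doppelganger pairs
that straddle the train/validation split.

The *dosage level* is the number of flagged pairs deliberately split so that
one member trains the model and the other is scored ("Doppel_x"); at level 0
every flagged pair sits entirely inside the training set. Classifiers that
can memorize near-duplicates (KNN most visibly, but also SVM and random
forests) then score inflated validation metrics in a dosage-dependent way.
Binomial random-guessing and exact-duplicate positive controls bracket the
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_model import AbundanceTable, SampleLabels, SamplePair, as_relative

__all__ = [
    "DosageDesign",
    "DosageResult",
    "dosage_split",
    "run_dosage_experiment",
    "negative_control",
    "positive_control",
]

_CLASSIFIERS = ("knn", "svm", "rf")


@dataclass(frozen=True)
class DosageDesign:
    """Configuration of the dosage experiment."""

    dosage_levels: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    validation_fraction: float = 0.3
    n_repeats: int = 50
    classifiers: tuple[str, ...] = _CLASSIFIERS
    knn_k: int = 5
    rf_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if any(l < 0 for l in self.dosage_levels):
            raise ValueError("dosage levels must be >= 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")
        unknown = set(self.classifiers) - set(_CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be positive")


@dataclass(frozen=True)
class DosageResult:
    """Per (classifier, dosage level, repeat) validation metrics plus controls."""

    metrics: pd.DataFrame  # columns: classifier, level, repeat, accuracy, f1, auc
    negative_control: np.ndarray
    positive_control: pd.DataFrame  # columns: classifier, repeat, accuracy

    def mean_metric(self, classifier: str, level: int, metric: str = "accuracy") -> float:
        m = self.metrics
        sel = m[(m.classifier == classifier) & (m.level == level)]
        return float(sel[metric].mean())

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(orient="records"),
            "negative_control": self.negative_control.tolist(),
            "positive_control": self.positive_control.to_dict(orient="records"),
        }


def _derive_seed(seed: int, *parts: int) -> int:
    ss = np.random.SeedSequence([seed, *parts])
    return int(ss.generate_state(1)[0] % (2**31))


def _straddle_candidates(
    pairs: Sequence[SamplePair],
) -> list[tuple[SamplePair, str, str]]:
    """Pairs usable for straddling, as (pair, train_member, val_member).

    A pair can straddle the split only if the member sent to validation sits
    in no *other* flagged pair — otherwise that other pair would straddle
    too and the dosage level would be off. The lexicographically larger
    member goes to validation when possible, the smaller one as a fallback.
    Candidates are additionally vertex-disjoint so levels compose.
    """
    degree: dict[str, int] = {}
    for p in pairs:
        for s in p.ids:
            degree[s] = degree.get(s, 0) + 1
    used: set[str] = set()
    out = []
    for p in pairs:
        if p.id_a in used or p.id_b in used:
            continue
        if degree[p.id_b] == 1:
            out.append((p, p.id_a, p.id_b))
        elif degree[p.id_a] == 1:
            out.append((p, p.id_b, p.id_a))
        else:
            continue
        used.update(p.ids)
    return out


def dosage_split(
    labels: SampleLabels,
    pairs: Sequence[SamplePair],
    level: int,
    design: DosageDesign,
    repeat_index: int = 0,
) -> tuple[list[str], list[str]]:
    """Class-stratified split with exactly ``level`` straddling flagged pairs.

    The chosen straddling pairs send their lexicographically larger member to
    validation; every other flagged pair is kept whole inside the training
    set. Remaining samples fill the stratified validation quota at random.
    Deterministic given (design.seed, level, repeat_index).
    """
    rng = np.random.default_rng(_derive_seed(design.seed, level, repeat_index))
    candidates = _straddle_candidates(pairs)
    if level > len(candidates):
        raise ValueError(
            f"level {level} exceeds {len(candidates)} straddle-capable flagged pairs"
        )
    order = rng.permutation(len(candidates))
    straddle = [candidates[i] for i in order[:level]]

    train: list[str] = []
    val: list[str] = []
    assigned: set[str] = set()
    for p, train_member, val_member in straddle:
        train.append(train_member)
        val.append(val_member)
        assigned.update(p.ids)
    for p in pairs:
        for s in p.ids:
            if s not in assigned:
                train.append(s)
                assigned.add(s)

    all_ids = sorted(labels.labels)
    for cls in labels.classes:
        members = [s for s in all_ids if labels[s] == cls]
        quota = int(round(design.validation_fraction * len(members)))
        quota = min(max(quota, 1), len(members) - 1)
        in_val = sum(1 for s in val if labels[s] == cls)
        free = [s for s in members if s not in assigned]
        need = quota - in_val
        if need < 0 or need > len(free):
            raise ValueError(
                f"infeasible split for class {cls!r}: quota {quota}, "
                f"{in_val} forced into validation, {len(free)} free samples"
            )
        rng.shuffle(free)
        val.extend(free[:need])
        train.extend(free[need:])

    train_lab = {labels[s] for s in train}
    val_lab = {labels[s] for s in val}
    if len(train_lab) < 2 or len(val_lab) < 2:
        raise ValueError("split leaves a side without both classes")
    return sorted(train), sorted(val)


def _make_classifier(name: str, design: DosageDesign, rng_seed: int):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=design.knn_k, metric="euclidean"), True
    if name == "svm":
        return SVC(kernel="rbf", random_state=rng_seed), True
    if name == "rf":
        return (
            RandomForestClassifier(n_estimators=design.rf_trees, random_state=rng_seed),
            False,  # scale-invariant: no standardization
        )
    raise ValueError(f"unknown classifier {name!r}")


def _fit_score(
    clf_name: str,
    design: DosageDesign,
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xva: np.ndarray,
    yva: np.ndarray,
    seed: int,
) -> tuple[float, float, float]:
    """Fit one classifier and return (accuracy, F1, AUC) on validation.

    Positive class for F1/AUC is 1 in the 0/1-encoded label vectors. KNN and
    SVM see train-standardized features; RF sees raw proportions.
    """
    clf, scale = _make_classifier(clf_name, design, seed)
    if scale:
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xva = scaler.transform(Xtr), scaler.transform(Xva)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xva)
    acc = accuracy_score(yva, pred)
    f1 = f1_score(yva, pred, pos_label=1, zero_division=0)
    if clf_name == "svm":
        scores = clf.decision_function(Xva)
    else:  # vote fraction / class probability of the positive class
        scores = clf.predict_proba(Xva)[:, list(clf.classes_).index(1)]
    if len(set(yva)) < 2:
        auc = np.nan
    else:
        auc = roc_auc_score(yva, scores)
    return float(acc), float(f1), float(auc)


def _encode(
    table: AbundanceTable, labels: SampleLabels, ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    rel = as_relative(table)
    idx = [rel.sample_index(s) for s in ids]
    X = rel.values[idx]
    y = np.array([1 if labels[s] == labels.case_label else 0 for s in ids])
    return X, y


def run_dosage_experiment(
    table: AbundanceTable,
    labels: SampleLabels,
    pairs: Sequence[SamplePair],
    design: DosageDesign = DosageDesign(),
) -> DosageResult:
    """Run the full dosage design: levels x classifiers x repeats."""
    max_level = max(design.dosage_levels, default=0)
    if max_level > len(_straddle_candidates(pairs)):
        raise ValueError("max dosage level exceeds available flagged pairs")
    records = []
    for level in design.dosage_levels:
        for rep in range(design.n_repeats):
            train_ids, val_ids = dosage_split(labels, pairs, level, design, rep)
            Xtr, ytr = _encode(table, labels, train_ids)
            Xva, yva = _encode(table, labels, val_ids)
            if len(set(ytr)) < 2:
                raise ValueError("single-class training fold")
            for name in design.classifiers:
                acc, f1, auc = _fit_score(
                    name, design, Xtr, ytr, Xva, yva,
                    _derive_seed(design.seed, level, rep, _CLASSIFIERS.index(name)),
                )
                records.append(
                    {
                        "classifier": name,
                        "level": level,
                        "repeat": rep,
                        "accuracy": acc,
                        "f1": f1,
                        "auc": auc,
                    }
                )
    metrics = pd.DataFrame.from_records(records)

    n_val = max(1, int(round(design.validation_fraction * table.n_samples)))
    neg = negative_control(
        n_validation=n_val,
        p_correct=0.5,
        n_repeats=design.n_repeats,
        seed=_derive_seed(design.seed, 7001),
    )
    pos = positive_control(table, labels, design)
    return DosageResult(metrics=metrics, negative_control=neg, positive_control=pos)


def negative_control(
    n_validation: int, p_correct: float, n_repeats: int, seed: int
) -> np.ndarray:
    """Random-guessing accuracy distribution: Binomial(N, P)/N draws."""
    if n_validation < 1 or n_repeats < 1:
        raise ValueError("n_validation and n_repeats must be positive")
    if not 0 <= p_correct <= 1:
        raise ValueError("p_correct must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.binomial(n_validation, p_correct, size=n_repeats) / n_validation


def positive_control(
    table: AbundanceTable,
    labels: SampleLabels,
    design: DosageDesign = DosageDesign(),
) -> pd.DataFrame:
    """Score classifiers on a validation set of exact training duplicates.

    The validation set duplicates randomly chosen training samples (labels
    included), the memorization ceiling of the dosage experiment.
    """
    all_ids = sorted(labels.labels)
    n_val_nominal = max(1, int(round(design.validation_fraction * len(all_ids))))
    records = []
    for rep in range(design.n_repeats):
        rng = np.random.default_rng(_derive_seed(design.seed, 7002, rep))
        train_ids = list(all_ids)
        n_dup = min(len(train_ids), n_val_nominal)
        dup_ids = list(rng.choice(train_ids, size=n_dup, replace=False))
        Xtr, ytr = _encode(table, labels, train_ids)
        Xva, yva = _encode(table, labels, dup_ids)
        for name in design.classifiers:
            acc, f1, auc = _fit_score(
                name, design, Xtr, ytr, Xva, yva,
                _derive_seed(design.seed, 7003, rep, _CLASSIFIERS.index(name)),
            )
            records.append({"classifier": name, "repeat": rep, "accuracy": acc})
    return pd.DataFrame.from_records(records)
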