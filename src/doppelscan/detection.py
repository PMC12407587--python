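"""Doppelganger-pair detection via the maximum between-class correlation cutoff.

Two samples form a *doppelganger pair* when they belong to the same class
(case-case or control-control) and their pairwise correlation exceeds the
largest correlation observed between any case and control sample. Because the
cutoff is the between-class maximum, no between-class pair can ever be
flagged: the procedure has perfect specificity by construction, and flags
only within-class similarities too extreme to arise across disease states.

The module exposes both plain functions and a scikit-learn style estimator
(:class:`DoppelgangerDetector`) whose ``transform`` removes flagged samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._stats import rank_sum_test
from .data_model import AbundanceTable, SampleLabels, SamplePair, as_relative

__all__ = [
    "CutoffValidation",
    "DoppelResult",
    "DoppelgangerDetector",
    "pairwise_correlation",
    "derive_cutoff",
    "identify_doppelgangers",
    "validate_cutoff",
    "remove_doppelgangers",
    "detect",
]

_HIST_BINS = 30


@dataclass(frozen=True)
class CutoffValidation:
    """Wilcoxon rank-sum comparison of between- vs within-class correlations.

    A clear separation (within-class values stochastically larger, with the
    between-class distribution terminating below the highest within-class
    values) is the empirical justification for the maximum-cutoff rule.
    """

    statistic: float
    pvalue: float
    bin_edges: np.ndarray
    between_counts: np.ndarray
    within_counts: np.ndarray
    n_between: int
    n_within: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "bin_edges": self.bin_edges.tolist(),
            "between_counts": self.between_counts.tolist(),
            "within_counts": self.within_counts.tolist(),
            "n_between": self.n_between,
            "n_within": self.n_within,
        }


@dataclass(frozen=True)
class DoppelResult:
    """Full output of a doppelganger detection run."""

    correlation: pd.DataFrame  # samples x samples, symmetric, unit diagonal
    method: str
    cutoff: float
    pairs: tuple[SamplePair, ...]  # flagged within-class pairs, r > cutoff
    validation: CutoffValidation | None = None

    @property
    def flagged_ids(self) -> set[str]:
        """Samples participating in at least one flagged pair."""
        out: set[str] = set()
        for p in self.pairs:
            out.update(p.ids)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "correlation": p.correlation,
                "pair_class": p.pair_class,
                "flagged": True,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(
            rows, columns=["id_a", "id_b", "correlation", "pair_class", "flagged"]
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "cutoff": self.cutoff,
            "n_pairs": len(self.pairs),
            "pairs": [
                {
                    "id_a": p.id_a,
                    "id_b": p.id_b,
                    "correlation": p.correlation,
                    "pair_class": p.pair_class,
                }
                for p in self.pairs
            ],
            "validation": self.validation.to_dict() if self.validation else None,
        }


def _transform_values(table: AbundanceTable, transform: str) -> np.ndarray:
    if transform == "relative":
        return as_relative(table).values
    if transform == "raw":
        return table.values
    if transform == "log1p":
        return np.log1p(table.values)
    raise ValueError(f"unknown transform {transform!r}")


def pairwise_correlation(
    table: AbundanceTable, method: str = "pearson", transform: str = "relative"
) -> pd.DataFrame:
    """Sample-by-sample correlation matrix across features.

    ``transform`` selects the representation correlated: per-sample
    proportions (default, removes library-size artifacts), raw values, or
    log1p counts. The choice matters: flagged-pair counts depend on it.
    """
    if table.n_samples < 2 or table.n_features < 2:
        raise ValueError("need at least 2 samples and 2 features")
    X = _transform_values(table, transform)
    constant = np.flatnonzero(X.std(axis=1) == 0)
    if constant.size:
        names = [table.sample_ids[i] for i in constant]
        raise ValueError(
            f"constant sample vectors (correlation undefined): {names}"
        )
    if method == "pearson":
        corr = np.corrcoef(X)
    elif method == "spearman":
        ranks = stats.rankdata(X, axis=1)
        corr = np.corrcoef(ranks)
    elif method == "kendall":
        n = table.n_samples
        corr = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                tau = stats.kendalltau(X[i], X[j]).statistic
                corr[i, j] = corr[j, i] = tau
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    ids = list(table.sample_ids)
    return pd.DataFrame(corr, index=ids, columns=ids)


def _split_pair_values(
    corr: pd.DataFrame, labels: SampleLabels
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle correlation values split into between/within groups."""
    ids = list(corr.index)
    lab = labels.label_array(ids)
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(len(ids), k=1)
    vals = corr.to_numpy()[iu]
    within_mask = same[iu]
    return vals[~within_mask], vals[within_mask]


def derive_cutoff(corr: pd.DataFrame, labels: SampleLabels) -> float:
    """Maximum correlation over all between-class (case-control) pairs."""
    between, _ = _split_pair_values(corr, labels)
    if between.size == 0:
        raise ValueError("no between-class pairs: both classes must be non-empty")
    return float(between.max())


def identify_doppelgangers(
    corr: pd.DataFrame, labels: SampleLabels, cutoff: float
) -> list[SamplePair]:
    """Within-class pairs with correlation strictly above the cutoff.

    Returned sorted by descending correlation, then lexicographic ids; ties
    at the cutoff are not flagged.
    """
    if not -1.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [-1, 1]")
    ids = list(corr.index)
    lab = labels.label_array(ids)
    C = corr.to_numpy()
    case = labels.case_label
    pairs: list[SamplePair] = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if lab[i] != lab[j] or C[i, j] <= cutoff:
                continue
            pair_class = "within_case" if lab[i] == case else "within_control"
            pairs.append(SamplePair.make(ids[i], ids[j], C[i, j], pair_class))
    pairs.sort(key=lambda p: (-p.correlation, p.id_a, p.id_b))
    return pairs


def validate_cutoff(corr: pd.DataFrame, labels: SampleLabels) -> CutoffValidation:
    """Test that within-class correlations differ from between-class ones.

    Two-sided Wilcoxon rank-sum on the two groups of pairwise correlation
    values, plus a shared-bin histogram of both distributions.
    """
    between, within = _split_pair_values(corr, labels)
    if between.size < 2 or within.size < 2:
        raise ValueError("need at least 2 pairs in each group")
    statistic, pvalue = rank_sum_test(between, within)
    pooled = np.concatenate([between, within])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:  # degenerate all-equal case
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, _HIST_BINS + 1)
    b_counts, _ = np.histogram(between, bins=edges)
    w_counts, _ = np.histogram(within, bins=edges)
    return CutoffValidation(
        statistic=statistic,
        pvalue=pvalue,
        bin_edges=edges,
        between_counts=b_counts,
        within_counts=w_counts,
        n_between=int(between.size),
        n_within=int(within.size),
    )


def remove_doppelgangers(
    table: AbundanceTable,
    pairs: Sequence[SamplePair],
    policy: str = "greedy_degree",
) -> tuple[AbundanceTable, list[str]]:
    """Drop samples until no flagged pair survives intact.

    ``greedy_degree`` iteratively removes the sample incident to the most
    unresolved pairs (a greedy vertex cover, keeping as many samples as
    possible on pair chains); ties break toward smaller library size, then
    lexicographic id. ``second_member`` simply drops ``id_b`` of every pair.
    """
    known = set(table.sample_ids)
    for p in pairs:
        missing = set(p.ids) - known
        if missing:
            raise KeyError(f"pair ids not in table: {sorted(missing)}")
    if policy == "second_member":
        removed = sorted({p.id_b for p in pairs})
    elif policy == "greedy_degree":
        libsize = dict(zip(table.sample_ids, table.library_sizes()))
        live = [set(p.ids) for p in pairs]
        removed = []
        while live:
            degree: dict[str, int] = {}
            for e in live:
                for s in e:
                    degree[s] = degree.get(s, 0) + 1
            victim = min(degree, key=lambda s: (-degree[s], libsize[s], s))
            removed.append(victim)
            live = [e for e in live if victim not in e]
        removed.sort()
    else:
        raise ValueError(f"unknown removal policy {policy!r}")
    return table.drop_samples(removed), removed


def detect(
    table: AbundanceTable,
    labels: SampleLabels,
    method: str = "pearson",
    transform: str = "relative",
    cutoff: float | None = None,
    validate: bool = True,
) -> DoppelResult:
    """Run the full detection procedure on an abundance table."""
    corr = pairwise_correlation(table, method=method, transform=transform)
    if cutoff is None:
        cutoff = derive_cutoff(corr, labels)
    pairs = identify_doppelgangers(corr, labels, cutoff)
    validation = None
    if validate:
        try:
            validation = validate_cutoff(corr, labels)
        except ValueError:
            validation = None  # too few pairs per group on tiny inputs
    return DoppelResult(
        correlation=corr,
        method=method,
        cutoff=float(cutoff),
        pairs=tuple(pairs),
        validation=validation,
    )


class DoppelgangerDetector(BaseEstimator):
    """Scikit-learn style doppelganger QC transformer.

    ``fit(X, y)`` computes the sample correlation matrix, derives the maximum
    between-class cutoff and flags within-class pairs above it; ``transform``
    removes the flagged samples under the configured removal policy (note the
    number of rows shrinks — this is a sample-level QC step, not a feature
    transformer).

    Parameters
    ----------
    method : {"pearson", "spearman", "kendall"}
        Correlation coefficient between sample abundance vectors.
    transform_mode : {"relative", "raw", "log1p"}
        Representation correlated; proportions by default.
    cutoff : float or None
        Override for the data-derived between-class maximum.
    policy : {"greedy_degree", "second_member"}
        Which member(s) of flagged pairs to remove.

    Attributes
    ----------
    correlation_ : pandas.DataFrame
        Symmetric sample-by-sample correlation matrix.
    cutoff_ : float
    pairs_ : tuple of SamplePair
        Flagged within-class pairs, descending correlation.
    validation_ : CutoffValidation or None
    result_ : DoppelResult
    """

    def __init__(
        self,
        method: str = "pearson",
        transform_mode: str = "relative",
        cutoff: float | None = None,
        policy: str = "greedy_degree",
        validate: bool = True,
    ):
        self.method = method
        self.transform_mode = transform_mode
        self.cutoff = cutoff
        self.policy = policy
        self.validate = validate

    def _as_table(self, X) -> AbundanceTable:
        if isinstance(X, AbundanceTable):
            return X
        if isinstance(X, pd.DataFrame):
            return AbundanceTable(
                tuple(map(str, X.index)),
                tuple(map(str, X.columns)),
                X.to_numpy(dtype=float),
            )
        X = np.asarray(X, dtype=float)
        return AbundanceTable(
            tuple(f"S{i}" for i in range(X.shape[0])),
            tuple(f"F{j}" for j in range(X.shape[1])),
            X,
        )

    def _as_labels(self, table: AbundanceTable, y) -> SampleLabels:
        if isinstance(y, SampleLabels):
            return y
        y = np.asarray(y)
        if y.shape[0] != table.n_samples:
            raise ValueError("y length does not match number of samples")
        return SampleLabels({s: str(v) for s, v in zip(table.sample_ids, y)})

    def fit(self, X, y):
        table = self._as_table(X)
        labels = self._as_labels(table, y)
        result = detect(
            table,
            labels,
            method=self.method,
            transform=self.transform_mode,
            cutoff=self.cutoff,
            validate=self.validate,
        )
        self.table_ = table
        self.labels_ = labels
        self.result_ = result
        self.correlation_ = result.correlation
        self.cutoff_ = result.cutoff
        self.pairs_ = result.pairs
        self.validation_ = result.validation
        return self

    def transform(self, X=None):
        """Return the fitted table with flagged samples removed."""
        if not hasattr(self, "result_"):
            raise RuntimeError("DoppelgangerDetector is not fitted")
        table = self.table_ if X is None else self._as_table(X)
        cleaned, removed = remove_doppelgangers(table, self.pairs_, policy=self.policy)
        self.removed_ids_ = removed
        return cleaned

    def fit_transform(self, X, y):
        return self.fit(X, y).transform()
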