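"""Per-feature association testing and bootstrap effect-size stability.

Redundant near-duplicate samples shrink within-class variability, which
inflates rank-test significance and destabilizes resampled effect-size
estimates. This module measures both: per-OTU Wilcoxon rank-sum tests before
and after doppelganger removal, and the across-bootstrap variance of
per-taxon log-fold changes (LFC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import rank_sum_test
from .data_model import AbundanceTable, SampleLabels, as_relative

__all__ = [
    "AssociationResult",
    "PvalueShift",
    "per_feature_wilcoxon",
    "compare_pvalues",
    "bootstrap_lfc_variance",
    "variance_reduction",
]

DEFAULT_PSEUDOCOUNT = 1e-6


@dataclass(frozen=True)
class AssociationResult:
    """Per-feature two-sided Wilcoxon rank-sum p-values (case vs control)."""

    feature_ids: tuple[str, ...]
    pvalues: np.ndarray
    qvalues: np.ndarray | None = None  # Benjamini-Hochberg, optional

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature_id": self.feature_ids, "pvalue": self.pvalues})
        if self.qvalues is not None:
            df["qvalue"] = self.qvalues
        return df

    def to_dict(self) -> dict:
        return self.to_frame().to_dict(orient="records")


@dataclass(frozen=True)
class PvalueShift:
    """Per-feature p-value movement after sample removal."""

    feature_ids: tuple[str, ...]
    p_before: np.ndarray
    p_after: np.ndarray
    n_higher: int
    n_lower: int
    n_tied: int

    def to_dict(self) -> dict:
        return {
            "n_higher": self.n_higher,
            "n_lower": self.n_lower,
            "n_tied": self.n_tied,
            "features": [
                {"feature_id": f, "p_before": float(b), "p_after": float(a)}
                for f, b, a in zip(self.feature_ids, self.p_before, self.p_after)
            ],
        }


def per_feature_wilcoxon(
    table: AbundanceTable, labels: SampleLabels, adjust: bool = False
) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum per feature on relative abundances.

    Exact enumeration when both class sizes are <= 12 (tie-free features);
    tie-corrected normal approximation otherwise. BH adjustment is optional
    and off by default.
    """
    rel = as_relative(table)
    lab = labels.label_array(rel.sample_ids)
    case_mask = lab == labels.case_label
    n_case, n_ctrl = int(case_mask.sum()), int((~case_mask).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 samples per class")
    Xc = rel.values[case_mask]
    Xk = rel.values[~case_mask]

    constant = np.ptp(rel.values, axis=0) == 0  # no rank separation possible
    if max(n_case, n_ctrl) <= 12:
        pvals = np.array(
            [
                1.0 if constant[j] else rank_sum_test(Xc[:, j], Xk[:, j])[1]
                for j in range(rel.n_features)
            ]
        )
    else:
        # vectorized asymptotic test across features
        res = stats.mannwhitneyu(
            Xc, Xk, alternative="two-sided", method="asymptotic", axis=0
        )
        pvals = np.asarray(res.pvalue, dtype=float)
        pvals[constant] = 1.0
    qvals = multipletests(pvals, method="fdr_bh")[1] if adjust else None
    return AssociationResult(rel.feature_ids, pvals, qvals)


def compare_pvalues(before: AssociationResult, after: AssociationResult) -> PvalueShift:
    """Count features whose p-value rose, fell, or tied after removal."""
    if before.feature_ids != after.feature_ids:
        raise ValueError("feature sets differ between the two results")
    higher = after.pvalues > before.pvalues
    lower = after.pvalues < before.pvalues
    return PvalueShift(
        feature_ids=before.feature_ids,
        p_before=before.pvalues,
        p_after=after.pvalues,
        n_higher=int(higher.sum()),
        n_lower=int(lower.sum()),
        n_tied=int((~higher & ~lower).sum()),
    )


def bootstrap_lfc_variance(
    table: AbundanceTable,
    labels: SampleLabels,
    n_boot: int = 100,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
) -> pd.Series:
    """Across-bootstrap variance of per-feature log2 fold changes.

    Each bootstrap resamples samples with replacement *within class*,
    preserving class sizes, then computes per feature
    ``log2((mean case rel. abundance + pc) / (mean control rel. abundance + pc))``.
    Returns the per-feature variance over the ``n_boot`` replicates.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    rel = as_relative(table)
    lab = labels.label_array(rel.sample_ids)
    case_idx = np.flatnonzero(lab == labels.case_label)
    ctrl_idx = np.flatnonzero(lab != labels.case_label)
    if case_idx.size < 2 or ctrl_idx.size < 2:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(seed)
    lfc = np.empty((n_boot, rel.n_features))
    for b in range(n_boot):
        ci = rng.choice(case_idx, size=case_idx.size, replace=True)
        ki = rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True)
        mc = rel.values[ci].mean(axis=0)
        mk = rel.values[ki].mean(axis=0)
        lfc[b] = np.log2((mc + pseudocount) / (mk + pseudocount))
    return pd.Series(lfc.var(axis=0, ddof=1), index=list(rel.feature_ids))


def variance_reduction(with_doppel: pd.Series, without_doppel: pd.Series) -> float:
    """Mean percent reduction in bootstrap LFC variance after removal.

    ``100 * mean over features with var_with > 0 of
    (var_with - var_without) / var_with``; features with zero baseline
    variance are excluded to avoid division by zero.
    """
    if not with_doppel.index.equals(without_doppel.index):
        raise ValueError("feature sets differ between variance vectors")
    vw = with_doppel.to_numpy(dtype=float)
    vo = without_doppel.to_numpy(dtype=float)
    eligible = vw > 0
    if not eligible.any():
        raise ValueError("no feature with positive baseline variance")
    return float(100.0 * np.mean((vw[eligible] - vo[eligible]) / vw[eligible]))
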