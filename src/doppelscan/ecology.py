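"""Alpha/beta diversity of doppelganger vs non-doppelganger samples.

Doppelganger members tend to show reduced richness and evenness and a
distinct species composition; this module computes the descriptive metrics
(observed richness, Shannon index, Pielou evenness, Bray-Curtis
dissimilarity) and a PERMANOVA group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import AbundanceTable, SamplePair, as_relative

__all__ = [
    "DiversityReport",
    "PermanovaResult",
    "alpha_diversity",
    "bray_curtis",
    "permanova",
    "doppelganger_groups",
]


@dataclass(frozen=True)
class PermanovaResult:
    """Pseudo-F and permutation p-value of a one-way PERMANOVA."""

    pseudo_f: float
    pvalue: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "pseudo_f": self.pseudo_f,
            "pvalue": self.pvalue,
            "n_permutations": self.n_permutations,
        }


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample observed richness, Shannon index (natural log), and
    Pielou evenness (H / ln richness; NaN when richness < 2)."""
    rel = as_relative(table)
    richness = (table.values > 0).sum(axis=1)
    H = np.zeros(table.n_samples)
    for i in range(table.n_samples):
        p = rel.values[i]
        p = p[p > 0]
        H[i] = -np.sum(p * np.log(p))
    with np.errstate(divide="ignore", invalid="ignore"):
        evenness = np.where(richness >= 2, H / np.log(np.maximum(richness, 2)), np.nan)
    return pd.DataFrame(
        {
            "richness": richness.astype(int),
            "shannon": H,
            "evenness": evenness,
        },
        index=list(table.sample_ids),
    )


def doppelganger_groups(
    table: AbundanceTable, pairs: Sequence[SamplePair]
) -> pd.Series:
    """Label each sample ``doppelganger`` if it is in >= 1 flagged pair."""
    members: set[str] = set()
    for p in pairs:
        members.update(p.ids)
    return pd.Series(
        ["doppelganger" if s in members else "non_doppelganger" for s in table.sample_ids],
        index=list(table.sample_ids),
        name="group",
    )


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity on relative abundances."""
    rel = as_relative(table)
    D = squareform(pdist(rel.values, metric="braycurtis"))
    ids = list(table.sample_ids)
    return pd.DataFrame(D, index=ids, columns=ids)


def _pseudo_f(D2: np.ndarray, groups: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from squared dissimilarities."""
    n = D2.shape[0]
    uniq = np.unique(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = D2[iu].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        if idx.size >= 2:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    k = uniq.size
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Pseudo-F follows the standard partition of the sum of squared
    dissimilarities into among- and within-group components;
    ``p = (1 + #{permuted F >= observed F}) / (1 + n_permutations)`` over
    seeded whole-label permutations.
    """
    D = dist.to_numpy() if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    groups = np.asarray(groups)
    if D.shape[0] != D.shape[1] or D.shape[0] != groups.size:
        raise ValueError("dissimilarity matrix and grouping sizes disagree")
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    D2 = D**2
    f_obs = _pseudo_f(D2, groups)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        if _pseudo_f(D2, perm) >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), int(n_permutations))
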