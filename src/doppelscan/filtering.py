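"""OTU filtering families and robustness sweeps of doppelganger detection.

Three standard feature filters — total counts, prevalence, and maximum
relative abundance — are applied at a grid of thresholds, with detection
re-run from scratch after each, to check that the flagged-pair set is stable
under preprocessing choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AbundanceTable, SampleLabels, as_relative
from .detection import detect

__all__ = ["FilterSpec", "SweepRow", "apply_filter", "robustness_sweep"]


@dataclass(frozen=True)
class FilterSpec:
    """One feature filter.

    kind
        ``total_counts`` keeps features with total count across samples
        strictly above ``threshold``; ``prevalence`` keeps features present
        (count > 0) in at least ``threshold`` fraction of samples;
        ``relative_abundance`` keeps features whose maximum per-sample
        proportion is >= threshold (``keep_above``, default) or
        <= threshold (``keep_below``).
    """

    kind: str
    threshold: float
    direction: str = "keep_above"

    def __post_init__(self) -> None:
        if self.kind not in ("total_counts", "prevalence", "relative_abundance"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.kind == "prevalence" and not 0 <= self.threshold <= 1:
            raise ValueError("prevalence threshold must be in [0, 1]")
        if self.direction not in ("keep_above", "keep_below"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def describe(self) -> str:
        if self.kind == "total_counts":
            return f"total counts > {self.threshold:g}"
        if self.kind == "prevalence":
            return f"present in >= {100 * self.threshold:g}% of samples"
        op = ">=" if self.direction == "keep_above" else "<="
        return f"max relative abundance {op} {self.threshold:g}"


@dataclass(frozen=True)
class SweepRow:
    """One row of a Table-1-style robustness sweep."""

    description: str
    n_features_kept: int
    n_pairs_found: int
    same_pairs_as_unfiltered: bool

    def to_dict(self) -> dict:
        return {
            "filter": self.description,
            "n_features_kept": self.n_features_kept,
            "n_pairs_found": self.n_pairs_found,
            "same_pairs_as_unfiltered": self.same_pairs_as_unfiltered,
        }


def apply_filter(table: AbundanceTable, spec: FilterSpec) -> AbundanceTable:
    """Drop feature columns failing the filter predicate; samples untouched."""
    if spec.kind in ("total_counts", "prevalence") and table.mode != "counts":
        raise ValueError(f"{spec.kind} filter requires a counts-mode table")
    if spec.kind == "total_counts":
        keep = table.values.sum(axis=0) > spec.threshold
    elif spec.kind == "prevalence":
        prevalence = (table.values > 0).mean(axis=0)
        keep = prevalence >= spec.threshold
    else:
        max_prop = as_relative(table).values.max(axis=0)
        if spec.direction == "keep_above":
            keep = max_prop >= spec.threshold
        else:
            keep = max_prop <= spec.threshold
    if not keep.any():
        raise ValueError(f"filter {spec.describe()!r} removes every feature")
    kept = [f for f, k in zip(table.feature_ids, keep) if k]
    return table.select_features(kept)


def robustness_sweep(
    table: AbundanceTable,
    labels: SampleLabels,
    specs: Sequence[FilterSpec],
    method: str = "pearson",
    transform: str = "relative",
) -> list[SweepRow]:
    """Re-run full detection after each filter and compare the pair sets.

    The correlation cutoff is re-derived on each filtered table (never reused
    from the unfiltered run).
    """
    base = detect(table, labels, method=method, transform=transform, validate=False)
    base_ids = {p.ids for p in base.pairs}
    rows = []
    for spec in specs:
        filtered = apply_filter(table, spec)
        res = detect(filtered, labels, method=method, transform=transform, validate=False)
        ids = {p.ids for p in res.pairs}
        rows.append(
            SweepRow(
                description=spec.describe(),
                n_features_kept=filtered.n_features,
                n_pairs_found=len(res.pairs),
                same_pairs_as_unfiltered=ids == base_ids,
            )
        )
    return rows


def sweep_frame(rows: Sequence[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])
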