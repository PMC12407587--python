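"""Core data structures for microbiome abundance matrices and sample metadata.

The canonical in-memory layout is samples x features, regardless of how the
table is stored on disk (many public microbiome tables are feature-major).
Absences are explicit zeros; there is no missing-value sentinel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleLabels",
    "SamplePair",
    "read_abundance_table",
    "read_labels",
    "write_abundance_table",
    "write_result",
    "to_relative",
]

#: row sums within this tolerance of 1 are treated as already-normalized
_RELATIVE_SUM_TOL = 1e-6


@dataclass(frozen=True)
class AbundanceTable:
    """A samples x features abundance matrix.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, one per row.
    feature_ids : sequence of str
        Unique feature (OTU/taxon/gene) identifiers, one per column.
    values : ndarray of shape (n_samples, n_features)
        Non-negative abundances. In ``relative`` mode every row sums to 1.
    mode : {"counts", "relative"}
    """

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    mode: str = "counts"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        if values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {values.shape} does not match {len(self.sample_ids)} samples "
                f"x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature identifiers")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite entries in abundance matrix")
        if np.any(values < 0):
            raise ValueError("negative entries in abundance matrix")
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                names = [self.sample_ids[i] for i in bad[:5]]
                raise ValueError(
                    f"relative-mode rows must sum to 1; offending samples: {names}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def select_samples(self, keep: Sequence[str]) -> "AbundanceTable":
        """Subset (and reorder) samples by identifier."""
        idx = [self.sample_index(s) for s in keep]
        return AbundanceTable(
            tuple(keep), self.feature_ids, self.values[idx], self.mode
        )

    def drop_samples(self, drop: Iterable[str]) -> "AbundanceTable":
        dropset = set(drop)
        unknown = dropset - set(self.sample_ids)
        if unknown:
            raise KeyError(f"unknown sample ids: {sorted(unknown)}")
        keep = [s for s in self.sample_ids if s not in dropset]
        return self.select_samples(keep)

    def select_features(self, keep: Sequence[str]) -> "AbundanceTable":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        try:
            idx = [pos[f] for f in keep]
        except KeyError as exc:
            raise KeyError(f"unknown feature id {exc.args[0]!r}") from None
        return AbundanceTable(self.sample_ids, tuple(keep), self.values[:, idx], self.mode)

    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and self.mode == other.mode
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )


@dataclass(frozen=True)
class SampleLabels:
    """Binary class labels (e.g., case/control) keyed by sample id."""

    labels: Mapping[str, str]
    case_label: str | None = None

    def __post_init__(self) -> None:
        labels = dict(self.labels)
        object.__setattr__(self, "labels", labels)
        classes = sorted(set(labels.values()))
        if len(classes) != 2:
            raise ValueError(f"exactly two classes required, got {classes}")
        case = self.case_label
        if case is None:
            # conventional metadata naming wins; otherwise first in sort order
            case = "case" if "case" in classes else classes[0]
            object.__setattr__(self, "case_label", case)
        elif case not in classes:
            raise ValueError(f"case_label {case!r} not among classes {classes}")

    @property
    def classes(self) -> tuple[str, str]:
        return tuple(sorted(set(self.labels.values())))  # type: ignore[return-value]

    @property
    def control_label(self) -> str:
        a, b = self.classes
        return b if self.case_label == a else a

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def label_array(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        return np.array([self.labels[s] for s in sample_ids])

    def members(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]

    def subset(self, sample_ids: Iterable[str]) -> "SampleLabels":
        sub = {s: self.labels[s] for s in sample_ids}
        return SampleLabels(sub, case_label=self.case_label)


@dataclass(frozen=True, order=True)
class SamplePair:
    """A canonically oriented (id_a < id_b) unordered sample pair."""

    id_a: str
    id_b: str
    correlation: float
    pair_class: str  # within_case | within_control | between

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError(
                f"pair must be canonically ordered id_a < id_b, got ({self.id_a!r}, {self.id_b!r})"
            )
        if not -1.0 - 1e-12 <= self.correlation <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.correlation} outside [-1, 1]")
        if self.pair_class not in ("within_case", "within_control", "between"):
            raise ValueError(f"unknown pair_class {self.pair_class!r}")

    @staticmethod
    def make(a: str, b: str, correlation: float, pair_class: str) -> "SamplePair":
        if a > b:
            a, b = b, a
        return SamplePair(a, b, float(correlation), pair_class)

    @property
    def ids(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


def read_abundance_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    delimiter: str = "\t",
) -> AbundanceTable:
    """Read a delimited abundance table into canonical samples x features layout.

    ``orientation`` states how the *file* is laid out; feature-major files
    (the common public-repository convention) are transposed on read. Mode is
    inferred: relative iff every sample row sums to 1 within 1e-6.
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate identifiers in header of {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "features_as_rows":
        df = df.T
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate identifiers in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i, row in enumerate(df.itertuples(index=False)):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at sample {df.index[i]!r}, "
                        f"feature {df.columns[j]!r}: {v!r}"
                    ) from None
        raise
    sums = values.sum(axis=1)
    relative = bool(np.all(np.abs(sums - 1.0) <= _RELATIVE_SUM_TOL))
    return AbundanceTable(
        tuple(map(str, df.index)),
        tuple(map(str, df.columns)),
        values,
        "relative" if relative else "counts",
    )


def write_abundance_table(
    table: AbundanceTable,
    path: str | Path,
    orientation: str = "samples_as_rows",
    delimiter: str = "\t",
) -> None:
    df = table.to_dataframe()
    if orientation == "features_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=delimiter, float_format="%.12g")


def read_labels(
    path: str | Path, delimiter: str = "\t", case_label: str | None = None
) -> SampleLabels:
    """Read sample metadata with columns ``sample_id`` and ``label``."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValueError(f"metadata {path} lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in metadata {path}")
    return SampleLabels(dict(zip(df["sample_id"], df["label"])), case_label=case_label)


def write_labels(labels: SampleLabels, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(
        {"sample_id": list(labels.labels), "label": list(labels.labels.values())}
    )
    df.to_csv(path, sep=delimiter, index=False)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Normalize raw counts to per-sample proportions."""
    if table.mode != "counts":
        raise ValueError("to_relative expects a counts-mode table")
    sums = table.values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        names = [table.sample_ids[i] for i in zero]
        raise ValueError(f"samples with zero library size: {names}")
    return AbundanceTable(
        table.sample_ids, table.feature_ids, table.values / sums[:, None], "relative"
    )


def as_relative(table: AbundanceTable) -> AbundanceTable:
    """Return the table in relative mode, normalizing if needed."""
    return table if table.mode == "relative" else to_relative(table)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def pairs_to_dataframe(pairs: Sequence[SamplePair], flagged: set | None = None) -> pd.DataFrame:
    rows = [
        {
            "id_a": p.id_a,
            "id_b": p.id_b,
            "correlation": p.correlation,
            "pair_class": p.pair_class,
            "flagged": bool(flagged is None or (p.id_a, p.id_b) in flagged),
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["id_a", "id_b", "correlation", "pair_class", "flagged"])


def write_result(result, path: str | Path, format: str = "json") -> None:
    """Serialize a result artifact to TSV (tabular views) or JSON (lossless)."""
    path = Path(path)
    if format == "json":
        payload = _jsonify(result.to_dict() if hasattr(result, "to_dict") else result)
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    elif format == "tsv":
        if isinstance(result, pd.DataFrame):
            df = result
        elif hasattr(result, "to_frame"):
            df = result.to_frame()
        elif isinstance(result, (list, tuple)) and all(
            isinstance(p, SamplePair) for p in result
        ):
            df = pairs_to_dataframe(result)
        else:
            raise TypeError(f"cannot render {type(result).__name__} as TSV")
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown format {format!r}")
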