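"""Cohort tables, feature schemas, and min-max normalization.

A cohort is a flat table: one row per subject, one column per clinical
feature, plus a categorical risk label (e.g. low / medium / high risk,
TIA, stroke).  Raw files may carry textual categories ("married",
"primary"); a :class:`FeatureSchema` declares each column's kind
(binary / ordinal / continuous) and, for textual columns, the
text-to-integer encoding.  After digitization every column is rescaled
independently to [0, 1] by min-max normalization,

    x' = (x - min x) / (max x - min x),

with the per-column (min, max) retained so held-out rows can be
transformed with training statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

VALID_KINDS = ("binary", "ordinal", "continuous")


@dataclass
class ColumnSpec:
    """Declaration of a single raw column."""

    name: str
    kind: str  # binary | ordinal | continuous
    encoding: dict[str, int] | None = None  # raw text -> integer code

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(
                f"column {self.name!r}: kind must be one of {VALID_KINDS}, got {self.kind!r}"
            )
        if self.encoding is not None:
            codes = sorted(self.encoding.values())
            if codes != list(range(len(codes))):
                raise ValueError(
                    f"column {self.name!r}: encoding must map onto consecutive "
                    f"integers starting at 0, got codes {codes}"
                )


@dataclass
class FeatureSchema:
    """Typed description of a cohort file: feature columns plus the label column.

    Parameters
    ----------
    columns : list of ColumnSpec
        One entry per feature column, in file order.
    label : str
        Name of the label column in the raw file.
    label_encoding : mapping, optional
        Text -> integer code for the label column; category names are the
        keys ordered by code.  If omitted the label column must already be
        integer-coded and ``label_names`` must be given.
    label_names : sequence of str, optional
        Category names ordered by code (derived from ``label_encoding``
        when that is present).
    """

    columns: list[ColumnSpec]
    label: str
    label_encoding: dict[str, int] | None = None
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in schema")
        if self.label_encoding is not None and not self.label_names:
            inv = sorted(self.label_encoding.items(), key=lambda kv: kv[1])
            codes = [v for _, v in inv]
            if codes != list(range(len(codes))):
                raise ValueError("label encoding codes must be consecutive from 0")
            self.label_names = [k for k, _ in inv]

    @property
    def feature_names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def feature_kinds(self) -> list[str]:
        return [c.kind for c in self.columns]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        raw = yaml.safe_load(Path(path).read_text())
        cols = [
            ColumnSpec(name=c["name"], kind=c["kind"], encoding=c.get("encoding"))
            for c in raw["columns"]
        ]
        return cls(
            columns=cols,
            label=raw["label"],
            label_encoding=raw.get("label_encoding"),
            label_names=list(raw.get("label_names", [])),
        )

    def to_yaml(self, path: str | Path) -> None:
        out = {
            "columns": [
                {"name": c.name, "kind": c.kind, **({"encoding": c.encoding} if c.encoding else {})}
                for c in self.columns
            ],
            "label": self.label,
        }
        if self.label_encoding is not None:
            out["label_encoding"] = self.label_encoding
        elif self.label_names:
            out["label_names"] = self.label_names
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


@dataclass
class FeatureTable:
    """Numeric subjects-by-features matrix with named, typed columns."""

    values: np.ndarray  # (n_subjects, d_features) float64
    feature_names: list[str]
    feature_kinds: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("table must have at least one row and one column")
        if d != len(self.feature_names) or d != len(self.feature_kinds):
            raise ValueError("feature_names/feature_kinds length must match columns")
        if np.isnan(self.values).any():
            raise ValueError("table contains missing entries")
        if self.normalized and ((self.values < 0).any() or (self.values > 1).any()):
            raise ValueError("normalized table has entries outside [0, 1]")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def d_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select(self, names: Sequence[str]) -> "FeatureTable":
        """Restrict to the given columns, preserving their stored order here."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            feature_kinds=[self.feature_kinds[i] for i in idx],
            normalized=self.normalized,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


@dataclass
class LabelVector:
    """Integer-coded risk category per subject."""

    codes: np.ndarray  # (n_subjects,) int
    category_names: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        k = len(self.category_names)
        if k < 2:
            raise ValueError("need at least two categories")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= k):
            raise ValueError(f"label codes must lie in [0, {k - 1}]")

    @property
    def n_categories(self) -> int:
        return len(self.category_names)

    def __len__(self) -> int:
        return int(self.codes.size)


def read_cohort(
    path: str | Path,
    schema: FeatureSchema,
    *,
    delimiter: str | None = None,
    drop_missing: bool = False,
) -> tuple[FeatureTable, LabelVector]:
    """Read a CSV/TSV cohort file and digitize textual columns per the schema.

    The returned table is NOT yet normalized.  Unknown category strings
    raise a ``ValueError`` naming the column and offending value.  Missing
    values raise by default; ``drop_missing=True`` drops the affected rows.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter, dtype=object)

    needed = schema.feature_names + [schema.label]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file lacks columns: {missing_cols}")
    df = df[needed]

    na_mask = df.isna().any(axis=1)
    if na_mask.any():
        if drop_missing:
            df = df.loc[~na_mask]
            if df.empty:
                raise ValueError("all rows contained missing values")
        else:
            bad = df.columns[df.isna().any(axis=0)].tolist()
            raise ValueError(
                f"missing values in columns {bad}; pass drop_missing=True to drop rows"
            )

    def digitize(series: pd.Series, name: str, encoding: Mapping[str, int] | None) -> np.ndarray:
        if encoding is not None:
            unknown = set(series.astype(str)) - set(encoding)
            if unknown:
                raise ValueError(
                    f"column {name!r}: unmapped category value(s) {sorted(unknown)!r}"
                )
            return series.astype(str).map(encoding).to_numpy(dtype=float)
        try:
            return series.astype(float).to_numpy()
        except ValueError as exc:
            raise ValueError(
                f"column {name!r} is textual but the schema declares no encoding: {exc}"
            ) from None

    cols = [digitize(df[c.name], c.name, c.encoding) for c in schema.columns]
    values = np.column_stack(cols)

    lab_raw = digitize(df[schema.label], schema.label, schema.label_encoding)
    codes = lab_raw.astype(int)
    if not np.array_equal(lab_raw, codes):
        raise ValueError(f"label column {schema.label!r} contains non-integer codes")
    names = schema.label_names or [str(i) for i in range(int(codes.max()) + 1)]

    table = FeatureTable(
        values=values,
        feature_names=schema.feature_names,
        feature_kinds=schema.feature_kinds,
        normalized=False,
    )
    return table, LabelVector(codes=codes, category_names=list(names))


@dataclass
class NormalizationStats:
    """Per-column (min, max) from a training table, reusable on held-out rows."""

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, table: FeatureTable, *, clip: bool = True) -> FeatureTable:
        if table.feature_names != self.feature_names:
            raise ValueError("column names do not match the stored statistics")
        span = self.maxs - self.mins
        out = np.zeros_like(table.values)
        nz = span > 0
        out[:, nz] = (table.values[:, nz] - self.mins[nz]) / span[nz]
        if clip:
            out = np.clip(out, 0.0, 1.0)
        return FeatureTable(
            values=out,
            feature_names=list(table.feature_names),
            feature_kinds=list(table.feature_kinds),
            normalized=True,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "mins": self.mins.tolist(),
                    "maxs": self.maxs.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        raw = json.loads(Path(path).read_text())
        return cls(
            feature_names=list(raw["feature_names"]),
            mins=np.asarray(raw["mins"], dtype=float),
            maxs=np.asarray(raw["maxs"], dtype=float),
        )


def minmax_normalize(table: FeatureTable) -> tuple[FeatureTable, NormalizationStats]:
    """Rescale each column to [0, 1] by (x - min) / (max - min).

    Constant columns cannot be rescaled (zero range); they are set to all
    zeros with a warning and left for downstream selection to discard.
    Returns the normalized table and the per-column statistics.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    mins = table.values.min(axis=0)
    maxs = table.values.max(axis=0)
    const = np.flatnonzero(maxs == mins)
    if const.size:
        names = [table.feature_names[i] for i in const]
        warnings.warn(
            f"constant column(s) {names} set to zeros (zero range)", UserWarning, stacklevel=2
        )
    stats = NormalizationStats(
        feature_names=list(table.feature_names), mins=mins.copy(), maxs=maxs.copy()
    )
    normalized = stats.transform(
        FeatureTable(
            values=table.values,
            feature_names=list(table.feature_names),
            feature_kinds=list(table.feature_kinds),
            normalized=False,
        ),
        clip=False,
    )
    return normalized, stats


def write_cohort(
    path: str | Path,
    table: FeatureTable,
    labels: LabelVector,
    *,
    label_column: str = "risk",
) -> None:
    """Write a numeric cohort CSV in the same layout ``read_cohort`` consumes."""
    df = table.to_dataframe()
    df[label_column] = labels.codes
    df.to_csv(path, index=False)
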