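"""Core data types: labelled matrices, module maps, annotation tables and
multi-layer result matrices, plus the preprocessing operations applied
before any analysis.

A :class:`DataMatrix` is a labelled numeric matrix (rows are genes or
probes, columns are samples or conditions) with a single value layer.  A
:class:`BinaryMatrix` restricts values to {0, 1, missing} and records
events such as "gene g was called up-regulated in sample s".  A
:class:`ModuleMap` holds named gene sets (pathways, GO terms, ...).  A
:class:`ResultMatrix` is the output of an analysis engine: the same grid of
labels, but with several named value layers per cell (observed, expected,
z, p-values, corrected p-values, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "BinaryMatrix",
    "ModuleMap",
    "AnnotationTable",
    "ResultMatrix",
    "TestConfig",
    "DataError",
    "median_center_scale",
    "log2ratio_vs_reference",
    "binarize",
    "filter_matrix",
    "filter_modules",
]


class DataError(ValueError):
    """Raised when input data violates a structural precondition."""


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise DataError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)
    return labels


class DataMatrix:
    """Labelled numeric matrix with one value layer.

    Parameters
    ----------
    values
        2-D array-like or :class:`pandas.DataFrame` of floats; NaN marks
        missing values.
    row_ids, col_ids
        Ordered unique labels; taken from the DataFrame when omitted.
    layer_name
        Name of the value layer (e.g. ``"log2ratio"``).
    """

    def __init__(self, values, row_ids=None, col_ids=None, layer_name: str = "value"):
        if isinstance(values, pd.DataFrame):
            df = values.astype(float)
            if row_ids is not None:
                df.index = pd.Index(_check_unique(row_ids, "row"))
            if col_ids is not None:
                df.columns = pd.Index(_check_unique(col_ids, "column"))
        else:
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 2:
                raise DataError("matrix values must be two-dimensional")
            if row_ids is None:
                row_ids = [f"r{i}" for i in range(arr.shape[0])]
            if col_ids is None:
                col_ids = [f"c{j}" for j in range(arr.shape[1])]
            df = pd.DataFrame(arr, index=_check_unique(row_ids, "row"),
                              columns=_check_unique(col_ids, "column"))
        _check_unique(list(df.index), "row")
        _check_unique(list(df.columns), "column")
        self.df = df
        self.layer_name = layer_name

    # -- basic protocol ----------------------------------------------------
    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def get(self, row_id: str, col_id: str) -> float:
        return float(self.df.at[row_id, col_id])

    def copy_like(self, values: np.ndarray, col_ids=None) -> "DataMatrix":
        return type(self)(values, self.row_ids,
                          col_ids if col_ids is not None else self.col_ids,
                          layer_name=self.layer_name)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DataMatrix):
            return NotImplemented
        if self.row_ids != other.row_ids or self.col_ids != other.col_ids:
            return False
        a, b = self.values, other.values
        both_nan = np.isnan(a) & np.isnan(b)
        return bool(np.all(both_nan | (a == b)))

    def __repr__(self) -> str:
        r, c = self.shape
        return f"<{type(self).__name__} {r}x{c} layer={self.layer_name!r}>"


class BinaryMatrix(DataMatrix):
    """DataMatrix whose non-missing values are all 0 or 1 (event matrix)."""

    def __init__(self, values, row_ids=None, col_ids=None, layer_name: str = "event"):
        super().__init__(values, row_ids, col_ids, layer_name=layer_name)
        v = self.values
        ok = np.isnan(v) | (v == 0.0) | (v == 1.0)
        if not ok.all():
            bad = v[~ok].flat[0]
            raise DataError(f"binary matrix contains non-binary value {bad!r}")


class ModuleMap:
    """Named gene sets: mapping module id -> ordered unique member ids.

    Member order is preserved (it matters for bit-stable serialization);
    membership queries use sets internally.  Empty modules are allowed on
    construction but flagged with a warning, mirroring permissive loading.
    """

    def __init__(self, modules: Mapping[str, Iterable[str]] | None = None,
                 descriptions: Mapping[str, str] | None = None):
        self._members: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = dict(descriptions or {})
        for name, members in (modules or {}).items():
            self.add(name, members)

    def add(self, module_id: str, members: Iterable[str],
            description: str | None = None) -> None:
        module_id = str(module_id)
        if module_id in self._members:
            raise DataError(f"duplicate module id: {module_id!r}")
        uniq: list[str] = []
        seen: set[str] = set()
        dups = 0
        for m in members:
            m = str(m)
            if m in seen:
                dups += 1
                continue
            seen.add(m)
            uniq.append(m)
        if dups:
            warnings.warn(f"module {module_id!r}: {dups} duplicate member(s) removed")
        if not uniq:
            warnings.warn(f"module {module_id!r} is empty")
        self._members[module_id] = uniq
        if description is not None:
            self.descriptions[module_id] = description

    @property
    def module_ids(self) -> list[str]:
        return list(self._members)

    def members(self, module_id: str) -> list[str]:
        return list(self._members[module_id])

    def member_set(self, module_id: str) -> frozenset[str]:
        return frozenset(self._members[module_id])

    def size(self, module_id: str) -> int:
        return len(self._members[module_id])

    def items(self):
        return ((k, list(v)) for k, v in self._members.items())

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, module_id: str) -> bool:
        return module_id in self._members

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModuleMap):
            return NotImplemented
        return self._members == other._members

    def __repr__(self) -> str:
        return f"<ModuleMap {len(self)} modules>"


class AnnotationTable:
    """Attribute table: one row per element, a unique primary id column plus
    arbitrary named attribute columns."""

    def __init__(self, df: pd.DataFrame, primary_id: str | None = None):
        if primary_id is None:
            primary_id = df.columns[0]
        ids = _check_unique(df[primary_id].astype(str).tolist(), "primary id")
        self.df = df.copy()
        self.df[primary_id] = ids
        self.primary_id = primary_id

    def attributes(self) -> list[str]:
        return [c for c in self.df.columns if c != self.primary_id]

    def lookup(self, element_id: str) -> dict[str, object]:
        row = self.df[self.df[self.primary_id] == element_id]
        if row.empty:
            raise KeyError(element_id)
        return row.iloc[0].to_dict()


#: layer names every hypothesis-test engine must emit
CORE_RESULT_LAYERS = ("observed", "expected", "z",
                      "p_left", "p_right", "p_two", "p_right_corrected")

_P_LAYER_PREFIXES = ("p_", "combined_p")


def _is_p_layer(name: str) -> bool:
    return name.startswith("p_") or name in ("combined_p", "jaccard")


class ResultMatrix:
    """Analysis output: a grid of (row, column) cells where each cell carries
    several named values ("layers"), e.g. observed, expected, z and the
    left / right / two-sided p-values.
    """

    def __init__(self, layers: Mapping[str, pd.DataFrame], default_layer: str):
        if not layers:
            raise DataError("ResultMatrix needs at least one layer")
        names = list(layers)
        first = layers[names[0]]
        self.layers: dict[str, pd.DataFrame] = {}
        for name, df in layers.items():
            if list(df.index) != list(first.index) or list(df.columns) != list(first.columns):
                raise DataError(f"layer {name!r} has inconsistent labels")
            df = df.astype(float)
            if _is_p_layer(name):
                v = df.to_numpy()
                bad = ~np.isnan(v) & ((v < -1e-12) | (v > 1 + 1e-12))
                if bad.any():
                    raise DataError(f"layer {name!r} has values outside [0, 1]")
            self.layers[name] = df
        if default_layer not in self.layers:
            raise DataError(f"default layer {default_layer!r} not among layers")
        self.default_layer = default_layer
        _check_unique(list(first.index), "row")
        _check_unique(list(first.columns), "column")

    @property
    def row_ids(self) -> list[str]:
        return list(next(iter(self.layers.values())).index)

    @property
    def col_ids(self) -> list[str]:
        return list(next(iter(self.layers.values())).columns)

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def layer(self, name: str) -> pd.DataFrame:
        return self.layers[name]

    def cell(self, row_id: str, col_id: str) -> dict[str, float]:
        """All layer values of one cell, e.g. for hover text or inspection."""
        return {name: float(df.at[row_id, col_id]) for name, df in self.layers.items()}

    def to_long(self) -> pd.DataFrame:
        """Long-format table: one line per (row, column) pair."""
        rows = []
        for r in self.row_ids:
            for c in self.col_ids:
                rec = {"row_id": r, "col_id": c}
                rec.update(self.cell(r, c))
                rows.append(rec)
        return pd.DataFrame(rows, columns=["row_id", "col_id", *self.layer_names])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResultMatrix):
            return NotImplemented
        if self.layer_names != other.layer_names:
            return False
        for name in self.layer_names:
            a, b = self.layers[name].to_numpy(), other.layers[name].to_numpy()
            if a.shape != b.shape:
                return False
            if not np.all((np.isnan(a) & np.isnan(b)) | (a == b)):
                return False
        return (self.row_ids == other.row_ids and self.col_ids == other.col_ids)

    def __repr__(self) -> str:
        r, c = self.shape
        return f"<ResultMatrix {r}x{c} layers={self.layer_names}>"


@dataclass
class TestConfig:
    """Configuration of one hypothesis-test run.

    ``seed`` has no default on purpose: bootstrap-based tests refuse to run
    without an explicit seed so results are always reproducible.
    """

    test_kind: str = "zscore_bootstrap"     # zscore_bootstrap | binomial_exact | fisher_exact
    statistic: str = "mean"                 # mean | median (z-score only)
    bootstrap_iterations: int = 10_000
    seed: int | None = None
    mtc: str = "bh"                         # none | holm | bh
    module_min_size: int = 5
    module_max_size: int | None = None      # None = unbounded
    with_replacement: bool = False          # bootstrap resampling mode

    def __post_init__(self):
        if self.test_kind not in ("zscore_bootstrap", "binomial_exact", "fisher_exact"):
            raise DataError(f"unknown test kind {self.test_kind!r}")
        if self.statistic not in ("mean", "median"):
            raise DataError(f"unknown statistic {self.statistic!r}")
        if self.mtc not in ("none", "holm", "bh"):
            raise DataError(f"unknown correction method {self.mtc!r}")
        if self.bootstrap_iterations < 1:
            raise DataError("bootstrap_iterations must be positive")
        if self.module_min_size < 1:
            raise DataError("module_min_size must be >= 1")
        if self.module_max_size is not None and self.module_max_size < self.module_min_size:
            raise DataError("module_max_size < module_min_size")


# ---------------------------------------------------------------------------
# preprocessing / filtering operations
# ---------------------------------------------------------------------------

def median_center_scale(m: DataMatrix) -> DataMatrix:
    """Median-center each row and divide by its sample standard deviation.

    Rows with zero variance are set to 0 everywhere (no signal) and a
    warning is emitted; missing values are ignored in the row statistics
    and stay missing in the output.
    """
    if m.shape[1] < 2:
        raise DataError("median_center_scale needs at least 2 columns")
    v = m.values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(v, axis=1, keepdims=True)
        sd = np.nanstd(v, axis=1, ddof=1, keepdims=True)
    out = np.full_like(v, np.nan)
    finite = ~np.isnan(v)
    const = (sd == 0) | np.isnan(sd)
    n_const = int(np.any(const & finite.any(axis=1, keepdims=True), axis=1).sum())
    if n_const:
        warnings.warn(f"{n_const} constant row(s) set to 0 after centring")
    safe_sd = np.where(const, 1.0, sd)
    centred = (v - med) / safe_sd
    out[finite] = np.where(np.broadcast_to(const, v.shape), 0.0, centred)[finite]
    return m.copy_like(out)


def log2ratio_vs_reference(m: DataMatrix, ref_cols: Sequence[str]) -> DataMatrix:
    """Per-row log2 ratio of each non-reference column against the mean of
    the reference columns (values assumed already log2-scale)."""
    ref_cols = list(ref_cols)
    if not ref_cols:
        raise DataError("ref_cols must be nonempty")
    missing = [c for c in ref_cols if c not in m.df.columns]
    if missing:
        raise DataError(f"reference columns not in matrix: {missing}")
    keep = [c for c in m.col_ids if c not in set(ref_cols)]
    if not keep:
        raise DataError("reference columns cover the whole matrix; nothing to compare")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref_mean = np.nanmean(m.df[ref_cols].to_numpy(), axis=1, keepdims=True)
    out = m.df[keep].to_numpy() - ref_mean
    res = DataMatrix(out, m.row_ids, keep, layer_name="log2ratio")
    return res


_CMP = {
    "lt": np.less, "le": np.less_equal, "gt": np.greater,
    "ge": np.greater_equal, "eq": np.equal, "ne": np.not_equal,
}


def binarize(m: DataMatrix, cmp: str, cutoff: float) -> BinaryMatrix:
    """Turn a real-valued matrix into a 0/1 event matrix by thresholding.

    ``cmp`` is one of lt/le/gt/ge/eq/ne; missing values stay missing.
    """
    if cmp not in _CMP:
        raise DataError(f"unknown comparator {cmp!r}")
    if not np.isfinite(cutoff):
        raise DataError("cutoff must be finite")
    v = m.values
    out = np.where(np.isnan(v), np.nan, _CMP[cmp](v, cutoff).astype(float))
    return BinaryMatrix(out, m.row_ids, m.col_ids, layer_name="event")


def filter_matrix(m: DataMatrix, keep_rows: Iterable[str] | None = None,
                  keep_cols: Iterable[str] | None = None) -> DataMatrix:
    """Keep only the named rows/columns, preserving the original order.

    Unknown labels are ignored with a warning; an empty result is an error.
    """
    rows = m.row_ids
    cols = m.col_ids
    if keep_rows is not None:
        wanted = {str(x) for x in keep_rows}
        unknown = wanted - set(rows)
        if unknown:
            warnings.warn(f"{len(unknown)} unknown row label(s) ignored")
        rows = [r for r in rows if r in wanted]
    if keep_cols is not None:
        wanted = {str(x) for x in keep_cols}
        unknown = wanted - set(cols)
        if unknown:
            warnings.warn(f"{len(unknown)} unknown column label(s) ignored")
        cols = [c for c in cols if c in wanted]
    if not rows or not cols:
        raise DataError("filter would produce an empty matrix")
    return type(m)(m.df.loc[rows, cols], layer_name=m.layer_name)


def filter_modules(mm: ModuleMap, min_size: int = 1, max_size: int | None = None,
                   universe: Iterable[str] | None = None) -> ModuleMap:
    """Restrict modules to a universe of testable items, then drop modules
    whose remaining size falls outside [min_size, max_size].

    The intersection happens BEFORE the size filter so that size reflects
    testable members only.  The returned map carries a ``filter_report``
    attribute: module id -> reason string for every dropped module.
    """
    if min_size < 1:
        raise DataError("min_size must be >= 1")
    uni = None if universe is None else {str(x) for x in universe}
    out = ModuleMap()
    report: dict[str, str] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, members in mm.items():
            if uni is not None:
                members = [x for x in members if x in uni]
            n = len(members)
            if n < min_size:
                report[name] = f"size {n} < min {min_size}"
            elif max_size is not None and n > max_size:
                report[name] = f"size {n} > max {max_size}"
            else:
                out.add(name, members, mm.descriptions.get(name))
    if len(out) == 0:
        raise DataError(
            f"all {len(mm)} module(s) dropped by size/universe filter "
            f"(min={min_size}, max={max_size})")
    out.filter_report = report  # type: ignore[attr-defined]
    return out
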