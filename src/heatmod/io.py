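"""Readers and writers for the tab-delimited file formats the package
understands.

Gene sets travel in three tab-delimited layouts:

* **GMT** — one module per line: ``name<TAB>description<TAB>member...``
* **GMX** — one module per column: first row names, second row
  descriptions, members below (ragged columns allowed)
* **TCM** — two-column mapping: one ``item<TAB>module`` pair per line

Matrices are plain tab-delimited text: a header row of column labels, then
one row label plus values per line; empty fields, ``NA`` and ``-`` read as
missing.  Analysis results serialize as a long-format TSV (one line per
cell, one column per layer) that round-trips exactly.

All files are UTF-8 with LF line endings and a TAB separator; labels may
not contain TABs.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import BinaryMatrix, DataError, DataMatrix, ModuleMap, ResultMatrix

__all__ = [
    "read_modules", "write_modules",
    "read_matrix", "write_matrix",
    "read_results_table", "write_results_table",
    "guess_format",
]

MISSING_TOKENS = {"", "NA", "-", "nan", "NaN"}
MODULE_FORMATS = ("gmt", "gmx", "tcm")


class ParseError(DataError):
    """A malformed line, with its location."""


def guess_format(path) -> str:
    """Infer a format id from a file extension."""
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in MODULE_FORMATS:
        return suffix
    if suffix in ("tdm", "tsv", "txt"):
        return "tdm"
    raise DataError(f"cannot infer format from extension {suffix!r}")


def _check_label(label: str, where: str) -> str:
    if "\t" in label:
        raise DataError(f"TAB inside {where} label {label!r}")
    return label


def _read_lines(path):
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError(f"{path}: file is empty")
    for i, line in enumerate(text.split("\n"), start=1):
        if line == "" or line.startswith("#"):
            continue
        yield i, line


def _num_to_str(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    if np.isnan(x):
        return ""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _parse_number(tok: str, path, lineno: int) -> float:
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return float("nan")
    try:
        return float(tok)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: not a number: {tok!r}") from None


# ---------------------------------------------------------------------------
# module formats
# ---------------------------------------------------------------------------

def read_modules(path, format: str | None = None,
                 tcm_order: str = "item-first") -> ModuleMap:
    """Read a gene-set file in GMT, GMX or TCM format.

    ``tcm_order`` selects the TCM column dialect: ``item-first`` (default,
    ``item<TAB>module``) or ``module-first``.
    """
    fmt = format or guess_format(path)
    if fmt not in MODULE_FORMATS:
        raise DataError(f"unknown module format {fmt!r}")
    mm = ModuleMap()
    if fmt == "gmt":
        for lineno, line in _read_lines(path):
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 2 fields")
            name, desc, *members = fields
            members = [m for m in members if m != ""]
            mm.add(name, members, description=desc)
    elif fmt == "gmx":
        rows = [line.split("\t") for _, line in _read_lines(path)]
        if len(rows) < 2:
            raise ParseError(f"{path}: GMX needs a name row and a description row")
        names, descs = rows[0], rows[1]
        for j, name in enumerate(names):
            if name == "":
                continue
            desc = descs[j] if j < len(descs) else ""
            members = [row[j] for row in rows[2:] if j < len(row) and row[j] != ""]
            mm.add(name, members, description=desc)
    else:  # tcm
        if tcm_order not in ("item-first", "module-first"):
            raise DataError(f"unknown tcm order {tcm_order!r}")
        pairs: dict[str, list[str]] = {}
        for lineno, line in _read_lines(path):
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: TCM line needs exactly 2 fields")
            item, module = fields if tcm_order == "item-first" else fields[::-1]
            pairs.setdefault(module, []).append(item)
        for module, items in pairs.items():
            mm.add(module, items)
    return mm


def write_modules(mm: ModuleMap, path, format: str | None = None,
                  tcm_order: str = "item-first") -> None:
    """Write a :class:`ModuleMap` in GMT, GMX or TCM format.

    Output is bit-stable: modules in insertion order, members in original
    order, TAB separated, LF endings.  TCM drops descriptions (the format
    has no field for them).
    """
    if len(mm) == 0:
        raise DataError("refusing to write an empty module map")
    fmt = format or guess_format(path)
    if fmt not in MODULE_FORMATS:
        raise DataError(f"unknown module format {fmt!r}")
    lines: list[str] = []
    for name, members in mm.items():
        _check_label(name, "module")
        for m in members:
            _check_label(m, "member")
    if fmt == "gmt":
        for name, members in mm.items():
            desc = mm.descriptions.get(name, "")
            _check_label(desc, "description")
            lines.append("\t".join([name, desc, *members]))
    elif fmt == "gmx":
        names = mm.module_ids
        descs = [mm.descriptions.get(n, "") for n in names]
        for d in descs:
            _check_label(d, "description")
        cols = [mm.members(n) for n in names]
        depth = max(len(c) for c in cols)
        lines.append("\t".join(names))
        lines.append("\t".join(descs))
        for i in range(depth):
            row = [col[i] if i < len(col) else "" for col in cols]
            lines.append("\t".join(row).rstrip("\t"))
    else:  # tcm
        for name, members in mm.items():
            for m in members:
                pair = (m, name) if tcm_order == "item-first" else (name, m)
                lines.append("\t".join(pair))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def read_matrix(path, binary: bool = False) -> DataMatrix:
    """Read a tab-delimited matrix: header row of column labels, then one
    row label + values per line.  Empty fields, ``NA`` and ``-`` are
    missing.  ``binary=True`` validates and returns a
    :class:`BinaryMatrix`."""
    it = _read_lines(path)
    try:
        _, header = next(it)
    except StopIteration:  # pragma: no cover - _read_lines already errors
        raise ParseError(f"{path}: no header line") from None
    cols = header.split("\t")[1:]  # first header field labels the row ids
    if len(set(cols)) != len(cols):
        raise ParseError(f"{path}: duplicate column header")
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in it:
        fields = line.split("\t")
        if len(fields) != len(cols) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(cols) + 1} fields, got {len(fields)}")
        if fields[0] in row_ids:
            raise ParseError(f"{path}:{lineno}: duplicate row label {fields[0]!r}")
        row_ids.append(fields[0])
        rows.append([_parse_number(tok, path, lineno) for tok in fields[1:]])
    if not rows:
        raise ParseError(f"{path}: no data rows")
    cls = BinaryMatrix if binary else DataMatrix
    return cls(np.asarray(rows, dtype=float), row_ids, cols)


def write_matrix(m: DataMatrix, path, row_header: str = "id") -> None:
    """Write a matrix as tab-delimited text; missing values become empty
    fields."""
    for lab in (*m.row_ids, *m.col_ids):
        _check_label(lab, "matrix")
    lines = ["\t".join([row_header, *m.col_ids])]
    v = m.values
    for i, r in enumerate(m.row_ids):
        lines.append("\t".join([r, *(_num_to_str(x) for x in v[i])]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def write_results_table(r: ResultMatrix, path) -> None:
    """Serialize a :class:`ResultMatrix` as a long-format TSV: one line per
    (row, column) cell, columns ``row_id``, ``col_id`` and one per layer.
    Values are written with full round-trip precision."""
    layer_names = r.layer_names
    header = ["row_id", "col_id", *layer_names]
    lines = ["#default_layer\t" + r.default_layer, "\t".join(header)]
    for row in r.row_ids:
        _check_label(row, "row")
        for col in r.col_ids:
            _check_label(col, "column")
            cell = r.cell(row, col)
            lines.append("\t".join(
                [row, col, *(_num_to_str(cell[k]) for k in layer_names)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_results_table(path) -> ResultMatrix:
    """Re-read a long-format results TSV written by
    :func:`write_results_table`."""
    text = Path(path).read_text(encoding="utf-8")
    default_layer = None
    body: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.split("\n"), start=1):
        if line.startswith("#default_layer\t"):
            default_layer = line.split("\t", 1)[1]
            continue
        if line == "" or line.startswith("#"):
            continue
        body.append((lineno, line))
    if not body:
        raise ParseError(f"{path}: empty results table")
    header = body[0][1].split("\t")
    if header[:2] != ["row_id", "col_id"]:
        raise ParseError(f"{path}: results table must start with row_id, col_id")
    layer_names = header[2:]
    row_ids: list[str] = []
    col_ids: list[str] = []
    cells: dict[tuple[str, str], list[float]] = {}
    for lineno, line in body[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(f"{path}:{lineno}: ragged results line")
        row, col = fields[0], fields[1]
        if row not in row_ids:
            row_ids.append(row)
        if col not in col_ids:
            col_ids.append(col)
        cells[(row, col)] = [_parse_number(t, path, lineno) for t in fields[2:]]
    layers = {}
    for k, name in enumerate(layer_names):
        grid = np.full((len(row_ids), len(col_ids)), np.nan)
        for (row, col), vals in cells.items():
            grid[row_ids.index(row), col_ids.index(col)] = vals[k]
        layers[name] = pd.DataFrame(grid, index=row_ids, columns=col_ids)
    if default_layer is None or default_layer not in layer_names:
        default_layer = layer_names[0]
    return ResultMatrix(layers, default_layer=default_layer)
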