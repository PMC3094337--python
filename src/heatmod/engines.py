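"""The five analysis engines: module enrichment, per-gene alteration
significance, p-value combination, correlation and overlap.

Each engine wires the statistical kernel over a labelled matrix (and,
for enrichment, a module map) and returns a :class:`ResultMatrix` whose
cells carry the full set of statistics for later browsing and export.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats
from .matrix import (BinaryMatrix, DataError, DataMatrix, ModuleMap,
                     ResultMatrix, TestConfig, filter_modules)

__all__ = [
    "run_enrichment",
    "run_oncodrive",
    "run_combination",
    "run_correlation",
    "run_overlap",
]

#: layers emitted by the hypothesis-test engines, in column order
TEST_LAYERS = ["observed", "expected", "z", "p_left", "p_right", "p_two",
               "n", "p_right_corrected"]


def _is_binary(m: DataMatrix) -> bool:
    return isinstance(m, BinaryMatrix)


def _check_test_matches_matrix(m: DataMatrix, cfg: TestConfig) -> None:
    if cfg.test_kind == "zscore_bootstrap" and _is_binary(m):
        raise DataError("z-score test expects a real-valued matrix; "
                        "binary event data calls for binomial or Fisher")
    if cfg.test_kind in ("binomial_exact", "fisher_exact") and not _is_binary(m):
        raise DataError(f"{cfg.test_kind} expects a binary event matrix; "
                        "binarize the data first or use the z-score test")


def _empty_layers(rows, cols) -> dict[str, pd.DataFrame]:
    return {name: pd.DataFrame(np.nan, index=rows, columns=cols)
            for name in TEST_LAYERS}


def _fill(layers, row, col, res: stats.TestResult) -> None:
    layers["observed"].at[row, col] = res.observed
    layers["expected"].at[row, col] = res.expected
    layers["z"].at[row, col] = np.nan if res.z is None else res.z
    layers["p_left"].at[row, col] = res.p_left
    layers["p_right"].at[row, col] = res.p_right
    layers["p_two"].at[row, col] = res.p_two
    layers["n"].at[row, col] = res.n_module


def _correct_columns(layers, mtc: str) -> None:
    """Fill p_right_corrected, one family per result column."""
    pr = layers["p_right"]
    if mtc == "none":
        layers["p_right_corrected"] = pr.copy()
        return
    out = pr.copy()
    for col in pr.columns:
        out[col] = stats.adjust_pvalues(pr[col].to_numpy(), method=mtc)
    layers["p_right_corrected"] = out


def run_enrichment(m: DataMatrix, mm: ModuleMap, cfg: TestConfig) -> ResultMatrix:
    """Module enrichment over every column of a matrix.

    For a real-valued matrix (e.g. expression log2 ratios) the z-score
    resampling test compares each module's mean (or median) in a column
    against random same-size gene sets drawn from that column.  For a
    binary event matrix the binomial or Fisher exact test asks whether
    events concentrate in the module.  Result rows are the surviving
    modules, columns the matrix columns; right-tail p-values are corrected
    across modules within each column.
    """
    _check_test_matches_matrix(m, cfg)
    mm = filter_modules(mm, cfg.module_min_size, cfg.module_max_size,
                        universe=m.row_ids)
    modules = mm.module_ids
    cols = m.col_ids
    layers = _empty_layers(modules, cols)
    row_index = {r: i for i, r in enumerate(m.row_ids)}
    values = m.values
    rng_streams = None
    if cfg.test_kind == "zscore_bootstrap":
        if cfg.seed is None:
            raise DataError("bootstrap enrichment requires an explicit seed")
        seeds = np.random.SeedSequence(cfg.seed).spawn(len(modules) * len(cols))
        rng_streams = iter(seeds)
    for mod in modules:
        member_idx = np.array([row_index[x] for x in mm.members(mod)], dtype=int)
        for j, col in enumerate(cols):
            colvals = values[:, j]
            modvals = colvals[member_idx]
            modvals = modvals[~np.isnan(modvals)]
            if cfg.test_kind == "zscore_bootstrap":
                rng = np.random.default_rng(next(rng_streams))
                if modvals.size < 3:
                    continue  # too few observed members: missing result
                bg = colvals[~np.isnan(colvals)]
                res = stats.zscore_bootstrap(modvals, bg, cfg, rng=rng)
            else:
                bg = colvals[~np.isnan(colvals)]
                if modvals.size < 3:
                    continue
                k = int(modvals.sum())
                if cfg.test_kind == "binomial_exact":
                    p0 = float(bg.mean()) if bg.size else 0.0
                    res = stats.binomial_exact(k, modvals.size, p0)
                else:
                    a = k
                    b = modvals.size - k
                    c = int(bg.sum()) - a
                    d = (bg.size - int(bg.sum())) - b
                    res = stats.fisher_exact(a, b, c, d)
            _fill(layers, mod, col, res)
    _correct_columns(layers, cfg.mtc)
    rm = ResultMatrix(layers, default_layer="p_right")
    rm.module_filter_report = getattr(mm, "filter_report", {})  # type: ignore[attr-defined]
    return rm


def run_oncodrive(m: DataMatrix, cfg: TestConfig) -> ResultMatrix:
    """Per-gene alteration significance against the whole-matrix background.

    The tested unit is a row (gene) and the null is built from the entire
    matrix: for real data, a z-score resampling test of the gene's values
    against random same-size draws from all matrix values; for binary
    data, a binomial test of the gene's event count against the global
    event rate.  The result has one column; p-values are corrected across
    genes.
    """
    _check_test_matches_matrix(m, cfg)
    if m.shape[1] < 2:
        raise DataError("per-gene analysis needs at least 2 columns")
    rows = m.row_ids
    layers = _empty_layers(rows, ["all"])
    values = m.values
    flat = values[~np.isnan(values)]
    if flat.size == 0:
        raise DataError("matrix has no non-missing values")
    rng_streams = None
    if cfg.test_kind == "zscore_bootstrap":
        if cfg.seed is None:
            raise DataError("bootstrap analysis requires an explicit seed")
        rng_streams = iter(np.random.SeedSequence(cfg.seed).spawn(len(rows)))
    global_rate = float(flat.mean()) if _is_binary(m) else None
    total_events = int(flat.sum()) if _is_binary(m) else None
    for i, gene in enumerate(rows):
        rowvals = values[i]
        rowvals = rowvals[~np.isnan(rowvals)]
        if cfg.test_kind == "zscore_bootstrap":
            rng = np.random.default_rng(next(rng_streams))
            if rowvals.size < 3:
                continue
            res = stats.zscore_bootstrap(rowvals, flat, cfg, rng=rng)
        else:
            if rowvals.size < 3:
                continue
            k = int(rowvals.sum())
            if cfg.test_kind == "binomial_exact":
                res = stats.binomial_exact(k, rowvals.size, global_rate)
            else:
                a = k
                b = rowvals.size - k
                c = total_events - a
                d = (flat.size - total_events) - b
                res = stats.fisher_exact(a, b, c, d)
        _fill(layers, gene, "all", res)
    _correct_columns(layers, cfg.mtc)
    return ResultMatrix(layers, default_layer="p_right")


def _extract_p_column(inp, layer: str) -> pd.DataFrame:
    """One or more p-value columns from a ResultMatrix layer or a plain
    p-value matrix."""
    if isinstance(inp, ResultMatrix):
        if layer not in inp.layers:
            raise DataError(f"input has no layer {layer!r}")
        return inp.layer(layer)
    if isinstance(inp, DataMatrix):
        return inp.df
    raise DataError(f"cannot combine input of type {type(inp).__name__}")


def run_combination(inputs, layer: str = "p_right",
                    cfg: stats.CombineConfig | None = None) -> ResultMatrix:
    """Combine per-row p-values across several experiments with the
    weighted Z-method.

    Each input (a :class:`ResultMatrix` layer or a p-value matrix)
    contributes its columns as independent experiments.  Rows are matched
    by id across inputs (union; missing where absent).  The single-column
    result carries ``combined_p``, ``combined_z`` and ``n_inputs_used``.
    With ``weight_mode="user"`` one weight per input is applied to all of
    that input's columns.
    """
    cfg = cfg or stats.CombineConfig()
    if not inputs:
        raise DataError("no inputs to combine")
    frames = [_extract_p_column(inp, layer) for inp in inputs]
    if cfg.weight_mode == "user" and len(cfg.weights) != len(inputs):
        raise DataError("need exactly one weight per input")
    all_rows: list[str] = []
    for f in frames:
        for r in f.index:
            if r not in all_rows:
                all_rows.append(r)
    n_frames = []
    if cfg.weight_mode == "sqrt_n":
        for inp in inputs:
            if isinstance(inp, ResultMatrix) and "n" in inp.layers:
                n_frames.append(inp.layer("n"))
            else:
                raise DataError("sqrt_n weighting needs inputs with an 'n' layer")
    combined_p = pd.DataFrame(np.nan, index=all_rows, columns=["combined"])
    combined_z = pd.DataFrame(np.nan, index=all_rows, columns=["combined"])
    n_used = pd.DataFrame(np.nan, index=all_rows, columns=["combined"])
    for row in all_rows:
        ps: list[float] = []
        ws: list[float] = []
        for i, f in enumerate(frames):
            for col in f.columns:
                p = float(f.at[row, col]) if row in f.index else float("nan")
                if cfg.weight_mode == "user":
                    w = float(cfg.weights[i])
                elif cfg.weight_mode == "sqrt_n":
                    n = float(n_frames[i].at[row, col]) if row in n_frames[i].index \
                        else float("nan")
                    w = float(np.sqrt(n)) if np.isfinite(n) and n > 0 else float("nan")
                else:
                    w = 1.0
                ps.append(p)
                ws.append(w)
        p_comb, z_comb, k = stats.weighted_z_combine(ps, ws)
        combined_p.at[row, "combined"] = p_comb
        combined_z.at[row, "combined"] = z_comb
        n_used.at[row, "combined"] = k
    return ResultMatrix(
        {"combined_p": combined_p, "combined_z": combined_z,
         "n_inputs_used": n_used},
        default_layer="combined_p")


def run_correlation(m: DataMatrix, axis: str = "columns") -> ResultMatrix:
    """All-pairs Pearson correlation of a matrix's columns (or rows).

    Returns a square symmetric result with layers ``r``, ``n`` and
    ``p_two``; the diagonal has r = 1.  Pairs with fewer than 3 shared
    non-missing observations are left missing.
    """
    if axis not in ("columns", "rows"):
        raise DataError(f"axis must be 'columns' or 'rows', got {axis!r}")
    data = m.values.T if axis == "columns" else m.values
    labels = m.col_ids if axis == "columns" else m.row_ids
    k = len(labels)
    r_grid = np.full((k, k), np.nan)
    n_grid = np.full((k, k), np.nan)
    p_grid = np.full((k, k), np.nan)
    for i in range(k):
        r_grid[i, i] = 1.0
        n_grid[i, i] = np.sum(~np.isnan(data[i]))
        for j in range(i + 1, k):
            res = stats.pearson(data[i], data[j])
            r_grid[i, j] = r_grid[j, i] = res["r"]
            n_grid[i, j] = n_grid[j, i] = res["n"]
            p_grid[i, j] = p_grid[j, i] = res["p_two"]
    layers = {name: pd.DataFrame(grid, index=labels, columns=labels)
              for name, grid in (("r", r_grid), ("n", n_grid), ("p_two", p_grid))}
    return ResultMatrix(layers, default_layer="r")


def run_overlap(m: BinaryMatrix, axis: str = "columns") -> ResultMatrix:
    """Pairwise overlap of positive cells between columns (or rows) of a
    binary matrix.

    Missing values count as 0 (logged).  Layers: ``count_both``,
    ``count_a``, ``count_b`` and the Jaccard index (0 when both sets are
    empty).
    """
    if not _is_binary(m):
        raise DataError("overlap analysis needs a binary event matrix")
    if axis not in ("columns", "rows"):
        raise DataError(f"axis must be 'columns' or 'rows', got {axis!r}")
    v = m.values
    if np.isnan(v).any():
        warnings.warn("missing values treated as 0 for overlap counting")
    v = np.nan_to_num(v, nan=0.0)
    data = v.T if axis == "columns" else v
    labels = m.col_ids if axis == "columns" else m.row_ids
    both = data @ data.T                       # co-occurring positives
    counts = data.sum(axis=1)
    k = len(labels)
    count_a = np.tile(counts[:, None], (1, k))
    count_b = count_a.T
    union = count_a + count_b - both
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, both / np.where(union > 0, union, 1.0), 0.0)
    layers = {
        "count_both": pd.DataFrame(both, index=labels, columns=labels),
        "count_a": pd.DataFrame(count_a, index=labels, columns=labels),
        "count_b": pd.DataFrame(count_b, index=labels, columns=labels),
        "jaccard": pd.DataFrame(jac, index=labels, columns=labels),
    }
    return ResultMatrix(layers, default_layer="jaccard")
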