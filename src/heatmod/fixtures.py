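"""Deterministic synthetic data: expression-like matrices with planted
module shifts, and binary event matrices with planted high-rate genes.

These generators emulate the structure of a typical module-level analysis
input — an expression matrix with gene sets, or an alteration-call matrix
— so every engine can be exercised and calibrated without any external
download.  The background for real-valued fixtures is iid standard normal,
which is also the calibration reference for the z-score resampling test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import BinaryMatrix, DataError, DataMatrix, ModuleMap

__all__ = ["FixtureSpec", "make_expression_fixture", "make_event_fixture"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``seed`` is mandatory: fixtures must be reproducible.  For expression
    fixtures, ``shift_delta`` is added to the values of ``n_planted``
    modules in every ``target_cols`` column (all columns when None).  For
    event fixtures, ``event_rate`` is the background Bernoulli rate and
    planted genes fire at ``planted_rate``.
    """

    seed: int
    n_genes: int = 500
    n_samples: int = 20
    n_modules: int = 20
    module_size_min: int = 20
    module_size_max: int = 100
    # real-valued (expression) effect model
    shift_delta: float = 0.0
    n_planted: int = 0
    target_cols: list[str] | None = None
    # binary (event) effect model
    event_rate: float = 0.1
    planted_rate: float = 0.1
    n_planted_genes: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise DataError("fixture seed is mandatory")
        for r in (self.event_rate, self.planted_rate):
            if not (0 <= r <= 1):
                raise DataError("rates must be in [0, 1]")
        if self.n_planted > self.n_modules:
            raise DataError("more planted modules than modules")
        if self.n_planted_genes > self.n_genes:
            raise DataError("more planted genes than genes")


def _labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


def make_expression_fixture(spec: FixtureSpec):
    """Expression-like matrix plus modules plus truth labels.

    Background values are iid N(0, 1); each planted module has
    ``shift_delta`` added to its members' values in the target columns.
    Returns ``(DataMatrix, ModuleMap, truth)`` where ``truth`` lists the
    planted module ids.
    """
    if not (1 <= spec.module_size_min <= spec.module_size_max):
        raise DataError("need 1 <= module_size_min <= module_size_max")
    if spec.module_size_max > spec.n_genes:
        raise DataError("module size exceeds number of genes")
    rng = np.random.default_rng(spec.seed)
    genes = _labels("g", spec.n_genes)
    samples = _labels("s", spec.n_samples)
    values = rng.standard_normal((spec.n_genes, spec.n_samples))
    mm = ModuleMap()
    gene_arr = np.array(genes)
    for m in range(spec.n_modules):
        size = int(rng.integers(spec.module_size_min, spec.module_size_max + 1))
        members = rng.choice(spec.n_genes, size=size, replace=False)
        mm.add(f"mod{m + 1}", gene_arr[np.sort(members)].tolist(),
               description=f"synthetic module {m + 1}")
    planted = mm.module_ids[: spec.n_planted]
    target_cols = spec.target_cols if spec.target_cols is not None else samples
    col_idx = [samples.index(c) for c in target_cols]
    gene_index = {g: i for i, g in enumerate(genes)}
    for mod in planted:
        rows = [gene_index[g] for g in mm.members(mod)]
        for j in col_idx:
            values[rows, j] += spec.shift_delta
    matrix = DataMatrix(values, genes, samples, layer_name="expression")
    return matrix, mm, {"planted_modules": planted, "target_cols": list(target_cols)}


def make_event_fixture(spec: FixtureSpec):
    """Binary event matrix plus truth labels.

    Background cells are Bernoulli(``event_rate``); the first
    ``n_planted_genes`` genes fire at ``planted_rate`` instead.  Returns
    ``(BinaryMatrix, truth)`` where ``truth`` lists the planted gene ids.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _labels("g", spec.n_genes)
    samples = _labels("s", spec.n_samples)
    values = (rng.random((spec.n_genes, spec.n_samples)) < spec.event_rate)
    values = values.astype(float)
    planted = genes[: spec.n_planted_genes]
    if planted:
        values[: len(planted)] = (
            rng.random((len(planted), spec.n_samples)) < spec.planted_rate
        ).astype(float)
    matrix = BinaryMatrix(values, genes, samples, layer_name="event")
    return matrix, {"planted_genes": planted}
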