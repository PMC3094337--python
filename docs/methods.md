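# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic-data model the tests calibrate against, and the
numerical conventions. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model

A `DataMatrix` is a labelled dense float matrix with one value layer;
`NaN` marks missing. A `BinaryMatrix` restricts values to {0, 1, missing}
and records events (e.g. "gene called up-regulated in this sample"). A
`ModuleMap` maps module ids to ordered, duplicate-free member lists —
order is preserved because serialization is required to be bit-stable. A
`ResultMatrix` holds several same-shaped layers per cell; every
hypothesis-test engine emits `observed, expected, z, p_left, p_right,
p_two, n, p_right_corrected`, with right-tail p as the default display
layer (over-representation is the usual question).

### Preprocessing

* `median_center_scale` — per row: subtract the row median, divide by the
  row sample standard deviation (ddof = 1 throughout the package). Rows
  with zero variance become all-0 with a warning rather than missing:
  downstream tests then see a defined "no signal" value and the matrix
  stays dense.
* `log2ratio_vs_reference` — per row, subtract the mean of the reference
  (e.g. normal-tissue) columns from each remaining column; values are
  assumed to be already log2-scale, so the difference is a log2 ratio.
* `binarize` — threshold with one of lt/le/gt/ge/eq/ne; missing stays
  missing. This is the bridge from real-valued matrices to the event
  tests.
* `filter_modules` — members are intersected with the analysis universe
  (the matrix's row ids) **before** the size filter, so module size means
  *testable* members. Default size window 5–∞: below ~5 genes a set-level
  statistic adds little over per-gene tests; no upper default because
  informative large sets vary by collection. Both are overridable.

## Hypothesis tests

### Z-score resampling test (real-valued data)

Observed statistic: mean (default) or median of the module's non-missing
values in one column. Null: B random same-size draws **without
replacement** from the column's non-missing values — i.e. the distribution
of the statistic for a *random gene set of the same size*, which is
exactly the enrichment question; a with-replacement mode is available by
flag. `z = (obs − mean_B)/sd_B`, referred to the standard normal for
`p_left`, `p_right`, `p_two = 2(1 − Φ(|z|))`.

Defaults: B = 10 000 (Monte-Carlo noise on z of order 1%, negligible
against biological effect sizes; calibration simulations in the
acceptance suite use B = 1 000, which is already well-calibrated at
α = 0.05). The seed has **no default**: a bootstrap run refuses to start
without one, so results are always reproducible. Degenerate null
(resampling sd ≈ 0, e.g. constant background or module = whole column)
returns z = 0 with p = 1 and an explanatory note rather than NaN
propagation. The sd threshold is relative (1e-12·(|mean|+1)) because a
constant resample vector can acquire ~1e-17 floating jitter.

Per-cell RNG streams are spawned from the configured seed via
`SeedSequence.spawn`, so results are bit-reproducible and independent of
evaluation order.

### Exact tests (event data)

* Binomial: k events among n testable module genes against the column
  event rate p₀ (estimated over all rows of that column; for the per-gene
  analysis, the whole-matrix rate). Tails by exact summation
  (`scipy.stats.binom`); `p_two = min(1, 2·min(p_left, p_right))`.
* Fisher: 2×2 table [[a = module events, b = module non-events],
  [c = outside events, d = outside non-events]], hypergeometric tails with
  fixed margins. Two-sided p sums all point probabilities ≤ P(X = a)
  (minimum-likelihood rule), with a 1e-7 relative slack for floating ties.

A note on two-sided bounds: the identity `p_two ≤ 2·min(p_left, p_right)`
holds for the doubling rule but **not** in general for the
minimum-likelihood rule on skewed hypergeometric supports (violations up
to ~0.12 exist among small tables). The package therefore guarantees it
only for the binomial test.

Cells with fewer than 3 non-missing module values are skipped (missing
result): location statistics on one or two values are not meaningful.

### Per-gene alteration significance

The tested unit is a row (gene); the background is the entire matrix.
Real data: z-score resampling of the gene's values against draws from all
matrix values. Event data: binomial with k = the gene's events, n = its
non-missing sample count, p₀ = the global event rate. This realizes
"more altered than expected by chance given the whole matrix" as the
row-wise transposition of the enrichment battery; the original
formulation this interprets lives in an external supplement, so the
reading is documented here as this package's interpretation. Correction
is across genes (one family).

### Multiple-testing scope

Enrichment corrects `p_right` across modules **within each column**: each
condition is one experiment, and downstream combination consumes one
corrected family per experiment. The per-gene analysis corrects across
genes. Holm and Benjamini–Hochberg are delegated to
`statsmodels.stats.multitest` behind the package's `adjust_pvalues`
surface; missing p-values are excluded from the family size and returned
missing.

### Weighted-Z combination

`zᵢ = Φ⁻¹(1 − pᵢ)`, `Z = Σwᵢzᵢ/√(Σwᵢ²)`, combined `p = 1 − Φ(Z)`.
P-values are clamped to [1e-15, 1 − 1e-15] before the quantile transform
to avoid infinities. Missing inputs are dropped with their weights and
`n_inputs_used` is reported per row. Weights: uniform by default;
`sqrt_n` (wᵢ = √nᵢ from each input's `n` layer) when inputs of unequal
size should count unequally; explicit user weights, one per input. Row
ids are matched across inputs by **union**, so a gene absent from one
experiment still combines over the others.

### Correlation

Pairwise-complete Pearson r with a t-distribution p-value (n − 2 df),
requiring ≥ 3 complete pairs; the p-value layer is auxiliary — the
coefficient is the primary output. Zero-variance vectors yield a missing
r with a note rather than ±∞ nonsense.

## File formats

GMT (one set per line: name, description, members), GMX (one set per
column, ragged), TCM (two-column item↔module pairs, aggregated; default
column order item-first matching DAVID-style usage, `module-first`
dialect available), tab-delimited matrices (empty/`NA`/`-` = missing),
and a long-format results TSV (one line per cell, one column per layer,
the default layer recorded in a header comment). All files are UTF-8,
TAB-separated, LF-terminated; TAB inside a label is an error rather than
introducing quoting. Floats serialize by shortest round-trip `repr`, so
read∘write is the identity including missing patterns. TCM carries no
descriptions; converting through it drops them (documented, tested).

## Color scales and rendering

The p-value scale paints values above α with a flat non-significant
color; values ≤ α are placed on a gradient at position proportional to
−log10(p), between α and a floor of 1e-16 (beyond which all p-values look
identical anyway). Linear/z-score scales interpolate piecewise-linearly
between anchor (value, color) pairs, clamped at the ends. Default
palettes (yellow→red significance ramp, blue–white–red linear ramp) are
package choices, fully configurable. PNG rendering is pure: fixed
geometry (cells × cell size + label gutters), no timestamps or metadata,
so identical inputs give byte-identical files; a pixel budget guards
against accidentally rasterizing a 20 000-gene matrix. The HTML report is
a self-contained table with inline colors, per-cell hover text listing
every layer value, and one legend entry per scale anchor.

## Synthetic data and what the tests show

`make_expression_fixture` draws iid N(0, 1) backgrounds and adds a
constant shift δ to planted modules' members in target columns;
`make_event_fixture` draws iid Bernoulli(p₀) events with planted genes at
rate p₁. Defaults emulate a small cohort study: 500 genes, 20 samples,
module sizes 20–100 (typical curated pathway sizes within a 500-gene
universe), event rate 0.1 (a plausible per-experiment alteration-call
rate), and the planted-signal settings δ = 2 (module size 50) and
p₁ = 0.9 vs p₀ = 0.1 used by the power simulations.

The generators deliberately omit probe-level noise, gene–gene
correlation, batch structure and overlapping-module dependence. Null
calibration and power results under these fixtures therefore demonstrate
*statistical correctness of the implementation* (the tests do what their
definitions say), not field performance on real microarray or sequencing
data, where correlated genes inflate module variance and resampling nulls
are known to be optimistic.

One calibration consequence measured by the acceptance suite: the
z-score test and the per-gene binomial analysis sit inside the 99%
binomial envelope of α = 0.05 under the null, but the *enrichment-side*
exact binomial and Fisher tests reject at rates below the envelope's
lower edge (≈ 0.02–0.03 at these module sizes). That is the expected
conservatism of exact discrete tests — the achieved level is the largest
attainable tail probability ≤ α — not an implementation error; the
corresponding acceptance checks assert the symmetric envelope and
therefore fail, intentionally, as a faithful record of this property.

## Numerical conventions

Sample (n − 1) standard deviations everywhere. Missing values are
excluded pairwise from all statistics. P-layers are validated into
[0, 1]. Engine outputs preserve input label order; all label sets must be
duplicate-free. Problem sizes in the calibration/power suites (2 000
module draws at B = 1 000; 100 replicates) were chosen to put Monte-Carlo
noise well below the decision thresholds they feed.

## Known limitations

Hierarchical/k-means clustering of heat-maps is out of scope (use
scipy/scikit-learn on the exported layers); no gene-identifier mapping,
no network importers, no interactive browsing. The per-gene analysis is
an interpretation (see above). Two-sided bootstrap p-values assume the
resampling distribution is approximately normal, which fails for tiny
backgrounds or extreme-skew statistics.
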