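"""Module enrichment on a real-valued expression matrix.

Builds a synthetic 300-gene x 4-sample matrix in which one module of 40
genes is shifted upward by 2 standard deviations, runs the z-score
resampling enrichment test per sample, and prints the top modules.
"""

import heatmod as hm

spec = hm.FixtureSpec(seed=11, n_genes=300, n_samples=4, n_modules=8,
                      module_size_min=20, module_size_max=40,
                      shift_delta=2.0, n_planted=1)
matrix, modules, truth = hm.make_expression_fixture(spec)
print(f"matrix: {matrix.shape[0]} genes x {matrix.shape[1]} samples; "
      f"{len(modules)} modules; planted: {truth['planted_modules']}")

cfg = hm.TestConfig(test_kind="zscore_bootstrap", statistic="mean",
                    bootstrap_iterations=2000, seed=7, mtc="bh")
result = hm.run_enrichment(matrix, modules, cfg)

col = "s1"
table = result.layer("p_right")[col].sort_values()
print(f"\nmodules ranked by right-tail p in sample {col}:")
for mod in table.index[:4]:
    cell = result.cell(mod, col)
    print(f"  {mod:8s} z={cell['z']:+7.2f}  p_right={cell['p_right']:.3g}  "
          f"BH-corrected={cell['p_right_corrected']:.3g}")

# A large positive z means the module's mean expression sits far above what
# random same-size gene sets achieve in that sample; the planted module
# should dominate while the null modules hover near p ~ 0.5.
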