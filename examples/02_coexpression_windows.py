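"""Find co-expressed gene clusters with the sliding-window permutation test.

Plants one cluster of 8 expressed genes inside 500 Kb of a 20 Mb chromosome
with a 2% expressed background, slides a 500 Kb window in 5 Kb steps, and
calls windows whose expressed-gene count exceeds the 0.95 quantile of a
label-shuffling null.
"""

from txfactory.cowindow import CowindowParams, merge_significant, permutation_test
from txfactory.synthetic_data import ExprGenParams, generate_expression_table

params = ExprGenParams(
    n_genes=2000,
    chrom_length_kb=20_000.0,
    planted_clusters=((0, 9_000.0, 500.0, 8),),  # chr1:9.0-9.5 Mb, 8 expressed genes
    background_expressed_rate=0.02,
    seed=5,
)
genes = generate_expression_table(params)
print(f"{len(genes)} genes, {genes['expressed'].sum()} expressed "
      f"(8 planted in one 500 Kb cluster, the rest background)")

results = permutation_test(genes, CowindowParams(seed=7), chrom_length_kb=20_000.0)
n_sig = int(results["significant"].sum())
print(f"{len(results)} windows tested, {n_sig} significant at the 0.95 permutation quantile")

regions = merge_significant(results)
print("merged co-expressed regions (the 'blue line' intervals):")
for r in regions.itertuples():
    print(f"  {r.chrom}:{r.start_kb:.0f}-{r.end_kb:.0f} Kb")
print("  -> the planted 9.0-9.5 Mb cluster is recovered; any other region is a"
      " chance aggregation of background genes at the 5% level")
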