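"""DEG filtering and overlap arithmetic.

Differential-expression tables are thresholded (|log2FC| > 0.5,
lfcSE < 0.5, padj < 0.01, all strict), then compared as exact set
partitions.  The synthetic universe carries the printed set sizes of the
knockout-vs-maturation comparison: 1,739 knockout DEGs, 3,266
maturation-regulated genes, 1,007 shared.
"""

import numpy as np

from metkit.genesets import GeneSet, filter_degs, panel_overlap, venn_partition
from metkit.synthetic import GeneSetSpec, GeneUniverseSpec, simulate_gene_tables

spec = GeneUniverseSpec(
    universe_size=20_000,
    sets=(GeneSetSpec("ko_p30", 1739), GeneSetSpec("maturation", 3266)),
    overlaps={("ko_p30", "maturation"): 1007},
    seed=1,
)
sim = simulate_gene_tables(spec)
ko = filter_degs(sim.tables["ko_p30"], label="ko_p30")
mat = filter_degs(sim.tables["maturation"], label="maturation")

venn = venn_partition(ko.genes, mat.genes)
print(f"knockout-only DEGs:    {venn.only_a}")
print(f"shared DEGs:           {venn.intersection}")
print(f"maturation-only DEGs:  {venn.only_b}")
print(f"share of knockout DEGs also maturation-regulated: "
      f"{venn.pct_of_a.raw:.1f}% (~{venn.pct_of_a.rounded}%)")
print(f"share of maturation DEGs affected in the knockout: "
      f"{venn.pct_of_b.raw:.1f}% (~{venn.pct_of_b.rounded}%)")

# a 64-gene hair-bundle panel with 16 members among the knockout DEGs
rng = np.random.default_rng(2)
in_degs = sorted(sim.truth_sets["ko_p30"])
out_degs = sorted(set(sim.tables["ko_p30"]["gene_id"]) - set(in_degs))
panel = GeneSet.from_iterable(
    "bundle_panel",
    list(rng.choice(in_degs, 16, replace=False))
    + list(rng.choice(out_degs, 48, replace=False)),
)
rep = panel_overlap(panel, ko)
print(f"\nbundle-gene panel: {rep.intersection}/{len(panel)} differentially "
      f"expressed ({rep.pct_of_a.rounded}%), "
      f"{rep.intersection_down} down / {rep.intersection_up} up")
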