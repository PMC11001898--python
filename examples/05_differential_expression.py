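"""Aging DEGs: Welch t-test T5 vs T4 with Benjamini-Hochberg FDR.

Fifty genes carry a planted 2-fold increase in the aging group. Genes are
pre-filtered (detected in >=10% of one group, |log2FC| >= 0.25), tested on
log-normalized values, and BH-adjusted; significant up-regulated genes are
intersected with a disease gene list.
"""

import lungspan as ls
from lungspan.containers import GeneSet

counts, ann, de_genes = ls.simulate_two_group_counts(
    n_genes=2000, n_de=50, log2_fc=1.0, cells_per_group=200, seed=5)
norm = ls.normalize(counts)
deg = ls.deg_t_test(norm, ann, "T5", "T4")

sig = deg[deg.p_adj < 0.05]
hits = sig[sig.gene.isin(de_genes)]
print(f"{len(deg)} genes tested, {len(sig)} significant at FDR 5%, "
      f"{len(hits)}/{len(de_genes)} planted genes recovered")
print(sig.nsmallest(5, "p_adj").round(4).to_string(index=False))

lists = {"disease_list": GeneSet("disease_list", set(de_genes))}
overlap = ls.overlap_disease_genes(deg, lists)
print(overlap[["disease_list", "n_overlap"]].to_string(index=False))
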