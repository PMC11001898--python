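"""Score a gene program per cell with abundance-matched random controls.

SC_j(i) = mean expression of the gene set minus the mean of a control pool
drawn from the same 25 mean-expression bins (100 controls per target
gene). On the planted development-up program the per-group mean score
rises monotonically from T1 to T5.
"""

import pandas as pd

import lungspan as ls
from lungspan.containers import GeneSet

cfg = ls.SimulationConfig(
    n_genes=800, cells_per_group={g: 100 for g in ls.GROUPS}, seed=3)
counts, ann, truth = ls.simulate_dataset(cfg)
counts, ann, _ = ls.qc_filter(counts, ann)
norm = ls.normalize(counts)

genes = {g for g, p in truth.program_of_gene.items()
         if p == "dev_up" and g in set(norm.genes)}
gs = GeneSet("development_program", genes)
assignment = ls.assign_control_genes(norm, gs, seed=3)
score = ls.module_score(norm, gs, assignment)

frame = pd.DataFrame({"score": score.score,
                      "group": ann.table["group"].astype(str).to_numpy()})
print(frame.groupby("group").score.mean().round(3))
print("-> positive and rising with age group: the planted program is "
      "expressed above abundance-matched background, most strongly in T5")
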