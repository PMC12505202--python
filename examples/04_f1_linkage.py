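"""Two-point linkage on a simulated diploid F1: screen markers, estimate
pairwise recombination fractions, cluster linkage groups, and summarize a
two-point (Haldane) map.
"""

import pandas as pd

from polytag import linkage as lk
from polytag.dosage import fit_f1_model
from polytag.simulate import SimConfig, simulate_f1, simulate_parents

cfg = SimConfig(seed=4, n_loci=840)   # 70 loci on each of 12 chromosomes
markers, parents = simulate_parents(cfg)
counts, truth = simulate_f1(cfg, markers, parents, n_offspring=150)
_, G = fit_f1_model(counts, ("P1", "P2"))

infos, log = lk.screen_f1_markers(G.dosage, ("P1", "P2"))
print(f"screened {len(infos)} usable markers; removed {log.counts()}")

rfm = lk.estimate_rf(G.dosage, infos, ("P1", "P2"))
groups, singletons = lk.cluster_linkage_groups(rfm, n_groups=12)
print(f"{len(groups)} linkage groups, sizes {[len(g) for g in groups]}, "
      f"{len(singletons)} singletons")

mk = pd.DataFrame({"chrom": [m.chrom for m in markers],
                   "pos": [m.pos for m in markers]},
                  index=pd.Index([m.locus_id for m in markers],
                                 name="locus_id"))
summary = lk.map_summary(groups, rfm, mk)
print(summary.round(2).to_string())
print(f"total two-point map length: {summary['length_cM'].sum():.1f} cM "
      "(each simulated chromosome is 100 cM)")
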