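"""Simulate a MADC-style read-count panel and run detection QC.

Generates a diploid cohort on a 12-chromosome panel, applies the <10-read
missingness rule, and computes pooled read-count MAF with the singleton
polymorphism threshold.
"""

from polytag import qc
from polytag.simulate import SimConfig, simulate_cohort
import pandas as pd

cfg = SimConfig(seed=1, n_loci=500)
markers, counts, truth = simulate_cohort(cfg, n_samples=40, ploidy=2)
print(f"simulated {counts.shape[0]} loci x {counts.shape[1]} samples, "
      f"mean depth {counts.total().to_numpy().mean():.1f}")

mask, report = qc.missingness(counts, min_reads=10)
print(f"mean sample-level missing rate: {report.sample_rate.mean():.2%} "
      "(cells with <10 Ref+Alt reads count as missing)")

filtered, log = qc.filter_by_missing(counts)
print(f"removed {len(log.removed_samples)} samples and "
      f"{len(log.removed_markers)} markers at the >=95% missing rule")

maf = qc.maf_from_reads(filtered)
sheet = pd.DataFrame({"sample_id": filtered.samples, "group": "sim",
                      "nominal_ploidy": 2}).set_index("sample_id")
poly, thr = qc.polymorphic_call(maf, sheet)
print(f"singleton threshold 1/G = {float(thr):.4%}; "
      f"{int(poly.sum())}/{len(poly)} markers polymorphic")
print("-> a marker counts as polymorphic when its minor-allele read share "
      "reaches the frequency of one allele copy in the whole panel")
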