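"""Design a fixed-size targeted panel from discovery variants: hard
filters (quality, MAF, missing rate, exact Hardy-Weinberg test) followed
by evenly spaced selection with QTL/genic priority.
"""

import numpy as np
import pandas as pd

from polytag.panel import filter_candidates, hwe_exact_test, select_even

rng = np.random.default_rng(6)
n = 5000
chrom_lengths = {str(c): 40_000_000 for c in range(1, 13)}
cands = pd.DataFrame({
    "chrom": rng.choice(list(chrom_lengths), n),
    "pos": rng.integers(1, 40_000_000, n),
    "quality": rng.uniform(0, 60, n),
    "maf": rng.uniform(0, 0.5, n),
    "missing_rate": rng.uniform(0, 1, n),
    "n_aa": rng.integers(0, 30, n),
    "n_ab": rng.integers(0, 30, n),
    "n_bb": rng.integers(0, 30, n),
    "qtl": rng.random(n) < 0.02,
    "genic": rng.random(n) < 0.3,
}, index=[f"snp{i}" for i in range(n)])

print(f"HWE exact test example: counts (25, 50, 25) -> "
      f"p = {hwe_exact_test(25, 50, 25):.3f} (perfect equilibrium)")

filtered = filter_candidates(cands)
passed = filtered[filtered["pass"]]
print(f"{len(passed)}/{n} candidates pass quality>20, MAF>5%, "
      "missing<75%, HWE p>0.01")

target = 300
sel = select_even(passed, target, chrom_lengths)
per_chrom = sel["chrom"].value_counts().sort_index()
print(f"selected {len(sel)} markers; per-chromosome counts "
      f"{per_chrom.min()}-{per_chrom.max()} "
      "(quotas proportional to chromosome length)")
gaps = sel.groupby("chrom")["pos"].apply(
    lambda p: np.diff(np.sort(p)).max() if len(p) > 1 else 0)
print(f"largest intra-chromosome gap: {gaps.max() / 1e6:.1f} Mbp "
      f"(ideal spacing ~{40_000_000 * 12 / target / 1e6:.1f} Mbp)")
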