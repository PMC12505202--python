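"""Infer sample ploidy from allele-count ratios, including the
colchicine first-generation failure mode.

A natural tetraploid shows three heterozygous ratio classes (0.25, 0.5,
0.75); a first-generation chromosome-doubled plant carries every allele in
duplicate, shows only the diploid classes, and is (correctly per the
method, wrongly per its genome content) called diploid.
"""

from polytag.ploidy import estimate_ploidy
from polytag.simulate import SimConfig, simulate_cohort

for label, ploidy, gen in [("diploid", 2, 0),
                           ("natural tetraploid", 4, 0),
                           ("colchicine gen-1 tetraploid", 4, 1),
                           ("colchicine gen-2 tetraploid", 4, 2)]:
    cfg = SimConfig(seed=10 + gen + ploidy, n_loci=300)
    _, counts, _ = simulate_cohort(cfg, n_samples=20, ploidy=ploidy,
                                   colchicine_gen=gen)
    calls, _ = estimate_ploidy(counts, candidates=(2, 4))
    counts_by_call = calls["call"].value_counts(dropna=False).to_dict()
    print(f"{label:30s} -> calls {counts_by_call}")
print("-> gen-1 doubled tetraploids are called 2: their allele ratios "
      "cluster only at 0/0.5/1, indistinguishable from a diploid")
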