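# polytag

Targeted-amplicon genotyping for mixed-ploidy plant panels.

Mid-density amplicon platforms (DArTag and kin) return, for every sample,
read counts of each *microhaplotype* discovered at a few thousand fixed
81-bp loci — the MADC ("missing allele discovery counts") table. Breeding
programs use these panels on material that mixes diploids, natural and
colchicine-induced tetraploids, interspecific hybrids, and biparental F1
families, as in cultivated cranberry (*Vaccinium macrocarpon*) and its
relatives. `polytag` turns a MADC table into analysis-ready genetics:

* **madc** — parse/write the MADC dialect, reduce microhaplotypes to
  target-SNP Ref/Alt counts, deduplicate target SNPs within 15 bp;
* **qc** — `<10`-read missingness, read-count MAF and the singleton
  polymorphism threshold `1/G` (G = total gametes), PIC, IBS, allele-ratio
  PCA;
* **ploidy** — reference-standardized allele-ratio (BAF) ploidy calls,
  including the documented failure mode where first-generation
  colchicine-doubled tetraploids pass as diploids;
* **dosage** — beta-binomial allele-dosage calling with allele bias,
  overdispersion and sequencing error, under a cohort ("norm") or
  Mendelian F1 prior, plus the standard post-dosage filters;
* **hybrid** — sub-genome classification of loci in wide-cross hybrids
  from parental read totals, with per-class ploidy settings;
* **linkage** — two-point RF/LOD estimation with phase enumeration, marker
  screening, RF-based filtering, ±5-neighbor repositioning, linkage-group
  clustering, and Haldane map summaries;
* **panel** — candidate-SNP hard filters (quality, MAF, missing rate,
  exact HWE test) and evenly spaced panel selection;
* **simulate** — a generator producing MADC-dialect data with full ground
  truth for all of the above.

## The models in brief

**Dosage.** At a locus of ploidy *m*, a sample with dosage *d* yields alt
reads `alt ~ BetaBinomial(depth, ξ(d), ρ)` with

```
ξ₀(d) = (d/m)(1−ε) + (1−d/m)ε,     ξ(d) = ξ₀ / (h(1−ξ₀) + ξ₀)
```

where *h* is allele bias, *ε* sequencing error and *ρ* overdispersion.
Marker-wise EM over the latent dosages maximizes the marginal likelihood;
genotypes are posterior modes. Markers are kept when `0.05 < h < 2`,
`prop_mis < 0.1` and `ρ < 0.05`.

**Ploidy.** Allele-count ratios are standardized against reference
samples of known dosage, then each candidate ploidy *m* is scored by a
fixed-mean Gaussian mixture on its interior peaks `k/m` (k = 1..m−1),
compared across candidates by per-marker BIC — the decision surface is
the number of heterozygous ratio classes.

**Informativeness.** `PIC = 1 − Σpᵢ² − ΣΣ 2pᵢ²pⱼ²` (maximum 0.375 for a
biallelic SNP); IBS is the share of identical dosages over mutually
observed loci.

**Linkage.** Two-point recombination fractions are maximum-likelihood
estimates over the admissible phase configurations of each marker pair's
cross types (ab×aa, aa×ab, ab×ab); `LOD = log₁₀ L(r̂)/L(0.5)`; map
distances use Haldane's `d = −50 ln(1−2r)`.

## Worked example

```bash
python examples/04_f1_linkage.py
```

```
screened 469 usable markers; removed {'monomorphic': 354, 'unexpected': 16, 'redundant': 0, 'high_missing': 0, 'distorted': 1}
12 linkage groups, sizes [44, 43, 43, 42, 42, 42, 41, 37, 36, 35, 34, 29], 1 singletons
...
total two-point map length: 1102.7 cM (each simulated chromosome is 100 cM)
```

A simulated F1 of 150 offspring on a 12×100 cM genome is dosage-called,
screened (markers monomorphic in the cross, impossible under the parents,
redundant, high-missing, or segregation-distorted are logged and removed),
and clustered into 12 linkage groups that are each pure for one true
chromosome; the two-point map totals ~1100 cM against the true 1200 cM.
The other `examples/*.py` scripts cover QC, ploidy inference (including
the colchicine gen-1 misclassification), dosage calling, hybrid
classification and panel design, each printing the numbers it computes
and what they mean.

A thin CLI wraps the same functions: `polytag simulate|qc|ploidy|dosage|
pic|ibs|classify-hybrid|rf|reposition|map|design-panel|run`.

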