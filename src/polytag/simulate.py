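"""Synthetic MADC-style read-count data with full ground truth.

The generator reproduces the statistical structure the downstream analysis
assumes: a 12-chromosome panel of target SNPs, negative-binomial per-cell
read depth, beta-binomial allele counts with per-locus allele bias and
sequencing error, mixed-ploidy cohorts (including first- and
second-generation colchicine-doubled tetraploids), diploid F1 crosses with
Haldane (no-interference) crossovers, and two-sub-genome hybrids whose loci
amplify from one, both, or neither parental genome.

All randomness flows from ``SimConfig.seed`` through a ``SeedSequence``;
each public operation draws from its own spawned stream, so cohorts, F1
families, and hybrid panels generated from one config are mutually
independent yet fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._model import expected_alt_fraction, haldane_r, sample_alt_reads
from .madc import CountMatrix, MarkerDef

_STREAMS = {"panel": 0, "cohort": 1, "f1": 2, "hybrid": 3, "parents": 4}


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the validated panel: 12 chromosomes, ~41 Mbp each
    (a ~492 Mbp genome), ~100 cM per chromosome, 3059 target loci, mean
    target depth 60 with negative-binomial dispersion (the platform's
    "general depth > 30" regime), modest lognormal allele bias, and small
    overdispersion / sequencing-error rates.
    """

    n_chrom: int = 12
    chrom_len_bp: int = 41_000_000
    chrom_len_cm: float = 100.0
    n_loci: int = 3059
    maf_low: float = 0.05          # founder alt-allele frequency range
    maf_high: float = 0.5
    depth_mean: float = 60.0       # negative-binomial mean per cell
    depth_dispersion: float = 3.0  # NB size parameter k (var = mu + mu^2/k)
    bias_log_sd: float = 0.2       # per-locus allele bias h ~ LogNormal(0, sd)
    rho: float = 0.01              # beta-binomial overdispersion
    eps: float = 0.001             # sequencing error
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if not (0 <= self.eps < 0.5):
            raise ValueError("eps must be in [0, 0.5)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent stream derived from the config seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[_STREAMS[stream]]
        )


@dataclass
class TruthSet:
    """Ground truth accompanying a simulated CountMatrix."""

    dosage: pd.DataFrame                  # loci x samples, integer
    ploidy: pd.Series                     # per sample
    allele_freq: pd.Series | None = None  # founder alt frequency per locus
    bias: pd.Series | None = None         # per-locus allele bias h
    haplotypes: dict = field(default_factory=dict)   # sample -> (2, L) array
    crossovers: pd.Series | None = None   # per F1 gamete, total crossover count
    locus_class: pd.Series | None = None  # hybrid amplification class
    contaminants: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# panel layout


def simulate_panel(cfg: SimConfig, rng=None):
    """Random marker panel: loci spread uniformly over cfg.n_chrom
    chromosomes, plus per-locus founder allele frequency and bias."""
    rng = cfg.rng("panel") if rng is None else rng
    per = np.full(cfg.n_chrom, cfg.n_loci // cfg.n_chrom)
    per[: cfg.n_loci % cfg.n_chrom] += 1
    markers, freqs, biases = [], [], []
    for c in range(cfg.n_chrom):
        pos = np.sort(rng.choice(cfg.chrom_len_bp, size=per[c], replace=False)) + 1
        for j, p in enumerate(pos):
            markers.append(MarkerDef(f"c{c + 1:02d}_{p:09d}", chrom=str(c + 1),
                                     pos=int(p), ref_allele="A", alt_allele="G"))
    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_loci)
    biases = np.exp(rng.normal(0.0, cfg.bias_log_sd, size=cfg.n_loci))
    idx = pd.Index([m.locus_id for m in markers], name="locus_id")
    return markers, pd.Series(freqs, index=idx), pd.Series(biases, index=idx)


def _reads_from_dosage(cfg, rng, dosage, ploidy_per_sample, bias):
    """Depth ~ NegBin, alt ~ BetaBinomial(depth, xi(d), rho) per cell."""
    L, S = dosage.shape
    k, mu = cfg.depth_dispersion, cfg.depth_mean
    depth = rng.negative_binomial(k, k / (k + mu), size=(L, S))
    m = np.broadcast_to(np.asarray(ploidy_per_sample, float), (L, S))
    xi = expected_alt_fraction(dosage, m, h=bias[:, None], eps=cfg.eps)
    alt = sample_alt_reads(rng, depth, xi, cfg.rho)
    return (depth - alt).astype(int), alt.astype(int)


def _pack(markers, ref, alt, sample_ids):
    idx = pd.Index([m.locus_id for m in markers], name="locus_id")
    return CountMatrix(pd.DataFrame(ref, index=idx, columns=sample_ids),
                       pd.DataFrame(alt, index=idx, columns=sample_ids))


def _tetraploid_gamete(rng, dosage4):
    """Tetrasomic gamete dosage: 2 of 4 chromosomes without replacement."""
    return rng.hypergeometric(dosage4, 4 - dosage4, 2)


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(cfg: SimConfig, n_samples: int, ploidy: int,
                    colchicine_gen: int = 0, prefix: str = "S"):
    """Unrelated cohort at a single ploidy.

    colchicine_gen=1 doubles a diploid genotype (dosages 0/2/4 only, so
    allele ratios cluster at 0, 0.5, 1 like a diploid); colchicine_gen=2
    crosses two independent first-generation tetraploids, restoring
    tetrasomic dosage classes.
    """
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    if colchicine_gen and ploidy != 4:
        raise ValueError("colchicine generations only apply to tetraploids")
    if colchicine_gen not in (0, 1, 2):
        raise ValueError("colchicine_gen must be 0, 1 or 2")
    rng = cfg.rng("cohort")
    markers, freq, bias = simulate_panel(cfg, rng)
    p = freq.to_numpy()[:, None]
    if colchicine_gen == 0:
        dosage = rng.binomial(ploidy, p, size=(cfg.n_loci, n_samples))
    elif colchicine_gen == 1:
        dosage = 2 * rng.binomial(2, p, size=(cfg.n_loci, n_samples))
    else:
        d1 = 2 * rng.binomial(2, p, size=(cfg.n_loci, n_samples))
        d2 = 2 * rng.binomial(2, p, size=(cfg.n_loci, n_samples))
        dosage = _tetraploid_gamete(rng, d1) + _tetraploid_gamete(rng, d2)
    ref, alt = _reads_from_dosage(cfg, rng, dosage, ploidy, bias.to_numpy())
    ids = [f"{prefix}{i + 1:03d}" for i in range(n_samples)]
    counts = _pack(markers, ref, alt, ids)
    truth = TruthSet(
        dosage=pd.DataFrame(dosage, index=counts.loci, columns=ids),
        ploidy=pd.Series(ploidy, index=ids),
        allele_freq=freq, bias=bias,
    )
    return markers, counts, truth


# ---------------------------------------------------------------------------
# F1 populations


def simulate_parents(cfg: SimConfig, n_parents: int = 2, prefix: str = "P"):
    """Phased diploid founders for an F1 cross."""
    rng = cfg.rng("parents")
    markers, freq, bias = simulate_panel(cfg, rng)
    ids = [f"{prefix}{i + 1}" for i in range(n_parents)]
    haps = {s: rng.binomial(1, freq.to_numpy(), size=(2, cfg.n_loci)) for s in ids}
    dosage = pd.DataFrame({s: haps[s].sum(axis=0) for s in ids},
                          index=pd.Index([m.locus_id for m in markers],
                                         name="locus_id"))
    truth = TruthSet(dosage=dosage, ploidy=pd.Series(2, index=ids),
                     allele_freq=freq, bias=bias, haplotypes=haps)
    return markers, truth


def _gamete(rng, hap_pair, chrom_of, r_adj):
    """One recombinant gamete from a phased diploid.

    Haldane model: the source haplotype follows a Markov chain along each
    chromosome, switching between adjacent markers with probability
    r = (1 - exp(-2 d_cM / 100)) / 2.  Returns (alleles, n_crossovers).
    """
    L = hap_pair.shape[1]
    state = np.empty(L, dtype=int)
    n_co = 0
    start = True
    for i in range(L):
        if start or chrom_of[i] != chrom_of[i - 1]:
            state[i] = rng.integers(2)
            start = False
        else:
            flip = rng.random() < r_adj[i]
            state[i] = state[i - 1] ^ int(flip)
            n_co += int(flip)
    return hap_pair[state, np.arange(L)], n_co


def simulate_f1(cfg: SimConfig, markers, parent_truth: TruthSet,
                n_offspring: int, n_contaminants: int = 0,
                parent_ids=("P1", "P2"), prefix: str = "F1_"):
    """Diploid F1 family from two phased parents, with optional unrelated
    contaminant samples mimicking pollen contamination.

    Output CountMatrix includes the two parents followed by the offspring;
    TruthSet records crossover counts per gamete and flags contaminants.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    rng = cfg.rng("f1")
    p1, p2 = parent_ids
    chrom_of = np.array([m.chrom for m in markers])
    pos = np.array([m.pos for m in markers], dtype=float)
    d_cm = np.zeros(len(markers))
    same = np.r_[False, chrom_of[1:] == chrom_of[:-1]]
    d_cm[same] = np.diff(pos)[same[1:]] * cfg.chrom_len_cm / cfg.chrom_len_bp
    r_adj = haldane_r(d_cm)

    freq = parent_truth.allele_freq.to_numpy()
    ids = [f"{prefix}{i + 1:03d}" for i in range(n_offspring)]
    cont_ids = ids[n_offspring - n_contaminants:] if n_contaminants else []
    dosages, crossovers = {}, {}
    for s in ids:
        if s in cont_ids:
            dosages[s] = rng.binomial(2, freq)
            crossovers[s] = 0
        else:
            g1, c1 = _gamete(rng, parent_truth.haplotypes[p1], chrom_of, r_adj)
            g2, c2 = _gamete(rng, parent_truth.haplotypes[p2], chrom_of, r_adj)
            dosages[s] = g1 + g2
            crossovers[s] = c1 + c2

    all_ids = [p1, p2] + ids
    dosage = np.column_stack(
        [parent_truth.dosage[p1], parent_truth.dosage[p2]]
        + [dosages[s] for s in ids])
    ref, alt = _reads_from_dosage(cfg, rng, dosage, 2,
                                  parent_truth.bias.to_numpy())
    counts = _pack(markers, ref, alt, all_ids)
    truth = TruthSet(
        dosage=pd.DataFrame(dosage, index=counts.loci, columns=all_ids),
        ploidy=pd.Series(2, index=all_ids),
        allele_freq=parent_truth.allele_freq, bias=parent_truth.bias,
        crossovers=pd.Series(crossovers),
        contaminants=cont_ids,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# interspecific hybrids

HYBRID_CLASSES = ("cran_specific", "blue_specific", "shared", "failed")


def simulate_hybrid(cfg: SimConfig, n_cran_parents: int = 5,
                    n_blue_parents: int = 2, n_offspring: int = 18,
                    class_proportions=(0.75, 0.08, 0.16),
                    noise_threshold: int = 10):
    """Two-sub-genome hybrid panel with locus-level amplification classes.

    Each locus is assigned cran_specific / blue_specific / shared with the
    given proportions (remainder = failed).  Reads are generated only from
    amplifying sub-genome(s); a non-amplifying group's total depth is drawn
    uniformly in [0, noise_threshold // 2] and split across its samples, so
    group sums respect the separated-regime classification rule.  Hybrids
    are tetraploid (a 2-allele gamete from each parental genome).
    """
    if any(p < 0 for p in class_proportions):
        raise ValueError("class proportions must be non-negative")
    if sum(class_proportions) > 1 + 1e-9:
        raise ValueError("class proportions must sum to <= 1")
    rng = cfg.rng("hybrid")
    markers, freq, bias = simulate_panel(cfg, rng)
    L = cfg.n_loci
    probs = list(class_proportions) + [1.0 - sum(class_proportions)]
    cls = rng.choice(4, size=L, p=probs)
    idx = pd.Index([m.locus_id for m in markers], name="locus_id")
    locus_class = pd.Series([HYBRID_CLASSES[c] for c in cls], index=idx)

    cran_ids = [f"CranP{i + 1}" for i in range(n_cran_parents)]
    blue_ids = [f"BlueP{i + 1}" for i in range(n_blue_parents)]
    hyb_ids = [f"Hyb{i + 1:03d}" for i in range(n_offspring)]
    p = freq.to_numpy()[:, None]
    cran_dos = rng.binomial(4, p, size=(L, n_cran_parents))
    blue_dos = rng.binomial(4, p, size=(L, n_blue_parents))
    cran_gam = _tetraploid_gamete(
        rng, cran_dos[:, rng.integers(n_cran_parents, size=n_offspring)])
    blue_gam = _tetraploid_gamete(
        rng, blue_dos[:, rng.integers(n_blue_parents, size=n_offspring)])

    amp_cran = np.isin(cls, [0, 2])[:, None]   # cran_specific or shared
    amp_blue = np.isin(cls, [1, 2])[:, None]
    shared = (cls == 2)[:, None]

    def noise(shape_samples):
        """Group-sum depth <= noise_threshold // 2, split across samples."""
        total = rng.integers(0, noise_threshold // 2 + 1, size=L)
        out = np.zeros((L, shape_samples), dtype=int)
        for i in range(L):
            out[i] = rng.multinomial(total[i], np.full(shape_samples,
                                                       1 / shape_samples))
        return out

    def group_reads(dosage, m, amplifies, ids):
        ref, alt = _reads_from_dosage(cfg, rng, dosage, m, bias.to_numpy())
        tot_noise = noise(len(ids))
        ref = np.where(amplifies, ref, tot_noise)
        alt = np.where(amplifies, alt, 0)
        return ref, alt

    cran_ref, cran_alt = group_reads(cran_dos, 4, amp_cran, cran_ids)
    blue_ref, blue_alt = group_reads(blue_dos, 4, amp_blue, blue_ids)

    # hybrids: amplifying copies only -> effective ploidy 2 (one sub-genome)
    # or 4 (both); failed loci get noise.
    hyb_dos_eff = np.where(shared, cran_gam + blue_gam,
                           np.where(amp_cran, cran_gam,
                                    np.where(amp_blue, blue_gam, 0)))
    hyb_m = np.where(shared, 4, 2)
    hyb_amp = amp_cran | amp_blue
    hyb_ref, hyb_alt = _reads_from_dosage(
        cfg, rng, hyb_dos_eff, np.broadcast_to(hyb_m, (L, n_offspring)),
        bias.to_numpy())
    hyb_noise = noise(n_offspring)
    hyb_ref = np.where(hyb_amp, hyb_ref, hyb_noise)
    hyb_alt = np.where(hyb_amp, hyb_alt, 0)

    all_ids = cran_ids + blue_ids + hyb_ids
    counts = _pack(markers, np.hstack([cran_ref, blue_ref, hyb_ref]),
                   np.hstack([cran_alt, blue_alt, hyb_alt]), all_ids)
    dosage = pd.DataFrame(np.hstack([cran_dos, blue_dos, hyb_dos_eff]),
                          index=idx, columns=all_ids)
    ploidy = pd.Series([4] * len(cran_ids) + [4] * len(blue_ids)
                       + [4] * len(hyb_ids), index=all_ids)
    truth = TruthSet(dosage=dosage, ploidy=ploidy, allele_freq=freq,
                     bias=bias, locus_class=locus_class)
    return markers, counts, truth, {"cran_parents": cran_ids,
                                    "blue_parents": blue_ids,
                                    "hybrids": hyb_ids}
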