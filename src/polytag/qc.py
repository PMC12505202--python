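"""Detection/missingness QC, read-ratio MAF, PIC, IBS and allele-ratio PCA.

Boundary conventions follow the panel-validation rules each statistic comes
from: a genotype cell is *missing* when its Ref+Alt depth is < 10 reads
(so exactly 10 reads is observed); sample- and marker-level filters remove
rates >= 95%; a marker is *polymorphic* when its pooled read-count MAF is
at least the singleton frequency 1/G, where G is the total gamete count
(sum of nominal ploidies) of the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .madc import CountMatrix

DEFAULT_MIN_READS = 10


@dataclass
class MissingnessReport:
    sample_rate: pd.Series     # missing loci / total tested loci
    marker_rate: pd.Series     # missing samples / total samples
    min_reads: int


@dataclass
class RemovalLog:
    """Ordered record of QC removals (samples first, then markers)."""

    removed_samples: list = field(default_factory=list)
    removed_markers: list = field(default_factory=list)
    sample_threshold: float = 0.95
    marker_threshold: float = 0.95

    @property
    def order(self):
        return ("samples", "markers")


def missingness(counts: CountMatrix, min_reads: int = DEFAULT_MIN_READS):
    """Missing mask (True = missing) and per-sample / per-marker rates.

    A cell is missing iff ref + alt < min_reads.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    mask = counts.total() < min_reads
    report = MissingnessReport(
        sample_rate=mask.mean(axis=0),
        marker_rate=mask.mean(axis=1),
        min_reads=min_reads,
    )
    return mask, report


def filter_by_missing(counts: CountMatrix, sample_threshold: float = 0.95,
                      marker_threshold: float = 0.95,
                      min_reads: int = DEFAULT_MIN_READS):
    """Remove high-missing samples, then recompute and remove high-missing
    markers (rates are >= threshold; order matters and is logged)."""
    for t in (sample_threshold, marker_threshold):
        if not (0 < t <= 1):
            raise ValueError("thresholds must be in (0, 1]")
    _, rep = missingness(counts, min_reads)
    bad_samples = rep.sample_rate[rep.sample_rate >= sample_threshold].index.tolist()
    kept = counts.subset(samples=counts.samples[~counts.samples.isin(bad_samples)])
    _, rep2 = missingness(kept, min_reads)
    bad_markers = rep2.marker_rate[rep2.marker_rate >= marker_threshold].index.tolist()
    kept = kept.subset(loci=kept.loci[~kept.loci.isin(bad_markers)])
    log = RemovalLog(bad_samples, bad_markers, sample_threshold, marker_threshold)
    return kept, log


def maf_from_reads(counts: CountMatrix) -> pd.Series:
    """Pooled read-count minor allele frequency per marker:
    min(sum ref, sum alt) / sum(ref + alt) over all samples.  Markers with
    zero total depth are NaN (undefined)."""
    ref = counts.ref.sum(axis=1).astype(float)
    alt = counts.alt.sum(axis=1).astype(float)
    tot = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(ref, alt) / tot
    maf[tot == 0] = np.nan
    return maf.rename("maf")


def singleton_threshold(sheet: pd.DataFrame) -> Fraction:
    """Frequency of a singleton allele: 1 / (total gametes G)."""
    g = int(sheet["nominal_ploidy"].sum())
    if g < 1:
        raise ValueError("empty sample sheet")
    return Fraction(1, g)


def polymorphic_call(maf: pd.Series, sheet: pd.DataFrame):
    """Marker is polymorphic iff MAF >= 1/G (singleton frequency).

    Returns (boolean Series, threshold as an exact Fraction).
    """
    thr = singleton_threshold(sheet)
    calls = maf >= float(thr)
    calls[maf.isna()] = False
    return calls.rename("polymorphic"), thr


# ---------------------------------------------------------------------------
# locus informativeness and sample identity


def pic(freqs) -> float:
    """Polymorphism information content (Botstein):

        PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

    Maximal for a biallelic locus at p = 0.5 (PIC = 0.375).
    """
    p = np.asarray(freqs, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one allele frequency")
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    sq = p ** 2
    cross = (sq.sum() ** 2 - (sq ** 2).sum()) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - sq.sum() - 2.0 * cross)


def allele_freq_from_dosages(dosages, ploidy) -> tuple:
    """Biallelic (p_ref, p_alt) from called dosages: p_alt = sum d / (m n)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no called dosages")
    p_alt = d.sum() / (ploidy * d.size)
    return 1.0 - p_alt, p_alt


def pic_per_marker(genotypes: pd.DataFrame, ploidy) -> pd.Series:
    """PIC from called dosages for every marker with >= 1 call.

    ploidy is a scalar or per-sample Series; frequencies use each sample's
    own copy number in the denominator.
    """
    m = (pd.Series(ploidy, index=genotypes.columns)
         if np.isscalar(ploidy) else pd.Series(ploidy))
    g = genotypes.to_numpy(dtype=float)
    mm = np.broadcast_to(m.to_numpy(dtype=float), g.shape)
    called = ~np.isnan(g)
    denom = (mm * called).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.nansum(g, axis=1) / denom
    out = np.full(len(genotypes), np.nan)
    for i, pa in enumerate(p_alt):
        if denom[i] > 0:
            out[i] = pic([1.0 - pa, pa])
    return pd.Series(out, index=genotypes.index, name="pic")


def ibs(g1, g2):
    """Identity by state between two genotype vectors.

    Returns (proportion of identical dosages, number of loci non-missing in
    both).  Raises ValueError when no locus is comparable.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no loci non-missing in both samples")
    return float((a[ok] == b[ok]).mean()), n


# ---------------------------------------------------------------------------
# allele-ratio PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x PCs
    loadings: pd.DataFrame          # markers x PCs
    variance_explained: np.ndarray  # percent, non-increasing
    dropped_markers: list


def allele_ratio_pca(counts: CountMatrix, n_pc: int = 10,
                     min_reads: int = DEFAULT_MIN_READS) -> PCAResult:
    """PCA on the per-cell Ref-read fraction (Ref / (Ref+Alt)).

    Missing cells (depth < min_reads) are imputed with the marker mean;
    markers observed in no sample are dropped with a warning.  Columns
    (markers) are centered and scores come from an SVD; variance explained
    is each squared singular value's share, in percent.
    """
    tot = counts.total().to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = counts.ref.to_numpy(dtype=float) / tot
    ratio[tot < min_reads] = np.nan
    obs = ~np.isnan(ratio)
    dropped = counts.loci[~obs.any(axis=1)].tolist()
    if dropped:
        warnings.warn(f"{len(dropped)} markers observed in no sample; dropped")
    keep = obs.any(axis=1)
    ratio = ratio[keep]
    X = ratio.T  # samples x markers
    col_mean = np.nanmean(X, axis=0)
    nan_at = np.isnan(X)
    X[nan_at] = np.broadcast_to(col_mean, X.shape)[nan_at]
    X = X - X.mean(axis=0)
    n_pc = min(n_pc, min(X.shape))
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    total = (s ** 2).sum()
    var = 100.0 * (s ** 2) / total if total > 0 else np.zeros_like(s)
    pcs = [f"PC{i + 1}" for i in range(n_pc)]
    return PCAResult(
        scores=pd.DataFrame(u[:, :n_pc] * s[:n_pc], index=counts.samples,
                            columns=pcs),
        loadings=pd.DataFrame(vt[:n_pc].T, index=counts.loci[keep], columns=pcs),
        variance_explained=var[:n_pc],
        dropped_markers=dropped,
    )
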