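"""Ploidy inference from allele-count ratios (B-allele frequencies).

The approach standardizes each marker's raw alt-read fraction against a
set of reference samples with known ploidy and dosages, so that dosage
clusters land on their expected positions d/m regardless of per-marker
allele bias, then scores each candidate ploidy by how well a sample's
heterozygous-band ratios concentrate on the candidate's interior peaks
k/m (k = 1..m-1).  The decision surface is the number of heterozygous
ratio classes: diploids show one interior peak (0.5), natural tetraploids
three (0.25, 0.5, 0.75).

A documented failure mode is reproduced faithfully: first-generation
chromosome-doubled (colchicine) tetraploids carry every allele in duplicate,
their ratios cluster only at 0, 0.5 and 1, and they are classified as
diploid despite tetraploid genome content.  Second-generation material
(after one round of tetrasomic meiosis) recovers odd dosages and is
classified tetraploid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .madc import CountMatrix
from .qc import DEFAULT_MIN_READS

DEFAULT_CANDIDATES = (2, 4)
DEFAULT_HET_BAND = (0.1, 0.9)
MIN_HET_MARKERS = 50        # below this a sample's call is undetermined
SIGMA_FLOOR = 0.01          # minimum mixture component spread
SIGMA_INIT = 0.05


@dataclass
class RatioMatrix:
    """Per-sample, per-marker alt-read fraction with an observed mask."""

    baf: pd.DataFrame       # loci x samples, NaN where unobserved
    observed: pd.DataFrame  # boolean


def compute_baf(counts: CountMatrix,
                min_reads: int = DEFAULT_MIN_READS) -> RatioMatrix:
    """Alt/(Ref+Alt) wherever depth >= min_reads."""
    frac = counts.alt_fraction(min_reads=min_reads)
    return RatioMatrix(baf=frac, observed=~frac.isna())


def standardize_baf(ratios: RatioMatrix, ref_dosages: pd.DataFrame,
                    ref_ploidy: int, min_cluster: int = 3,
                    min_clusters: int = 2):
    """Map raw ratios onto the expected dosage grid using reference samples.

    For each marker, reference samples are grouped by their known dosage;
    every dosage class with >= min_cluster observed samples contributes an
    anchor (observed cluster mean -> expected position d/ref_ploidy).  A
    marker needs >= min_clusters anchors, else it is excluded and logged.
    The piecewise-linear transform through the anchors (pinned at (0,0) and
    (1,1)) is applied to all samples.

    Returns (standardized RatioMatrix restricted to usable markers,
    list of skipped marker ids).
    """
    common = [s for s in ref_dosages.columns if s in ratios.baf.columns]
    if not common:
        raise ValueError("no reference samples present in the ratio matrix")
    baf = ratios.baf.to_numpy(dtype=float)
    ref_baf = ratios.baf[common].to_numpy(dtype=float)
    ref_dos = ref_dosages.reindex(index=ratios.baf.index)[common].to_numpy(
        dtype=float)
    out = np.full_like(baf, np.nan)
    usable = np.zeros(baf.shape[0], dtype=bool)
    skipped = []
    for i in range(baf.shape[0]):
        ok = ~np.isnan(ref_baf[i]) & ~np.isnan(ref_dos[i])
        anchors = []
        for d in np.unique(ref_dos[i, ok]):
            sel = ok & (ref_dos[i] == d)
            if sel.sum() >= min_cluster:
                anchors.append((float(ref_baf[i, sel].mean()),
                                float(d) / ref_ploidy))
        if len(anchors) < min_clusters:
            skipped.append(ratios.baf.index[i])
            continue
        anchors.sort()
        xs = [a[0] for a in anchors]
        ys = [a[1] for a in anchors]
        if xs[0] > 0.0:
            xs, ys = [0.0] + xs, [0.0] + ys
        if xs[-1] < 1.0:
            xs, ys = xs + [1.0], ys + [1.0]
        out[i] = np.interp(baf[i], xs, ys)
        usable[i] = True
    if not usable.any():
        raise ValueError("no marker passed the standardization precondition")
    idx = ratios.baf.index[usable]
    std = pd.DataFrame(out[usable], index=idx, columns=ratios.baf.columns)
    return RatioMatrix(baf=std, observed=~std.isna()), skipped


@dataclass
class PloidyCall:
    sample_id: str
    scores: dict            # candidate -> score (lower is better)
    call: int | None        # argmin, None when undetermined
    margin: float           # second best - best
    n_markers: int


def _score_candidate(vals: np.ndarray, m: int, het_band,
                     sigma_init: float = SIGMA_INIT, n_iter: int = 200,
                     tol: float = 1e-9) -> float:
    """Per-marker BIC of a fixed-mean Gaussian mixture on the candidate's
    interior peaks k/m inside the heterozygous band.

    Component means are pinned at the expected dosage-ratio peaks; mixture
    weights and a common spread sigma are fitted by EM.  The BIC penalty
    (one free weight per extra peak, plus sigma) is what lets a diploid-like
    ratio profile reject the tetraploid candidate even though its peak set
    nests the diploid's.  Lower score = better fit.
    """
    peaks = np.arange(1, m) / m
    peaks = peaks[(peaks > het_band[0]) & (peaks < het_band[1])]
    k = peaks.size
    if k == 0 or vals.size == 0:
        return np.inf
    # k peak components + one uniform background over the band, which
    # absorbs stray ratios so extra peaks are not rewarded for outliers
    log_unif = -np.log(het_band[1] - het_band[0])
    w = np.full(k + 1, 1.0 / (k + 1))
    sigma = sigma_init
    ll_old = -np.inf
    n = vals.size
    for _ in range(n_iter):
        logpdf = np.empty((n, k + 1))
        logpdf[:, :k] = (np.log(w[:k])[None, :]
                         - 0.5 * ((vals[:, None] - peaks[None, :]) / sigma) ** 2
                         - np.log(sigma) - 0.5 * np.log(2 * np.pi))
        logpdf[:, k] = np.log(w[k]) + log_unif
        row_max = logpdf.max(axis=1, keepdims=True)
        lse = row_max[:, 0] + np.log(np.exp(logpdf - row_max).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logpdf - lse[:, None])
        w = np.maximum(resp.mean(axis=0), 1e-9)
        w /= w.sum()
        peak_mass = resp[:, :k].sum()
        if peak_mass > 0:
            sigma = float(np.sqrt(
                (resp[:, :k] * (vals[:, None] - peaks[None, :]) ** 2).sum()
                / peak_mass))
        sigma = min(max(sigma, SIGMA_FLOOR), 0.5)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    df = k + 1  # k free weights (incl. background) + sigma
    return float((-2.0 * ll + df * np.log(n)) / n)


def call_ploidy(std: RatioMatrix, candidates=DEFAULT_CANDIDATES,
                het_band=DEFAULT_HET_BAND,
                min_markers: int = MIN_HET_MARKERS) -> pd.DataFrame:
    """Score every candidate ploidy per sample; call = argmin.

    Only standardized ratios inside het_band are used (homozygous ratios
    carry no copy-number signal).  Samples with fewer than min_markers
    usable ratios are left undetermined (call <NA>).  Scores are
    per-marker averages, hence invariant to marker order.
    """
    candidates = sorted(set(int(c) for c in candidates))
    rows = []
    for s in std.baf.columns:
        vals = std.baf[s].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        vals = vals[(vals > het_band[0]) & (vals < het_band[1])]
        scores = {m: _score_candidate(vals, m, het_band)
                  for m in candidates}
        if vals.size < min_markers:
            rows.append({"sample_id": s, "call": pd.NA, "margin": np.nan,
                         "n_markers": int(vals.size),
                         **{f"score_{m}": scores[m] for m in candidates}})
            continue
        ranked = sorted(scores, key=lambda m: scores[m])
        best = ranked[0]
        margin = (scores[ranked[1]] - scores[best]) if len(ranked) > 1 else np.nan
        rows.append({"sample_id": s, "call": best, "margin": margin,
                     "n_markers": int(vals.size),
                     **{f"score_{m}": scores[m] for m in candidates}})
    return pd.DataFrame(rows).set_index("sample_id")


def estimate_ploidy(counts: CountMatrix, candidates=DEFAULT_CANDIDATES,
                    min_reads: int = DEFAULT_MIN_READS,
                    min_diploid_refs: int = 10, seed: int = 0,
                    **call_kwargs):
    """Two-pass ploidy estimation for a cohort of unknown samples.

    Pass 1 scores the raw allele-count ratios of every sample (the
    peak-mixture spread absorbs moderate allele bias, so no reference is
    needed yet).  Pass 2 genotypes the pass-1-confirmed diploids under the
    "norm" model at m = 2, standardizes every sample's ratios against those
    reference dosage clusters, and re-calls.  When fewer than
    min_diploid_refs diploids are confirmed (e.g. a purely tetraploid
    cohort) the pass-1 calls stand, with a warning.

    Returns (final call DataFrame, pass-1 call DataFrame).
    """
    from .dosage import fit_norm_model

    ratios = compute_baf(counts, min_reads=min_reads)
    pass1 = call_ploidy(ratios, candidates=candidates, **call_kwargs)
    diploids = pass1.index[pass1["call"] == 2].tolist()
    if len(diploids) < min_diploid_refs:
        warnings.warn("too few confirmed diploids for pass 2; "
                      "returning pass-1 calls")
        return pass1, pass1
    _, G2 = fit_norm_model(counts.subset(samples=diploids), m=2,
                           min_reads=min_reads, seed=seed)
    std2, _ = standardize_baf(ratios, G2.dosage, ref_ploidy=2)
    pass2 = call_ploidy(std2, candidates=candidates, **call_kwargs)
    return pass2, pass1
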