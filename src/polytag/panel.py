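"""Candidate-SNP filtering and evenly spaced panel selection.

A discovery set of candidate variants is reduced to a fixed-size targeted
panel in two steps.  First, hard filters: quality score > 20, minor allele
frequency > 5%, missing rate < 75%, and a non-significant exact
Hardy-Weinberg equilibrium test at p = 0.01.  Second, even genomic
distribution: each chromosome receives a quota proportional to its length,
the chromosome is cut into quota-many equal bins, and the best variant per
bin is chosen by priority (QTL-associated flag, then genic flag, then
highest MAF).  Empty bins are backfilled by repeatedly adding the
candidate that most reduces the chromosome's largest inter-marker gap.
A user-supplied mandatory list (e.g. trait-associated markers) is always
included and counted against quotas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

QUALITY_MIN = 20.0
MAF_MIN = 0.05
MISSING_MAX = 0.75
HWE_ALPHA = 0.01


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test for a biallelic variant.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (two-sided by probability ordering).  Returns 1.0 for monomorphic data.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_aa + n_ab        # rare-or-not does not matter: symmetric
    n_b = 2 * n_bb + n_ab
    minor = min(n_a, n_b)
    if minor == 0:
        return 1.0
    # possible heterozygote counts share the parity of the minor allele count
    hets = np.arange(minor % 2, minor + 1, 2)
    n_aa_h = (n_a - hets) // 2
    n_bb_h = (n_b - hets) // 2
    logp = (hets * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(n_aa_h + 1) - gammaln(hets + 1) - gammaln(n_bb_h + 1)
            + gammaln(n_a + 1) + gammaln(n_b + 1)
            - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[np.where(hets == n_ab)[0][0]]
    return float(p[p <= p_obs * (1 + 1e-12)].sum())


def filter_candidates(variants: pd.DataFrame) -> pd.DataFrame:
    """Apply the four hard filters; per-rule verdicts are retained.

    Expects columns quality, maf, missing_rate, and either hwe_p or the
    genotype counts n_aa/n_ab/n_bb (from which the exact test is run).
    Returns a copy with boolean columns quality_ok, maf_ok, missing_ok,
    hwe_ok and the conjunction in column pass.
    """
    df = variants.copy()
    if "hwe_p" not in df.columns:
        df["hwe_p"] = [hwe_exact_test(r.n_aa, r.n_ab, r.n_bb)
                       for r in df.itertuples()]
    df["quality_ok"] = df["quality"] > QUALITY_MIN
    df["maf_ok"] = df["maf"] > MAF_MIN
    df["missing_ok"] = df["missing_rate"] < MISSING_MAX
    df["hwe_ok"] = df["hwe_p"] > HWE_ALPHA
    df["pass"] = df[["quality_ok", "maf_ok", "missing_ok", "hwe_ok"]].all(axis=1)
    return df


def _max_gap(positions: np.ndarray, length: int) -> float:
    pts = np.sort(np.concatenate([[0], positions, [length]]))
    return float(np.diff(pts).max())


def select_even(passed: pd.DataFrame, target_n: int, chrom_lengths: dict,
                mandatory=(), priority=("qtl", "genic", "maf")) -> pd.DataFrame:
    """Pick target_n variants with even genomic spacing.

    ``passed`` needs columns chrom, pos, maf and boolean qtl / genic flags,
    indexed by variant id.  Selection is deterministic for fixed input;
    each selected variant records its chromosome, bin and selection reason
    (priority pick, gap backfill, or mandatory).
    """
    if target_n > len(passed):
        raise ValueError("target_n exceeds the number of passing variants")
    passed = passed.copy()
    for flag in ("qtl", "genic"):
        if flag not in passed.columns:
            passed[flag] = False
    mandatory = [m for m in mandatory]
    unknown = [m for m in mandatory if m not in passed.index]
    if unknown:
        raise ValueError(f"mandatory variants not in candidate set: {unknown}")

    lengths = pd.Series(chrom_lengths, dtype=float)
    quota = (lengths / lengths.sum() * target_n)
    base = np.floor(quota).astype(int)
    rem = target_n - base.sum()
    order = (quota - base).sort_values(ascending=False).index
    for c in order[:rem]:
        base[c] += 1

    chosen = {}
    for chrom, q in base.items():
        if q <= 0:
            continue
        sub = passed[passed["chrom"] == chrom]
        length = int(lengths[chrom])
        edges = np.linspace(0, length, q + 1)
        bins = np.clip(np.searchsorted(edges, sub["pos"], side="right") - 1,
                       0, q - 1)
        sub = sub.assign(_bin=bins)
        picked = []
        mand_here = [m for m in mandatory if m in sub.index]
        for m in mand_here:
            picked.append((m, int(sub.loc[m, "_bin"]), "mandatory"))
        taken_bins = {b for _, b, _ in picked}
        for b in range(q):
            if b in taken_bins:
                continue
            cands = sub[(sub["_bin"] == b) & ~sub.index.isin(
                [m for m, _, _ in picked])]
            if cands.empty:
                continue
            ranked = cands.sort_values(
                by=[c for c in priority if c != "maf"] + ["maf"],
                ascending=[False] * (len(priority) - 1) + [False],
                kind="mergesort")
            picked.append((ranked.index[0], b, "priority"))
        # backfill: close the largest remaining gaps
        while len(picked) < q:
            ids = [m for m, _, _ in picked]
            pool = sub[~sub.index.isin(ids)]
            if pool.empty:
                break
            pos_sel = sub.loc[ids, "pos"].to_numpy()
            best_id, best_gap = None, np.inf
            for vid, vpos in pool["pos"].items():
                g = _max_gap(np.append(pos_sel, vpos), length)
                if g < best_gap - 1e-9:
                    best_gap, best_id = g, vid
            picked.append((best_id, int(sub.loc[best_id, "_bin"]), "backfill"))
        for m, b, why in picked:
            chosen[m] = (chrom, b, why)

    for m in mandatory:      # mandatory on chromosomes with zero quota
        if m not in chosen:
            chosen[m] = (passed.loc[m, "chrom"], -1, "mandatory")

    out = passed.loc[list(chosen)].copy()
    out["bin"] = [chosen[m][1] for m in out.index]
    out["selection_reason"] = [chosen[m][2] for m in out.index]
    return out.sort_values(["chrom", "pos"])
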