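"""Two-point linkage utilities for diploid outcrossing F1 populations.

Markers segregate by cross type — ab×aa (only parent 1 heterozygous),
aa×ab, or ab×ab — and pairwise recombination fractions are estimated by
maximum likelihood over the discrete linkage-phase configurations
admissible for each pair's cross types.  Offspring genotypes are first
reduced by subtracting the homozygous parents' fixed contributions, after
which the joint genotype table of a pair depends only on which parents are
doubly heterozygous and on their phases; this lets all pairs of the same
configuration share one likelihood surface and be maximized on a common
r-grid in a handful of matrix products.

Pairs informative through different parents only (ab×aa against aa×ab)
carry no two-point information in a diploid F1 and are reported as
unavailable (r = NaN, LOD = 0).

Downstream utilities implement the map-cleaning heuristics used with
reference-ordered panels: an RF-based linkage filter, detachment and
reassignment of markers showing weak linkage (RF > 0.4) to any of their
±5 physical neighbors and strong linkage (RF < 0.1) to exactly one other
chromosome, linkage-group clustering by connected components, and a
two-point (Haldane) map summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._model import haldane_cm
from .dosage import f1_prior

CROSS_TYPES = ("ab×aa", "aa×ab", "ab×ab", "uninformative", "unexpected")

_ERR_MIX = 1e-3     # genotyping-error mass mixed into the pair table
_R_GRID = np.linspace(0.0, 0.5, 251)


@dataclass
class F1MarkerInfo:
    marker_id: str
    p1: int
    p2: int
    cross_type: str
    expected: np.ndarray    # offspring dosage distribution over 0..2


def classify_cross(p1, p2) -> str:
    if np.isnan(p1) or np.isnan(p2):
        return "unexpected"
    p1, p2 = int(p1), int(p2)
    if p1 == 1 and p2 == 1:
        return "ab×ab"
    if p1 == 1:
        return "ab×aa"
    if p2 == 1:
        return "aa×ab"
    if p1 == p2:
        return "uninformative"
    return "unexpected"


@dataclass
class ScreenLog:
    """Removal counts per stage, in the order applied."""

    monomorphic: list = field(default_factory=list)
    unexpected: list = field(default_factory=list)
    redundant: dict = field(default_factory=dict)   # removed -> representative
    high_missing: list = field(default_factory=list)
    distorted: list = field(default_factory=list)
    n_tested_segregation: int = 0

    def counts(self) -> dict:
        return {"monomorphic": len(self.monomorphic),
                "unexpected": len(self.unexpected),
                "redundant": len(self.redundant),
                "high_missing": len(self.high_missing),
                "distorted": len(self.distorted)}


def screen_f1_markers(genotypes: pd.DataFrame, parents,
                      max_missing: float = 0.10, alpha: float = 0.05):
    """Screen diploid F1 markers before RF estimation.

    ``genotypes`` is a loci x samples dosage DataFrame (NaN = missing)
    containing both parents.  Removal stages, applied in order and logged:
    (1) monomorphic in offspring; (2) markers uninformative or impossible
    given the parents (both parents homozygous, unexpected aa×bb patterns,
    or observed offspring classes of zero Mendelian probability);
    (3) redundant markers (identical offspring genotype vectors; the first
    is kept as representative); (4) > max_missing offspring missing;
    (5) segregation chi-square against the Mendelian expectation at
    Bonferroni-adjusted p <= alpha, with the number of markers tested at
    this stage as the correction divisor.

    Returns (list of F1MarkerInfo for kept markers, ScreenLog).
    """
    p1, p2 = parents
    for p in (p1, p2):
        if p not in genotypes.columns:
            raise ValueError(f"parent {p} absent from genotype matrix")
    off_cols = [c for c in genotypes.columns if c not in (p1, p2)]
    off = genotypes[off_cols]
    log = ScreenLog()
    surviving = []

    for marker_id, row in off.iterrows():
        vals = row.dropna()
        if vals.nunique() < 2:
            log.monomorphic.append(marker_id)
            continue
        surviving.append(marker_id)

    kept2 = []
    infos = {}
    for marker_id in surviving:
        d1, d2 = genotypes.loc[marker_id, p1], genotypes.loc[marker_id, p2]
        ct = classify_cross(d1, d2)
        if ct in ("uninformative", "unexpected"):
            log.unexpected.append(marker_id)
            continue
        expected = f1_prior(int(d1), int(d2))
        observed = off.loc[marker_id].dropna().astype(int)
        if any(expected[g] < 1e-9 for g in observed.unique()):
            log.unexpected.append(marker_id)
            continue
        infos[marker_id] = F1MarkerInfo(marker_id, int(d1), int(d2), ct,
                                        expected)
        kept2.append(marker_id)

    seen = {}
    kept3 = []
    for marker_id in kept2:
        key = tuple(off.loc[marker_id].fillna(-1).astype(int))
        if key in seen:
            log.redundant[marker_id] = seen[key]
        else:
            seen[key] = marker_id
            kept3.append(marker_id)

    kept4 = []
    for marker_id in kept3:
        if off.loc[marker_id].isna().mean() > max_missing:
            log.high_missing.append(marker_id)
        else:
            kept4.append(marker_id)

    log.n_tested_segregation = len(kept4)
    kept5 = []
    for marker_id in kept4:
        p = segregation_test(off.loc[marker_id], infos[marker_id].expected)
        if min(1.0, p * log.n_tested_segregation) <= alpha:
            log.distorted.append(marker_id)
        else:
            kept5.append(marker_id)
    return [infos[m] for m in kept5], log


def segregation_test(offspring: pd.Series, expected: np.ndarray) -> float:
    """Chi-square goodness of fit of offspring dosages to the Mendelian
    class probabilities (classes with zero probability excluded)."""
    obs = offspring.dropna().astype(int)
    classes = np.where(expected > 1e-9)[0]
    counts = np.array([(obs == c).sum() for c in classes], dtype=float)
    probs = expected[classes] / expected[classes].sum()
    if counts.sum() == 0:
        return 1.0
    stat, p = stats.chisquare(counts, f_exp=probs * counts.sum())
    return float(p)


# ---------------------------------------------------------------------------
# pairwise recombination fractions


@dataclass
class RFMatrix:
    ids: pd.Index
    r: np.ndarray          # symmetric, NaN where unavailable
    lod: np.ndarray
    phase: np.ndarray      # phase code of the ML configuration (int8)
    n: np.ndarray          # jointly observed offspring per pair

    def to_long(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.ids), k=1)
        return pd.DataFrame({
            "marker_i": self.ids[iu[0]], "marker_j": self.ids[iu[1]],
            "r": self.r[iu], "lod": self.lod[iu],
            "phase": self.phase[iu], "n": self.n[iu]})

    def frame(self, which="r") -> pd.DataFrame:
        return pd.DataFrame(getattr(self, which), index=self.ids,
                            columns=self.ids)


def _parent_pair_dist(pattern: str, r: np.ndarray, phase: int) -> np.ndarray:
    """Gamete-contribution distribution of one parent over allele pairs
    (aA, aB) in {0,1}^2, shape (len(r), 2, 2)."""
    G = len(r)
    out = np.zeros((G, 2, 2))
    if pattern == "both":
        par, rec = (1.0 - r) / 2.0, r / 2.0
        if phase == 0:     # coupling
            out[:, 0, 0] = out[:, 1, 1] = par
            out[:, 0, 1] = out[:, 1, 0] = rec
        else:              # repulsion
            out[:, 0, 1] = out[:, 1, 0] = par
            out[:, 0, 0] = out[:, 1, 1] = rec
    elif pattern == "A":
        out[:, 0, 0] = out[:, 1, 0] = 0.5
    elif pattern == "B":
        out[:, 0, 0] = out[:, 0, 1] = 0.5
    else:
        out[:, 0, 0] = 1.0
    return out


def _pair_table(pat1: str, pat2: str, phase1: int, phase2: int,
                r: np.ndarray) -> np.ndarray:
    """Joint reduced-genotype table T[g, gA, gB] over (0..2)^2 for each r."""
    m1 = _parent_pair_dist(pat1, r, phase1)
    m2 = _parent_pair_dist(pat2, r, phase2)
    T = np.zeros((len(r), 3, 3))
    for a1 in range(2):
        for b1 in range(2):
            for a2 in range(2):
                for b2 in range(2):
                    T[:, a1 + a2, b1 + b2] += m1[:, a1, b1] * m2[:, a2, b2]
    return (1.0 - _ERR_MIX) * T + _ERR_MIX / 9.0


def estimate_rf(genotypes: pd.DataFrame, infos, parents,
                min_overlap: int = 10, grid: np.ndarray = _R_GRID,
                chunk: int = 40000) -> RFMatrix:
    """ML two-point RF and LOD for every screened marker pair.

    ``genotypes`` holds offspring and parent dosages; ``infos`` is the
    screened F1MarkerInfo list.  Likelihoods are maximized on a 251-point
    r-grid in [0, 0.5] (0.002 resolution) per admissible phase
    configuration; the phase with the highest likelihood wins, ties broken
    toward the smaller r.  LOD = log10 L(r_hat) / L(0.5).  Pairs with fewer
    than min_overlap jointly observed offspring, and pairs with no shared
    doubly heterozygous parent, are unavailable (r NaN, LOD 0).
    """
    p1, p2 = parents
    ids = pd.Index([i.marker_id for i in infos], name="locus_id")
    M = len(ids)
    off_cols = [c for c in genotypes.columns if c not in (p1, p2)]
    O = genotypes.loc[ids, off_cols].to_numpy(dtype=float)

    # subtract fixed contributions of homozygous parents
    het1 = np.array([i.p1 == 1 for i in infos])
    het2 = np.array([i.p2 == 1 for i in infos])
    fixed = (np.array([0 if i.p1 == 1 else i.p1 // 2 for i in infos])
             + np.array([0 if i.p2 == 1 else i.p2 // 2 for i in infos]))
    O = O - fixed[:, None]

    ind = np.stack([(O == g).astype(np.float32) for g in range(3)])  # 3,M,n
    obs = (~np.isnan(O)).astype(np.float32)
    n_joint = (obs @ obs.T).astype(int)

    # 9 pairwise count tables: C[g1, g2, i, j]
    C = np.einsum("gmn,hkn->ghmk", ind, ind, optimize=True)

    r_mat = np.full((M, M), np.nan)
    lod_mat = np.zeros((M, M))
    phase_mat = np.zeros((M, M), dtype=np.int8)

    # per-parent pattern across a pair: both / A only / B only / none
    def pair_pattern(het):
        pat = np.empty((M, M), dtype="<U4")
        pat[np.outer(het, het)] = "both"
        pat[np.outer(het, ~het)] = "A"
        pat[np.outer(~het, het)] = "B"
        pat[np.outer(~het, ~het)] = "none"
        return pat

    pat1 = pair_pattern(het1)
    pat2 = pair_pattern(het2)
    iu = np.triu_indices(M, k=1)
    informative = ((pat1[iu] == "both") | (pat2[iu] == "both")) \
        & (n_joint[iu] >= min_overlap)

    half_idx = int(np.argmin(np.abs(grid - 0.5)))
    key_pairs = np.char.add(np.char.add(pat1[iu], "|"), pat2[iu])
    for key in np.unique(key_pairs[informative]):
        sel = informative & (key_pairs == key)
        if not sel.any():
            continue
        k1, k2 = key.split("|")
        phases1 = (0, 1) if k1 == "both" else (0,)
        phases2 = (0, 1) if k2 == "both" else (0,)
        rows = iu[0][sel]
        cols = iu[1][sel]
        Csel = C[:, :, rows, cols].reshape(9, -1).T.astype(np.float32)  # P,9
        P = Csel.shape[0]
        best_ll = np.full(P, -np.inf, dtype=np.float32)
        best_r = np.full(P, np.nan)
        best_phase = np.zeros(P, dtype=np.int8)
        best_ll_half = np.full(P, -np.inf, dtype=np.float32)
        for ph1 in phases1:
            for ph2 in phases2:
                logT = np.log(_pair_table(k1, k2, ph1, ph2, grid)
                              ).reshape(len(grid), 9).T.astype(np.float32)
                code = np.int8(ph1 * 2 + ph2)
                for s in range(0, P, chunk):
                    ll = Csel[s:s + chunk] @ logT          # chunk x G
                    amax = ll.argmax(axis=1)
                    llmax = ll[np.arange(ll.shape[0]), amax]
                    rhat = grid[amax]
                    llh = ll[:, half_idx]
                    cur = slice(s, min(s + chunk, P))
                    better = (llmax > best_ll[cur] + 1e-6) | (
                        (np.abs(llmax - best_ll[cur]) <= 1e-6)
                        & (rhat < best_r[cur]))
                    best_r[cur] = np.where(better, rhat, best_r[cur])
                    best_phase[cur] = np.where(better, code, best_phase[cur])
                    best_ll[cur] = np.maximum(best_ll[cur], llmax)
                    best_ll_half[cur] = np.maximum(best_ll_half[cur], llh)
        lod = (best_ll - best_ll_half) / np.log(10.0)
        r_mat[rows, cols] = r_mat[cols, rows] = best_r
        lod_mat[rows, cols] = lod_mat[cols, rows] = np.maximum(lod, 0.0)
        phase_mat[rows, cols] = phase_mat[cols, rows] = best_phase

    np.fill_diagonal(r_mat, 0.0)
    np.fill_diagonal(lod_mat, 0.0)
    return RFMatrix(ids=ids, r=r_mat, lod=lod_mat, phase=phase_mat, n=n_joint)


# ---------------------------------------------------------------------------
# RF-based cleaning heuristics


def rf_filter(rf: RFMatrix, chrom_assign: pd.Series, min_linked: int = 2,
              max_regions: int = 3, link_rf: float = 0.3,
              link_lod: float = 3.0) -> list:
    """Remove markers unlikely to be linked anywhere (< min_linked partners
    at r <= link_rf and LOD >= link_lod) or linked across too many
    chromosomes (> max_regions distinct chromosomes among partners)."""
    chroms = chrom_assign.reindex(rf.ids).to_numpy()
    linked = (rf.r <= link_rf) & (rf.lod >= link_lod)
    np.fill_diagonal(linked, False)
    removed = []
    for i, marker_id in enumerate(rf.ids):
        partners = np.where(linked[i])[0]
        if len(partners) < min_linked:
            removed.append(marker_id)
            continue
        if len(set(chroms[partners])) > max_regions:
            removed.append(marker_id)
    return removed


@dataclass
class RepositionResult:
    detached: list
    reassigned: dict        # marker -> new chromosome
    unplaced: list          # detached but not reassigned
    log: pd.DataFrame


def reposition_markers(rf: RFMatrix, markers: pd.DataFrame,
                       weak_rf: float = 0.4, strong_rf: float = 0.1,
                       window: int = 5, rule: str = "any") -> RepositionResult:
    """Detach and reassign markers inconsistent with their reference order.

    A marker is detached from its assigned chromosome when its RF to at
    least one (rule="any"; rule="all" requires every informative neighbor)
    of its ±window physical neighbors exceeds weak_rf.  A detached marker
    with RF < strong_rf to markers on exactly one other chromosome is
    reassigned there, carrying no physical position (linkage-only
    placement); strong links to several chromosomes leave it unplaced.
    ``markers`` needs columns chrom and pos indexed by locus_id.
    """
    markers = markers.loc[rf.ids]
    pos_of = {m: i for i, m in enumerate(rf.ids)}
    detached, reassigned, unplaced, rows = [], {}, [], []
    for chrom, sub in markers.groupby("chrom", sort=False):
        order = sub.sort_values("pos").index.tolist()
        for k, marker_id in enumerate(order):
            neigh = order[max(0, k - window):k] + order[k + 1:k + 1 + window]
            rvals = np.array([rf.r[pos_of[marker_id], pos_of[nb]]
                              for nb in neigh])
            rvals = rvals[~np.isnan(rvals)]
            if rvals.size == 0:
                continue
            weak = (rvals > weak_rf).any() if rule == "any" \
                else (rvals > weak_rf).all()
            if weak:
                detached.append(marker_id)

    det_set = set(detached)
    for marker_id in detached:
        i = pos_of[marker_id]
        own = markers.loc[marker_id, "chrom"]
        strong = [j for j in range(len(rf.ids))
                  if j != i and not np.isnan(rf.r[i, j])
                  and rf.r[i, j] < strong_rf
                  and rf.ids[j] not in det_set
                  and markers.iloc[j]["chrom"] != own]
        target_chroms = sorted({markers.iloc[j]["chrom"] for j in strong})
        if len(target_chroms) == 1:
            reassigned[marker_id] = target_chroms[0]
            rows.append({"marker_id": marker_id, "action": "reassigned",
                         "from": own, "to": target_chroms[0]})
        else:
            unplaced.append(marker_id)
            rows.append({"marker_id": marker_id, "action": "detached",
                         "from": own,
                         "to": ";".join(target_chroms) if target_chroms else ""})
    log = pd.DataFrame(rows, columns=["marker_id", "action", "from", "to"])
    return RepositionResult(detached, reassigned, unplaced, log)


def cluster_linkage_groups(rf: RFMatrix, link_rf: float = 0.25,
                           link_lod: float = 5.0,
                           n_groups: int | None = None,
                           lod_step: float = 0.25, max_lod: float = 30.0):
    """Connected components of the linkage graph (edges where r <= link_rf
    and LOD >= link_lod).  Returns (multi-marker groups sorted by size
    descending, singleton marker ids).

    When the chromosome number is known, pass it as n_groups: if the graph
    yields fewer multi-marker components (a single spurious high-LOD edge
    among the ~M^2/2 tested pairs can bridge two chromosomes), the LOD
    threshold is raised in lod_step increments until the expected count is
    reached, mirroring how mapping tools cluster into a stated group
    number.
    """
    def components(lod_thr):
        adj = (rf.r <= link_rf) & (rf.lod >= lod_thr)
        np.fill_diagonal(adj, False)
        return connected_components(csr_matrix(adj), directed=False), adj

    (n_comp, labels), adj = components(link_lod)
    if n_groups is not None:
        lod_thr = link_lod
        while lod_thr < max_lod:
            sizes = np.bincount(labels)
            if (sizes > 1).sum() >= n_groups:
                break
            lod_thr += lod_step
            (n_comp, labels), adj = components(lod_thr)
    groups, singletons = [], []
    for c in range(n_comp):
        members = [rf.ids[i] for i in np.where(labels == c)[0]]
        if len(members) > 1:
            groups.append(members)
        else:
            singletons.extend(members)
    groups.sort(key=len, reverse=True)
    return groups, singletons


def two_point_map(group, rf: RFMatrix, markers: pd.DataFrame,
                  reassigned: dict | None = None,
                  max_gap_cm: float = 50.0) -> dict:
    """Two-point map summary of one linkage group.

    Markers with a physical position are ordered by it; reassigned markers
    (linkage-only placement) are appended at the end, ordered by their
    strongest-linked partner's position.  Adjacent distances use the
    Haldane map function d = -50 ln(1 - 2r) and an adjacent r of 0.5 caps
    the gap at max_gap_cm and is flagged.  A pair with no two-point
    information (markers informative through different parents) adds no
    length: the chain anchor stays at the last measurable marker and the
    skipped marker is placed at the current position, so the summary
    reflects only measured recombination.
    """
    reassigned = reassigned or {}
    pos_of = {m: i for i, m in enumerate(rf.ids)}
    placed = [m for m in group if m not in reassigned]
    placed.sort(key=lambda m: (str(markers.loc[m, "chrom"]),
                               markers.loc[m, "pos"]))
    floating = [m for m in group if m in reassigned]

    def anchor_pos(m):
        i = pos_of[m]
        partners = [pos_of[p] for p in placed]
        if not partners:
            return 0.0
        rvals = np.array([rf.r[i, j] for j in partners])
        rvals = np.where(np.isnan(rvals), 1.0, rvals)
        best = placed[int(np.argmin(rvals))]
        return markers.loc[best, "pos"]

    floating.sort(key=anchor_pos)
    order = placed + floating

    gaps, flagged, unmeasured = [], [], []
    positions = [0.0]
    cur = 0.0
    anchor = order[0] if order else None
    for b in order[1:]:
        r = rf.r[pos_of[anchor], pos_of[b]]
        if np.isnan(r):
            unmeasured.append(b)
            positions.append(cur)
            continue
        if r >= 0.5 - 1e-9:
            gap = max_gap_cm
            flagged.append((anchor, b))
        else:
            gap = min(float(haldane_cm(r)), max_gap_cm)
        cur += gap
        gaps.append(gap)
        positions.append(cur)
        anchor = b
    length = cur
    return {"order": order,
            "positions_cm": np.asarray(positions),
            "length_cm": length,
            "n_markers": len(order),
            "markers_per_cm": len(order) / length if length > 0 else np.inf,
            "max_gap_cm": float(max(gaps)) if gaps else 0.0,
            "capped_gaps": flagged,
            "unmeasured": unmeasured}


def map_summary(groups, rf: RFMatrix, markers: pd.DataFrame,
                reassigned: dict | None = None) -> pd.DataFrame:
    """Per-group map table: LG, length cM, markers/cM, total markers,
    max gap cM."""
    rows = []
    for g, group in enumerate(groups, start=1):
        res = two_point_map(group, rf, markers, reassigned)
        rows.append({"LG": g, "length_cM": res["length_cm"],
                     "markers_per_cM": res["markers_per_cm"],
                     "total_markers": res["n_markers"],
                     "max_gap_cM": res["max_gap_cm"]})
    return pd.DataFrame(rows).set_index("LG")
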