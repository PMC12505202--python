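import numpy as np
import pandas as pd
import pytest

from polytag import linkage as lk
from polytag._model import haldane_r
from polytag.dosage import fit_f1_model
from polytag.simulate import SimConfig, simulate_f1, simulate_parents


def _testcross_pair(rng, n, r, informative_parent=1):
    """Genotypes of two ab x aa (or aa x ab) markers at recombination
    fraction r, returned as two offspring dosage arrays in {0, 1}."""
    g1 = rng.integers(0, 2, n)
    rec = rng.random(n) < r
    g2 = np.where(rec, 1 - g1, g1)
    return g1, g2


def _frame(marker_rows, parent_dosages, n):
    """Genotype DataFrame with parents P1/P2 followed by offspring."""
    cols = ["P1", "P2"] + [f"o{i}" for i in range(n)]
    data = []
    for row, (p1, p2) in zip(marker_rows, parent_dosages):
        data.append([p1, p2] + list(row))
    idx = pd.Index([f"m{i}" for i in range(len(marker_rows))],
                   name="locus_id")
    return pd.DataFrame(data, index=idx, columns=cols).astype(float)


@pytest.fixture(scope="module")
def f1_panel():
    """Simulated 12-chromosome F1 with called dosages, shared by the
    heavier linkage tests.  70 loci per chromosome leave ~35 informative
    markers each after screening (roughly half are monomorphic in any
    given cross), enough for every adjacent informative pair to stay
    well inside linkage range."""
    cfg = SimConfig(seed=31, n_loci=840)
    markers, pt = simulate_parents(cfg)
    counts, truth = simulate_f1(cfg, markers, pt, n_offspring=150)
    _, G = fit_f1_model(counts, ("P1", "P2"))
    mk = pd.DataFrame({"chrom": [m.chrom for m in markers],
                       "pos": [m.pos for m in markers]},
                      index=pd.Index([m.locus_id for m in markers],
                                     name="locus_id"))
    infos, log = lk.screen_f1_markers(G.dosage, ("P1", "P2"))
    rfm = lk.estimate_rf(G.dosage, infos, ("P1", "P2"))
    return {"G": G.dosage, "markers": mk, "infos": infos, "log": log,
            "rf": rfm}


class TestScreen:
    def test_monomorphic_removed(self):
        G = _frame([[2] * 20], [(2, 2)], 20)
        infos, log = lk.screen_f1_markers(G, ("P1", "P2"))
        assert infos == [] and log.monomorphic == ["m0"]

    def test_unexpected_cross_removed(self):
        rng = np.random.default_rng(0)
        # aa x bb: all offspring het; the constant row is caught as
        # monomorphic, so plant one stray call to reach the cross check
        row = np.ones(20)
        row[0] = 0
        G = _frame([row], [(0, 2)], 20)
        infos, log = lk.screen_f1_markers(G, ("P1", "P2"))
        assert log.unexpected == ["m0"]

    def test_impossible_offspring_class_removed(self):
        row = np.array([0, 1] * 10)
        row[0] = 2          # impossible under ab x aa
        G = _frame([row], [(1, 0)], 20)
        infos, log = lk.screen_f1_markers(G, ("P1", "P2"))
        assert log.unexpected == ["m0"]

    def test_redundant_markers_keep_first(self):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 2, 40)
        G = _frame([row, row, 1 - row], [(1, 0)] * 3, 40)
        infos, log = lk.screen_f1_markers(G, ("P1", "P2"))
        assert log.redundant == {"m1": "m0"}
        assert {i.marker_id for i in infos} == {"m0", "m2"}

    def test_high_missing_removed(self):
        rng = np.random.default_rng(2)
        row = rng.integers(0, 2, 40).astype(float)
        row[:6] = np.nan      # 15% missing
        G = _frame([row], [(1, 0)], 40)
        infos, log = lk.screen_f1_markers(G, ("P1", "P2"))
        assert log.high_missing == ["m0"]

    def test_distorted_marker_removed(self):
        """90:10 at n=100 under a 1:1 expectation fails the chi-square."""
        row = np.array([0] * 90 + [1] * 10)
        G = _frame([row], [(1, 0)], 100)
        infos, log = lk.screen_f1_markers(G, ("P1", "P2"))
        assert log.distorted == ["m0"]

    def test_bonferroni_divisor_is_tested_marker_count(self):
        """Hand check on a 10-marker fixture: a marker is removed iff
        p * n_tested <= 0.05."""
        rng = np.random.default_rng(3)
        rows, parents = [], []
        for _ in range(9):
            rows.append(rng.integers(0, 2, 100))
            parents.append((1, 0))
        skew = np.array([0] * 68 + [1] * 32)   # p ~ 0.0003; adj p ~ 0.003
        rows.append(skew)
        parents.append((1, 0))
        G = _frame(rows, parents, 100)
        infos, log = lk.screen_f1_markers(G, ("P1", "P2"))
        assert log.n_tested_segregation == 10
        from scipy import stats
        p_raw = stats.chisquare([68, 32], f_exp=[50, 50]).pvalue
        assert (("m9" in log.distorted)
                == (min(1.0, p_raw * log.n_tested_segregation) <= 0.05))

    def test_absent_parent_is_error(self):
        G = _frame([[0, 1] * 5], [(1, 0)], 10)
        with pytest.raises(ValueError):
            lk.screen_f1_markers(G, ("P1", "nope"))

    def test_type_i_error_of_segregation_test(self):
        """Empirical size <= 0.07 at nominal 0.05 over 2000 null markers."""
        rng = np.random.default_rng(4)
        rejections = 0
        expected = np.array([0.5, 0.5, 0.0])
        for _ in range(2000):
            counts = rng.binomial(100, 0.5)
            obs = pd.Series([0] * counts + [1] * (100 - counts)).astype(float)
            if lk.segregation_test(obs, expected) <= 0.05:
                rejections += 1
        assert rejections / 2000 <= 0.07


class TestEstimateRf:
    def test_identical_columns_rf_zero(self):
        rng = np.random.default_rng(5)
        row = rng.integers(0, 2, 20)
        G = _frame([row, row.copy()], [(1, 0)] * 2, 20)
        # bypass redundancy screening: estimate RF on both markers directly
        infos = [lk.F1MarkerInfo(f"m{i}", 1, 0, "ab×aa",
                                 np.array([0.5, 0.5, 0.0])) for i in range(2)]
        rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
        assert rfm.r[0, 1] == 0.0
        assert rfm.lod[0, 1] > 3.0

    @pytest.mark.parametrize("parent_dosages", [
        [(1, 0), (1, 0)],     # testcross through parent 1
        [(1, 1), (1, 1)],     # ab x ab with phase ambiguity
    ])
    def test_rf_within_2se_of_truth(self, parent_dosages):
        rng = np.random.default_rng(6)
        n, r = 200, 0.2
        se = np.sqrt(r * (1 - r) / n)
        a1, b1 = _testcross_pair(rng, n, r)
        if parent_dosages[0] == (1, 1):
            a2, b2 = _testcross_pair(rng, n, r)
            rows = [a1 + a2, b1 + b2]
        else:
            rows = [a1, b1]
        G = _frame(rows, parent_dosages, n)
        infos, _ = lk.screen_f1_markers(G, ("P1", "P2"))
        rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
        assert rfm.r[0, 1] == pytest.approx(r, abs=2 * se)

    def test_unlinked_markers_high_rf(self):
        """Independent markers give r >= 0.4 in >= 95% of 200 replicates."""
        rng = np.random.default_rng(7)
        n = 100
        rows, parents = [], []
        for _ in range(200):
            rows.append(rng.integers(0, 2, n))
            rows.append(rng.integers(0, 2, n))
            parents += [(1, 0), (1, 0)]
        G = _frame(rows, parents, n)
        infos = [lk.F1MarkerInfo(f"m{i}", 1, 0, "ab×aa",
                                 np.array([0.5, 0.5, 0.0]))
                 for i in range(len(rows))]
        rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
        r_pairs = np.array([rfm.r[2 * k, 2 * k + 1] for k in range(200)])
        assert (r_pairs >= 0.4).mean() >= 0.95

    def test_no_shared_het_parent_unavailable(self):
        rng = np.random.default_rng(8)
        G = _frame([rng.integers(0, 2, 50), rng.integers(0, 2, 50) + 0],
                   [(1, 0), (0, 1)], 50)
        infos, _ = lk.screen_f1_markers(G, ("P1", "P2"))
        rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
        assert np.isnan(rfm.r[0, 1]) and rfm.lod[0, 1] == 0.0

    def test_low_overlap_unavailable(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 2, 30).astype(float)
        b = a.copy()
        a[:15] = np.nan
        b[15:] = np.nan      # zero joint observations
        G = _frame([a, b], [(1, 0)] * 2, 30)
        infos = [lk.F1MarkerInfo(f"m{i}", 1, 0, "ab×aa",
                                 np.array([0.5, 0.5, 0.0])) for i in range(2)]
        rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
        assert np.isnan(rfm.r[0, 1])

    def test_estimator_consistency_in_n(self):
        """Mean |r_hat - r| shrinks as n grows through 50..400."""
        rng = np.random.default_rng(10)
        r = 0.2
        errs = []
        for n in (50, 100, 200, 400):
            rows, parents = [], []
            for _ in range(60):
                a, b = _testcross_pair(rng, n, r)
                rows += [a, b]
                parents += [(1, 0), (1, 0)]
            G = _frame(rows, parents, n)
            infos = [lk.F1MarkerInfo(f"m{i}", 1, 0, "ab×aa",
                                     np.array([0.5, 0.5, 0.0]))
                     for i in range(len(rows))]
            rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
            err = np.mean([abs(rfm.r[2 * k, 2 * k + 1] - r)
                           for k in range(60)])
            errs.append(err)
        assert all(b < a for a, b in zip(errs, errs[1:]))


class TestRfFilter:
    def test_randomized_marker_removed(self, f1_panel):
        rng = np.random.default_rng(11)
        G = f1_panel["G"].copy()
        victim = f1_panel["infos"][0].marker_id
        off = [c for c in G.columns if c not in ("P1", "P2")]
        G.loc[victim, off] = rng.integers(0, 2, len(off)).astype(float)
        infos, _ = lk.screen_f1_markers(G, ("P1", "P2"))
        rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
        removed = lk.rf_filter(rfm, f1_panel["markers"]["chrom"])
        assert victim in removed

    def test_consistent_panel_untouched(self, f1_panel):
        removed = lk.rf_filter(f1_panel["rf"], f1_panel["markers"]["chrom"])
        assert removed == []

    def test_chimeric_marker_removed(self, f1_panel):
        """A marker spliced from four chromosomes links everywhere."""
        G = f1_panel["G"].copy()
        mk = f1_panel["markers"]
        donors = []
        for chrom in ("1", "2", "3", "4"):
            ids = [i.marker_id for i in f1_panel["infos"]
                   if mk.loc[i.marker_id, "chrom"] == chrom
                   and (i.p1, i.p2) == (1, 0)]
            if ids:
                donors.append(ids[0])
        assert len(donors) >= 4
        off = [c for c in G.columns if c not in ("P1", "P2")]
        q = len(off) // 4
        chimera = pd.concat([
            G.loc[donors[k], off[k * q:(k + 1) * q if k < 3 else len(off)]]
            for k in range(4)])
        G.loc["chimera"] = 0.0
        G.loc["chimera", off] = chimera
        G.loc["chimera", ["P1", "P2"]] = [1.0, 0.0]
        mk2 = pd.concat([mk, pd.DataFrame({"chrom": ["1"], "pos": [1]},
                                          index=["chimera"])])
        infos, _ = lk.screen_f1_markers(G, ("P1", "P2"))
        rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
        removed = lk.rf_filter(rfm, mk2["chrom"], max_regions=3)
        assert "chimera" in removed


class TestReposition:
    def test_planted_swap_recovered(self, f1_panel):
        mk = f1_panel["markers"].copy()
        victim = f1_panel["infos"][5].marker_id
        true_chrom = mk.loc[victim, "chrom"]
        mk.loc[victim, "chrom"] = "12" if true_chrom != "12" else "1"
        res = lk.reposition_markers(f1_panel["rf"], mk)
        assert victim in res.detached
        assert res.reassigned.get(victim) == true_chrom

    def test_consistent_panel_no_changes(self, f1_panel):
        res = lk.reposition_markers(f1_panel["rf"], f1_panel["markers"])
        assert res.detached == [] and res.reassigned == {}

    def test_unlinked_marker_detached_not_reassigned(self, f1_panel):
        rng = np.random.default_rng(12)
        G = f1_panel["G"].copy()
        victim = f1_panel["infos"][3].marker_id
        off = [c for c in G.columns if c not in ("P1", "P2")]
        G.loc[victim, off] = rng.integers(0, 2, len(off)).astype(float)
        infos, _ = lk.screen_f1_markers(G, ("P1", "P2"))
        rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
        res = lk.reposition_markers(rfm, f1_panel["markers"])
        assert victim in res.detached
        assert victim not in res.reassigned
        assert victim in res.unplaced

    def test_reassignment_requires_detachment(self, f1_panel):
        res = lk.reposition_markers(f1_panel["rf"], f1_panel["markers"])
        assert set(res.reassigned) <= set(res.detached)


class TestClusterAndMap:
    def test_twelve_pure_groups(self, f1_panel):
        groups, singletons = lk.cluster_linkage_groups(f1_panel["rf"],
                                                       n_groups=12)
        assert len(groups) == 12
        mk = f1_panel["markers"]
        for g in groups:
            assert mk.loc[g, "chrom"].nunique() == 1

    def test_two_unlinked_markers_are_singletons(self):
        rng = np.random.default_rng(13)
        G = _frame([rng.integers(0, 2, 60), rng.integers(0, 2, 60)],
                   [(1, 0)] * 2, 60)
        infos = [lk.F1MarkerInfo(f"m{i}", 1, 0, "ab×aa",
                                 np.array([0.5, 0.5, 0.0])) for i in range(2)]
        rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
        groups, singletons = lk.cluster_linkage_groups(rfm)
        assert groups == [] and set(singletons) == {"m0", "m1"}

    def test_groups_invariant_to_marker_order(self, f1_panel):
        rng = np.random.default_rng(14)
        infos = list(f1_panel["infos"])
        perm = rng.permutation(len(infos))
        rfm2 = lk.estimate_rf(f1_panel["G"], [infos[i] for i in perm],
                              ("P1", "P2"))
        g1, _ = lk.cluster_linkage_groups(f1_panel["rf"])
        g2, _ = lk.cluster_linkage_groups(rfm2)
        assert {frozenset(g) for g in g1} == {frozenset(g) for g in g2}

    def test_zero_recombination_zero_length(self):
        rng = np.random.default_rng(15)
        row = rng.integers(0, 2, 40)
        G = _frame([row, row.copy(), row.copy()], [(1, 0)] * 3, 40)
        infos = [lk.F1MarkerInfo(f"m{i}", 1, 0, "ab×aa",
                                 np.array([0.5, 0.5, 0.0])) for i in range(3)]
        rfm = lk.estimate_rf(G, infos, ("P1", "P2"))
        mk = pd.DataFrame({"chrom": "1", "pos": [10, 20, 30]},
                          index=rfm.ids)
        res = lk.two_point_map(["m0", "m1", "m2"], rfm, mk)
        assert res["length_cm"] == 0.0

    def test_haldane_distance_example(self):
        """r = 0.0906 between adjacent markers maps to ~10 cM."""
        r = haldane_r(10.0)
        rng = np.random.default_rng(16)
        ids = pd.Index(["a", "b"], name="locus_id")
        rfm = lk.RFMatrix(ids=ids,
                          r=np.array([[0.0, r], [r, 0.0]]),
                          lod=np.full((2, 2), 10.0),
                          phase=np.zeros((2, 2), dtype=np.int8),
                          n=np.full((2, 2), 100))
        mk = pd.DataFrame({"chrom": "1", "pos": [1, 2]}, index=ids)
        res = lk.two_point_map(["a", "b"], rfm, mk)
        assert res["length_cm"] == pytest.approx(10.0, abs=0.01)

    def test_adjacent_half_capped_and_flagged(self):
        ids = pd.Index(["a", "b"], name="locus_id")
        rfm = lk.RFMatrix(ids=ids, r=np.array([[0.0, 0.5], [0.5, 0.0]]),
                          lod=np.zeros((2, 2)),
                          phase=np.zeros((2, 2), dtype=np.int8),
                          n=np.full((2, 2), 100))
        mk = pd.DataFrame({"chrom": "1", "pos": [1, 2]}, index=ids)
        res = lk.two_point_map(["a", "b"], rfm, mk)
        assert res["length_cm"] == 50.0
        assert res["capped_gaps"] == [("a", "b")]

    def test_single_chromosome_length_within_20pct(self):
        """Simulated 100 cM chromosome, 40 markers, n = 200."""
        cfg = SimConfig(seed=33, n_chrom=1, n_loci=40, chrom_len_cm=100.0,
                        chrom_len_bp=41_000_000)
        markers, pt = simulate_parents(cfg)
        counts, _ = simulate_f1(cfg, markers, pt, n_offspring=200)
        _, G = fit_f1_model(counts, ("P1", "P2"))
        infos, _ = lk.screen_f1_markers(G.dosage, ("P1", "P2"))
        rfm = lk.estimate_rf(G.dosage, infos, ("P1", "P2"))
        groups, _ = lk.cluster_linkage_groups(rfm)
        mk = pd.DataFrame({"chrom": [m.chrom for m in markers],
                           "pos": [m.pos for m in markers]},
                          index=pd.Index([m.locus_id for m in markers],
                                         name="locus_id"))
        res = lk.two_point_map(groups[0], rfm, mk)
        assert 80.0 <= res["length_cm"] <= 120.0
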