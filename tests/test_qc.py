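from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polytag import qc
from polytag.simulate import SimConfig, simulate_cohort

from conftest import make_counts


class TestMissingness:
    @pytest.mark.parametrize("ref, alt, missing", [
        (4, 5, True),     # 9 reads: below the <10 rule
        (10, 0, False),   # boundary: 10 is not < 10
        (0, 0, True),
    ])
    def test_cell_rule(self, ref, alt, missing):
        counts = make_counts([[ref]], [[alt]])
        mask, _ = qc.missingness(counts)
        assert bool(mask.iloc[0, 0]) is missing

    def test_toy_rates(self):
        ref = [[10, 10, 10], [10, 10, 10], [3, 10, 10]]
        alt = np.zeros((3, 3), dtype=int)
        _, rep = qc.missingness(make_counts(ref, alt))
        assert rep.sample_rate.tolist() == [1 / 3, 0.0, 0.0]
        assert rep.marker_rate.tolist() == [0.0, 0.0, 1 / 3]

    def test_empty_matrix_is_error(self):
        counts = make_counts(np.zeros((0, 3)), np.zeros((0, 3)),
                             loci=[], samples=list("abc"))
        with pytest.raises(ValueError):
            qc.missingness(counts)

    def test_matches_brute_force_recount(self):
        """filter_by_missing agrees with a cell-by-cell recount on random
        fixtures."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            L, S = rng.integers(3, 12), rng.integers(3, 8)
            tot = rng.integers(0, 40, size=(L, S))
            alt = rng.binomial(tot, 0.3)
            counts = make_counts(tot - alt, alt)
            thr_s, thr_m = 0.5, 0.5
            kept, log = qc.filter_by_missing(counts, thr_s, thr_m)
            miss = tot < 10
            bad_s = set(np.array(counts.samples)[miss.mean(axis=0) >= thr_s])
            assert set(log.removed_samples) == bad_s
            keep_s = [j for j, s in enumerate(counts.samples)
                      if s not in bad_s]
            bad_m = set(np.array(counts.loci)[
                miss[:, keep_s].mean(axis=1) >= thr_m]) if keep_s else set()
            assert set(log.removed_markers) == bad_m

    def test_samples_removed_before_marker_rates(self):
        """A marker missing only in an all-missing sample survives because
        marker rates are recomputed after sample removal."""
        ref = np.full((4, 3), 20)
        ref[:, 0] = 0            # sample 0 entirely missing
        ref[0, 0] = 0            # marker 0 missing only in sample 0
        counts = make_counts(ref, np.zeros_like(ref))
        kept, log = qc.filter_by_missing(counts, 0.95, 0.25)
        assert log.removed_samples == ["s0"]
        assert log.removed_markers == []
        assert "m0" in kept.loci

    def test_planted_bad_marker_removed(self):
        ref = np.full((5, 20), 30)
        ref[2, 1:] = 0           # marker 2 missing in 19/20 samples
        counts = make_counts(ref, np.zeros_like(ref))
        kept, log = qc.filter_by_missing(counts, 0.95, 0.95)
        assert log.removed_markers == ["m2"]
        assert log.removed_samples == []


class TestMafAndPolymorphism:
    def test_maf_examples(self):
        counts = make_counts([[90], [50], [10]], [[10], [50], [0]])
        maf = qc.maf_from_reads(counts)
        assert maf.tolist() == [0.10, 0.5, 0.0]

    def test_all_zero_marker_flagged_undefined(self):
        maf = qc.maf_from_reads(make_counts([[0]], [[0]]))
        assert np.isnan(maf.iloc[0])

    def test_singleton_threshold_343_accessions(self):
        """330 diploids + 13 tetraploids -> 1/712 ~ 0.14%."""
        sheet = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(343)],
            "group": "x",
            "nominal_ploidy": [2] * 330 + [4] * 13})
        thr = qc.singleton_threshold(sheet.set_index("sample_id"))
        assert thr == Fraction(1, 712)
        assert round(float(thr) * 100, 2) == 0.14

    def test_threshold_exact_rational(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ploidies = rng.choice([1, 2, 3, 4, 6], size=rng.integers(1, 30))
            sheet = pd.DataFrame({
                "sample_id": [f"s{i}" for i in range(len(ploidies))],
                "group": "x", "nominal_ploidy": ploidies}).set_index("sample_id")
            assert qc.singleton_threshold(sheet) == Fraction(1, int(ploidies.sum()))

    def test_polymorphic_boundary_and_below(self):
        sheet = pd.DataFrame({"sample_id": [f"s{i}" for i in range(10)],
                              "group": "x",
                              "nominal_ploidy": [2] * 10}).set_index("sample_id")
        maf = pd.Series([0.05, 0.04, 0.0], index=["a", "b", "c"])
        calls, thr = qc.polymorphic_call(maf, sheet)
        assert thr == Fraction(1, 20)
        assert calls.tolist() == [True, False, False]  # >= rule at 0.05


class TestPic:
    @pytest.mark.parametrize("freqs, expected", [
        ([0.5, 0.5], 0.375),
        ([1.0], 0.0),
        ([1.0, 0.0], 0.0),
        ([0.9, 0.1], 1 - 0.82 - 2 * 0.81 * 0.01),
    ])
    def test_examples(self, freqs, expected):
        assert qc.pic(freqs) == pytest.approx(expected, abs=1e-12)

    def test_maximized_at_half_over_grid(self):
        grid = np.linspace(0.01, 0.99, 99)
        vals = [qc.pic([p, 1 - p]) for p in grid]
        assert max(vals) == pytest.approx(qc.pic([0.5, 0.5]))
        assert grid[int(np.argmax(vals))] == pytest.approx(0.5, abs=0.011)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(2, 6)
            p = rng.dirichlet(np.ones(n))
            brute = 1 - sum(pi ** 2 for pi in p) - sum(
                2 * p[i] ** 2 * p[j] ** 2
                for i in range(n) for j in range(i + 1, n))
            assert qc.pic(p) == pytest.approx(brute, abs=1e-12)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            qc.pic([0.6, 0.6])

    def test_per_marker_from_dosages(self):
        g = pd.DataFrame([[0, 1, 2, 1]], index=["m"],
                         columns=list("abcd")).astype(float)
        # p_alt = 4/8 -> PIC 0.375
        assert qc.pic_per_marker(g, 2).iloc[0] == pytest.approx(0.375)


class TestIbs:
    def test_identical_vectors(self):
        prop, n = qc.ibs([0, 1, 2], [0, 1, 2])
        assert prop == 1.0 and n == 3

    def test_hand_count_with_missing(self):
        prop, n = qc.ibs([0, 1, 2, np.nan], [0, 1, 1, 2])
        assert prop == pytest.approx(2 / 3) and n == 3

    def test_disjoint_missingness_is_error(self):
        with pytest.raises(ValueError):
            qc.ibs([np.nan, 1.0], [0.0, np.nan])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.sampled_from([0.0, 1.0, 2.0, np.nan]), min_size=1,
                    max_size=30).filter(lambda v: any(not np.isnan(x)
                                                      for x in v)))
    def test_symmetric_and_reflexive(self, vec):
        other = list(reversed(vec))
        try:
            p_ab, n_ab = qc.ibs(vec, other)
            p_ba, n_ba = qc.ibs(other, vec)
            assert p_ab == p_ba and n_ab == n_ba
        except ValueError:
            with pytest.raises(ValueError):
                qc.ibs(other, vec)
        assert qc.ibs(vec, vec)[0] == 1.0


class TestAlleleRatioPca:
    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        tot = rng.integers(20, 60, size=(30, 4))
        alt = rng.binomial(tot, 0.4)
        ref, alt = tot - alt, alt
        ref[:, 3], alt[:, 3] = ref[:, 0], alt[:, 0]  # duplicate sample
        res = qc.allele_ratio_pca(make_counts(ref, alt), n_pc=3)
        np.testing.assert_allclose(res.scores.iloc[0], res.scores.iloc[3],
                                   atol=1e-9)

    def test_variance_explained_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        tot = rng.integers(20, 60, size=(40, 12))
        alt = rng.binomial(tot, rng.uniform(0.1, 0.9, size=(40, 1)))
        res = qc.allele_ratio_pca(make_counts(tot - alt, alt), n_pc=5)
        v = res.variance_explained
        assert np.all(np.diff(v) <= 1e-9) and v.sum() <= 100 + 1e-6

    def test_unobserved_marker_dropped_with_warning(self):
        ref = np.full((3, 4), 30)
        ref[1] = 0
        with pytest.warns(UserWarning, match="dropped"):
            res = qc.allele_ratio_pca(make_counts(ref, np.zeros_like(ref)),
                                      n_pc=2)
        assert res.dropped_markers == ["m1"]

    def test_two_populations_separate_on_pc1(self):
        """Cohorts simulated from divergent founder frequencies separate
        with silhouette > 0.5 on PC1."""
        from sklearn.metrics import silhouette_score
        cfg_a = SimConfig(seed=11, n_loci=300, maf_low=0.05, maf_high=0.2)
        cfg_b = SimConfig(seed=11, n_loci=300, maf_low=0.35, maf_high=0.5)
        _, ca, _ = simulate_cohort(cfg_a, 20, 2, prefix="A")
        _, cb, _ = simulate_cohort(cfg_b, 20, 2, prefix="B")
        counts = make_counts(
            np.hstack([ca.ref.to_numpy(), cb.ref.to_numpy()]),
            np.hstack([ca.alt.to_numpy(), cb.alt.to_numpy()]),
            loci=list(ca.loci), samples=list(ca.samples) + list(cb.samples))
        res = qc.allele_ratio_pca(counts, n_pc=2)
        labels = [0] * 20 + [1] * 20
        score = silhouette_score(res.scores[["PC1"]], labels)
        assert score > 0.5
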