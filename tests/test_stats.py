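"""Within-subject factorial ANOVA and cluster-based permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

import aperiodic as ap
from aperiodic.exceptions import DataError, InputError
from conftest import make_exponent_table


@pytest.fixture(scope="module")
def adjacency60():
    return ap.equidistant_montage(60)


@pytest.fixture(scope="module")
def adjacency20():
    return ap.equidistant_montage(20)


class TestMontage:
    def test_default_montage_structure(self, adjacency60):
        m = adjacency60.matrix
        assert m.shape == (60, 60)
        assert np.array_equal(m, m.T)
        assert not m.diagonal().any()
        assert adjacency60.is_connected

    def test_from_edges(self):
        adj = ap.MontageAdjacency.from_edges(["a", "b", "c"],
                                             [("a", "b"), ("b", "c")])
        assert adj.matrix.sum() == 4
        assert adj.is_connected

    def test_disconnected_warns_with_components(self):
        with pytest.warns(UserWarning, match="disconnected"):
            adj = ap.MontageAdjacency.from_edges(
                ["a", "b", "c", "d"], [("a", "b"), ("c", "d")])
        assert not adj.is_connected


class TestWithinSubjectAnova:
    def test_null_contrast_gives_f0_p1(self, rng):
        t = make_exponent_table(rng, n_subjects=8)
        # force MPH cells exactly equal to placebo cells
        piv = t.pivot_table(index=["participant", "period", "prime",
                                   "flanker"], columns="drug",
                            values="exponent").reset_index()
        piv["mph"] = piv["placebo"]
        t2 = piv.melt(id_vars=["participant", "period", "prime", "flanker"],
                      value_vars=["mph", "placebo"], var_name="drug",
                      value_name="exponent")
        res = ap.rm_anova(t2)
        assert res["drug"].F == 0.0
        assert res["drug"].p == 1.0

    def test_f_equals_squared_paired_t(self, rng):
        """Independent oracle: per-subject marginal-mean differences fed to
        scipy's paired t; F must equal t^2 exactly for every 2-level effect."""
        t = make_exponent_table(rng, n_subjects=12,
                                effects={"drug": 0.1, "period": 0.05})
        res = ap.rm_anova(t)
        cells = t.groupby(["participant", "period", "drug", "prime",
                           "flanker"])["exponent"].mean().reset_index()
        for factor in ("period", "drug", "prime", "flanker"):
            lv = sorted(cells[factor].unique())
            hi = (cells[cells[factor] == lv[1]]
                  .groupby("participant")["exponent"].mean())
            lo = (cells[cells[factor] == lv[0]]
                  .groupby("participant")["exponent"].mean())
            tstat, p = sst.ttest_rel(hi, lo)
            assert res[factor].F == pytest.approx(tstat ** 2, abs=1e-10)
            assert res[factor].p == pytest.approx(p, abs=1e-12)
            assert res[factor].df1 == 1 and res[factor].df2 == 11

    def test_interaction_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        t = make_exponent_table(rng, n_subjects=9,
                                effects={"drug": 0.1, "prime": 0.03})
        mine = ap.rm_anova(t)
        ref = AnovaRM(t, "exponent", "participant",
                      within=["period", "drug", "prime", "flanker"]
                      ).fit().anova_table
        for e in mine:
            key = ":".join(e.effect.split(" x "))
            assert e.F == pytest.approx(ref.loc[key, "F Value"], abs=1e-8)
            assert e.p == pytest.approx(ref.loc[key, "Pr > F"], abs=1e-10)

    def test_partial_eta_sq_identity(self, rng):
        t = make_exponent_table(rng, n_subjects=10, effects={"drug": 0.1})
        for e in ap.rm_anova(t):
            assert e.partial_eta_sq == pytest.approx(
                e.F / (e.F + e.df2), abs=1e-12)

    def test_injected_drug_effect_detected(self):
        """n=25 with a +0.129 MPH shift and 0.05 within-subject noise must
        yield p < .001 in (nearly) every replicate."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = make_exponent_table(rng, n_subjects=25, noise_sd=0.05,
                                    effects={"drug": 0.129})
            res = ap.rm_anova(t)
            e = res["drug"]
            hi = e.level_means["placebo"][0]
            lo = e.level_means["mph"][0]
            if e.p < 0.001 and lo > hi:
                hits += 1
        assert hits >= 9

    def test_level_means_reported_with_sem(self, rng):
        t = make_exponent_table(rng, n_subjects=6)
        res = ap.rm_anova(t)
        means = res["drug"].level_means
        assert set(means) == {"mph", "placebo"}
        for m, sem in means.values():
            assert np.isfinite(m) and sem > 0

    def test_missing_cells_rejected_with_listing(self, rng):
        t = make_exponent_table(rng, n_subjects=4)
        t = t.drop(t.index[0])
        with pytest.raises(DataError):
            ap.rm_anova(t)
        t2 = make_exponent_table(rng, n_subjects=4)
        t2.loc[0, "exponent"] = np.nan
        with pytest.raises(DataError):
            ap.rm_anova(t2)

    def test_fewer_than_two_subjects_rejected(self, rng):
        t = make_exponent_table(rng, n_subjects=1)
        with pytest.raises(InputError):
            ap.rm_anova(t)

    def test_summary_formats(self, rng):
        text = ap.rm_anova(make_exponent_table(rng, n_subjects=5)).summary()
        assert "period x drug" in text and "(1,4)" in text


class TestFollowUpAnovas:
    def test_null_data_null_in_both_splits(self, rng):
        t = make_exponent_table(rng, n_subjects=20, noise_sd=0.05)
        out = ap.follow_up_anovas(t, "period")
        for res in out.values():
            assert all(e.p > 0.001 for e in res)

    def test_within_only_effect_found_only_within(self, rng):
        t = make_exponent_table(rng, n_subjects=20, noise_sd=0.02)
        within = t["period"] == "within_trial"
        mph = t["drug"] == "mph"
        t.loc[within & mph, "exponent"] += 0.15
        out = ap.follow_up_anovas(t, "period")
        assert out["within_trial"]["drug"].p_corrected < 0.001
        assert out["pre_trial"]["drug"].p_corrected > 0.05

    def test_bonferroni_doubling(self, rng):
        t = make_exponent_table(rng, n_subjects=8)
        out = ap.follow_up_anovas(t, "period")
        for res in out.values():
            for e in res:
                assert e.p_corrected == pytest.approx(min(1.0, 2 * e.p))


class TestClusterPermutation:
    def test_identical_data_empty_result(self, adjacency20, rng):
        a = rng.standard_normal((10, 20))
        res = ap.cluster_permutation_test(a, a.copy(), adjacency20, seed=0)
        assert res.clusters == []
        assert np.all(res.stat_map == 0)

    def test_localized_effect_detected_exactly(self, adjacency20):
        """A d=3 effect at one electrode plus its neighbours must come back
        as a significant cluster of exactly those electrodes."""
        target = 7
        members = sorted([target] + list(np.flatnonzero(
            adjacency20.matrix[target])))
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            diff = rng.standard_normal((25, 20))
            diff[:, members] += 3.0
            a = diff
            b = np.zeros_like(a)
            res = ap.cluster_permutation_test(a, b, adjacency20, stat="F",
                                              n_permutations=500, seed=seed)
            sig = res.significant_clusters
            if len(sig) == 1 and sorted(
                    adjacency20.names.index(n) for n in sig[0].electrodes
                    ) == members:
                hits += 1
        assert hits >= 9

    def test_positive_effect_positive_sign_only(self, adjacency20, rng):
        a = rng.standard_normal((25, 20)) + 1.5
        b = rng.standard_normal((25, 20))
        res = ap.cluster_permutation_test(a, b, adjacency20, stat="paired_t",
                                          n_permutations=200, seed=1)
        assert res.clusters
        assert all(c.sign == "positive" for c in res.clusters)
        assert all(c.mass > 0 for c in res.clusters)

    def test_stricter_threshold_shrinks_clusters(self, adjacency20, rng):
        a = rng.standard_normal((15, 20)) + 0.8
        b = rng.standard_normal((15, 20))
        loose = ap.cluster_permutation_test(a, b, adjacency20, stat="F",
                                            sample_alpha=0.05,
                                            n_permutations=100, seed=2)
        strict = ap.cluster_permutation_test(a, b, adjacency20, stat="F",
                                             sample_alpha=0.001,
                                             n_permutations=100, seed=2)
        n_loose = sum(len(c.electrodes) for c in loose.clusters)
        n_strict = sum(len(c.electrodes) for c in strict.clusters)
        assert n_strict <= n_loose

    def test_p_floor_and_observed_included(self, adjacency20, rng):
        a = rng.standard_normal((25, 20)) + 2.0
        b = rng.standard_normal((25, 20))
        res = ap.cluster_permutation_test(a, b, adjacency20,
                                          n_permutations=200, seed=3)
        for c in res.clusters:
            assert c.p_value >= 1.0 / 201.0

    def test_relabeling_symmetry(self, adjacency20, rng):
        a = rng.standard_normal((12, 20)) + 0.5
        b = rng.standard_normal((12, 20))
        r1 = ap.cluster_permutation_test(a, b, adjacency20, stat="paired_t",
                                         n_permutations=300, seed=4)
        r2 = ap.cluster_permutation_test(b, a, adjacency20, stat="paired_t",
                                         n_permutations=300, seed=4)
        p1 = sorted(c.p_value for c in r1.clusters)
        p2 = sorted(c.p_value for c in r2.clusters)
        assert p1 == p2
        signs1 = sorted(c.sign for c in r1.clusters)
        signs2 = sorted({"positive": "negative",
                         "negative": "positive"}[c.sign]
                        for c in r2.clusters)
        assert signs1 == signs2

    def test_power_monotone_in_effect_size(self, adjacency20):
        detect = []
        for effect in (0.3, 0.8, 2.0):
            hits = 0
            for seed in range(8):
                rng = np.random.default_rng(7000 + seed)
                a = rng.standard_normal((20, 20))
                a[:, :6] += effect
                b = rng.standard_normal((20, 20))
                res = ap.cluster_permutation_test(a, b, adjacency20,
                                                  stat="F",
                                                  n_permutations=300,
                                                  seed=seed)
                hits += bool(res.significant_clusters)
            detect.append(hits)
        assert detect[0] <= detect[1] + 1
        assert detect[-1] >= detect[0]
        assert detect[-1] == 8  # d=2 at n=20 is essentially always found

    def test_too_few_subjects_rejected(self, adjacency20):
        with pytest.raises(InputError):
            ap.cluster_permutation_test(np.zeros((1, 20)), np.zeros((1, 20)),
                                        adjacency20)

    def test_adjacency_coverage_enforced(self, adjacency20, rng):
        with pytest.raises(InputError):
            ap.cluster_permutation_test(rng.standard_normal((5, 10)),
                                        rng.standard_normal((5, 10)),
                                        adjacency20)


class TestElectrodewiseTests:
    def _table(self, rng, n_subjects=12, n_electrodes=20, drug_shift=0.0):
        rows = []
        subj = rng.normal(0, 0.2, n_subjects)
        for s in range(n_subjects):
            for per in ("pre_trial", "within_trial"):
                for drug in ("placebo", "mph"):
                    for prime in ("congruent", "incongruent"):
                        for fl in ("congruent", "incongruent"):
                            base = 3.4 + subj[s] + rng.normal(
                                0, 0.05, n_electrodes)
                            if drug == "mph":
                                base = base + drug_shift
                            for e in range(n_electrodes):
                                rows.append((s, per, drug, prime, fl,
                                             f"E{e + 1:02d}", base[e]))
        return pd.DataFrame(rows, columns=["participant", "period", "drug",
                                           "prime", "flanker", "electrode",
                                           "exponent"])

    def test_eight_maps_produced(self, adjacency20, rng):
        t = self._table(rng)
        out = ap.electrodewise_condition_tests(t, adjacency20,
                                               n_permutations=100, seed=0)
        assert len(out) == 8
        assert all(len(k) == 3 for k in out)

    def test_uniform_drug_effect_significant_everywhere(self, adjacency20):
        rng = np.random.default_rng(31)
        t = self._table(rng, n_subjects=25, drug_shift=0.129)
        out = ap.electrodewise_condition_tests(t, adjacency20,
                                               n_permutations=200, seed=5)
        for res in out.values():
            sig = res.significant_clusters
            assert sig and all(c.sign == "positive" for c in sig)

    def test_deterministic_under_seed(self, adjacency20, rng):
        t = self._table(rng)
        o1 = ap.electrodewise_condition_tests(t, adjacency20,
                                              n_permutations=100, seed=9)
        o2 = ap.electrodewise_condition_tests(t, adjacency20,
                                              n_permutations=100, seed=9)
        for k in o1:
            assert [c.p_value for c in o1[k].clusters] == \
                [c.p_value for c in o2[k].clusters]
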