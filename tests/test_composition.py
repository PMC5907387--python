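import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from gutshift import composition as comp


class TestAggregateRank:
    LINEAGES = {
        "sp1": {"genus": "G1"},
        "sp2": {"genus": "G1"},
        "sp3": {"genus": "G2"},
    }

    def test_sums_within_genus(self):
        abund = pd.DataFrame({"s0": [0.3, 0.2, 0.5]}, index=["sp1", "sp2", "sp3"])
        out = comp.aggregate_rank(abund, self.LINEAGES, "genus")
        assert out.loc["G1", "s0"] == pytest.approx(0.5)
        assert out.loc["G2", "s0"] == pytest.approx(0.5)

    def test_all_unassigned_collapses_to_one_row(self):
        abund = pd.DataFrame({"s0": [0.4, 0.6]}, index=["x", "y"])
        out = comp.aggregate_rank(abund, {}, "genus")
        assert list(out.index) == ["unassigned"]
        assert out.loc["unassigned", "s0"] == pytest.approx(1.0)

    def test_mixed_table_matches_hand_sums(self):
        lineages = {
            "a": {"genus": "G1"}, "b": {"genus": "G2"}, "c": {"genus": "G3"},
            "d": {"genus": "G1"}, "e": {},
        }
        abund = pd.DataFrame(
            {"s0": [0.1, 0.2, 0.3, 0.25, 0.15], "s1": [0.5, 0.1, 0.1, 0.1, 0.2]},
            index=list("abcde"),
        )
        out = comp.aggregate_rank(abund, lineages, "genus")
        assert out.loc["G1"].tolist() == pytest.approx([0.35, 0.6])
        assert out.loc["unassigned"].tolist() == pytest.approx([0.15, 0.2])

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError):
            comp.aggregate_rank(pd.DataFrame({"s": [1.0]}, index=["a"]), {}, "clade")


class TestLogTransform:
    def test_feature_pseudo_is_tenth_of_min_nonzero(self):
        abund = pd.DataFrame({"s0": [0.0], "s1": [0.001], "s2": [0.01]}, index=["f"])
        out = comp.log_transform(abund)
        assert out.loc["f", "s0"] == pytest.approx(-4.0)
        assert out.loc["f", "s1"] == pytest.approx(math.log10(0.0011))
        assert out.loc["f", "s2"] == pytest.approx(math.log10(0.0101))

    def test_constant_positive_feature_stays_constant(self):
        abund = pd.DataFrame({"s0": [0.5], "s1": [0.5]}, index=["f"])
        out = comp.log_transform(abund)
        assert out.loc["f", "s0"] == out.loc["f", "s1"]

    def test_fixed_policy(self):
        abund = pd.DataFrame({"s0": [0.0], "s1": [0.1]}, index=["f"])
        out = comp.log_transform(abund, pseudo_policy="fixed:1e-6")
        assert out.loc["f", "s0"] == pytest.approx(-6.0)
        assert out.loc["f", "s1"] == pytest.approx(math.log10(0.1 + 1e-6))

    def test_all_zero_feature_falls_back_to_global(self, caplog):
        abund = pd.DataFrame(
            {"s0": [0.0, 0.2], "s1": [0.0, 0.8]}, index=["dead", "live"]
        )
        pseudo = comp.feature_pseudocounts(abund)
        assert pseudo["dead"] == pytest.approx(0.02)

    def test_shift_makes_matrix_nonnegative(self):
        abund = pd.DataFrame(
            {"s0": [0.0, 0.9], "s1": [1e-4, 0.3]}, index=["a", "b"]
        )
        out = comp.log_transform(abund, shift_to_nonnegative=True)
        assert (out.to_numpy() >= -1e-12).all()


class TestDistances:
    def test_disjoint_support_is_maximal(self):
        m = pd.DataFrame({"x": [1.0, 0.0], "y": [0.0, 1.0]})
        assert comp.distance_matrix(m, "bray_curtis").loc["x", "y"] == pytest.approx(1.0)
        assert comp.distance_matrix(m, "weighted_jaccard").loc["x", "y"] == pytest.approx(1.0)

    @pytest.mark.parametrize("metric", ["bray_curtis", "weighted_jaccard", "manhattan"])
    def test_identity(self, metric):
        m = pd.DataFrame({"x": [0.2, 0.8], "y": [0.2, 0.8]})
        assert comp.distance_matrix(m, metric).loc["x", "y"] == pytest.approx(0.0)

    def test_hand_computed_values(self):
        m = pd.DataFrame({"x": [2.0, 2.0], "y": [1.0, 3.0]})
        assert comp.distance_matrix(m, "bray_curtis").loc["x", "y"] == pytest.approx(0.25)
        assert comp.distance_matrix(m, "weighted_jaccard").loc["x", "y"] == pytest.approx(0.4)
        assert comp.distance_matrix(m, "manhattan").loc["x", "y"] == pytest.approx(2.0)

    def test_negative_input_rejected_for_compositional_metrics(self):
        m = pd.DataFrame({"x": [-0.1, 1.0], "y": [0.5, 0.5]})
        with pytest.raises(ValueError):
            comp.distance_matrix(m, "bray_curtis")

    def test_bounds_and_symmetry_on_random_data(self, rng):
        m = pd.DataFrame(rng.uniform(size=(6, 8)))
        for metric in ("bray_curtis", "weighted_jaccard"):
            d = comp.distance_matrix(m, metric).to_numpy()
            assert ((d >= 0) & (d <= 1)).all()
            np.testing.assert_allclose(d, d.T)
            np.testing.assert_allclose(np.diag(d), 0.0)


class TestPcoa:
    def test_zero_distances_give_zero_coordinates(self):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        coords, _ = comp.pcoa(d, k=2)
        np.testing.assert_allclose(coords.to_numpy(), 0.0)

    def test_colinear_three_points(self):
        # d(A,B)=d(B,C)=1, d(A,C)=2: points on a line; exactly one positive
        # eigenvalue, the second is 0 (verified by hand on the centered matrix)
        d = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc"),
            dtype=float,
        )
        coords, evals = comp.pcoa(d, k=2)
        assert evals[0] > 0
        assert abs(evals[1]) < 1e-10
        np.testing.assert_allclose(coords["PCo2"], 0.0, atol=1e-8)

    def test_euclidean_roundtrip(self, rng):
        pts = rng.normal(size=(7, 4))
        d = pd.DataFrame(cdist(pts, pts))
        coords, evals = comp.pcoa(d, k=7)
        d2 = cdist(coords.to_numpy(), coords.to_numpy())
        np.testing.assert_allclose(d.to_numpy(), d2, atol=1e-8)
        assert (evals >= -1e-10).all()

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(6, 3))
        d = cdist(pts, pts)
        coords, evals = comp.pcoa(pd.DataFrame(d), k=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        np.testing.assert_allclose(
            np.abs(coords.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :3]),
            atol=1e-8,
        )

    def test_k_too_large_rejected(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            comp.pcoa(d, k=4)


class TestPermanova:
    @staticmethod
    def _clustered(rng, n_per, sep):
        a = rng.normal(size=(n_per, 2))
        b = rng.normal(size=(n_per, 2)) + sep
        pts = np.vstack([a, b])
        labels = ["a"] * n_per + ["b"] * n_per
        return pd.DataFrame(cdist(pts, pts)), labels

    def test_perfect_separation_gives_minimal_p(self):
        n = 8
        pts = np.array([[0.0, 0.0]] * n + [[1.0, 0.0]] * n)
        d = pd.DataFrame(cdist(pts, pts))
        labels = ["a"] * n + ["b"] * n
        f, p = comp.permanova(d, labels, n_permutations=199, seed=0)
        assert math.isinf(f)
        assert p == pytest.approx(1 / 200)

    def test_exhaustive_matches_independent_enumeration(self, rng):
        # 5 samples, groups of 2 and 3: enumerate all C(5,2)=10 assignments by hand
        pts = rng.normal(size=(5, 2))
        d = pd.DataFrame(cdist(pts, pts))
        labels = np.array(["a", "a", "b", "b", "b"])
        f_obs, p = comp.permanova(d, labels, n_permutations=None)

        def brute_f(lab):
            dm = d.to_numpy()
            n = 5
            iu = np.triu_indices(n, 1)
            ss_total = (dm[iu] ** 2).sum() / n
            ss_within = 0.0
            for g in ("a", "b"):
                idx = np.flatnonzero(np.asarray(lab) == g)
                sub = dm[np.ix_(idx, idx)]
                ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
            return ((ss_total - ss_within) / 1) / (ss_within / 3)

        hits = 0
        for combo in itertools.combinations(range(5), 2):
            lab = np.array(["b"] * 5)
            lab[list(combo)] = "a"
            if brute_f(lab) >= f_obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / 10)

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        d, labels = self._clustered(rng, 6, 1.5)
        f, _ = comp.permanova(d, labels, n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.to_numpy()), grouping=labels, permutations=99
        )
        assert f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_null_p_roughly_uniform(self, rng):
        # under shuffled labels 4-16% of p-values should fall below 0.05
        hits = 0
        reps = 200
        for _ in range(reps):
            pts = rng.normal(size=(12, 2))
            d = pd.DataFrame(cdist(pts, pts))
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            _, p = comp.permanova(d, labels, n_permutations=99, seed=int(rng.integers(2**31)))
            hits += p <= 0.05
        assert 0.04 * reps <= hits <= 0.16 * reps

    def test_singleton_group_rejected(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            comp.permanova(d, ["a", "a", "b"])


class TestPairedShift:
    def test_identical_timepoints_shift_zero(self, small_study):
        abund = small_study.abundance.copy()
        meta = small_study.metadata
        for dog in meta.dog_id.unique():
            abund[f"{dog}_post"] = abund[f"{dog}_baseline"]
        shifts = comp.paired_shift(abund, meta)
        np.testing.assert_allclose(shifts["shift"], 0.0, atol=1e-12)

    def test_planted_hplc_exceeds_lphc(self, planted_study):
        shifts = comp.paired_shift(planted_study.abundance, planted_study.metadata)
        med_h = shifts.loc[shifts.diet == "HPLC", "shift"].median()
        med_l = shifts.loc[shifts.diet == "LPHC", "shift"].median()
        assert med_h > med_l
        _, p = comp.compare_shift_groups(shifts, shifts.diet == "HPLC", shifts.diet == "LPHC")
        assert p < 0.05

    def test_ow_hyper_response_dominates(self, planted_study):
        shifts = comp.paired_shift(planted_study.abundance, planted_study.metadata)
        hplc = shifts[shifts.diet == "HPLC"]
        ow = np.sort(hplc.loc[hplc.condition == "OW", "shift"].to_numpy())
        ln = np.sort(hplc.loc[hplc.condition == "LN", "shift"].to_numpy())
        # stochastic dominance: OW quantiles sit above LN quantiles
        q = np.linspace(0.1, 0.9, 9)
        assert (np.quantile(ow, q) >= np.quantile(ln, q)).mean() >= 0.8
        assert ow.mean() > ln.mean()

    def test_incomplete_dog_excluded(self, small_study):
        meta = small_study.metadata.iloc[1:]  # drop one baseline sample
        shifts = comp.paired_shift(small_study.abundance, meta)
        assert len(shifts) == small_study.metadata.dog_id.nunique() - 1


class TestRatioTest:
    def test_numerator_equals_denominator(self):
        abund = pd.DataFrame(
            {"s0": [0.5, 0.5], "s1": [0.3, 0.7], "s2": [0.2, 0.8], "s3": [0.6, 0.4]},
            index=["a", "b"],
        )
        res = comp.ratio_test(
            abund, ["a", "b"], ["a", "b"],
            {"g1": ["s0", "s1"], "g2": ["s2", "s3"]},
        )
        assert res["p_value"] == pytest.approx(1.0)

    def test_planted_ratio_shift(self, planted_study):
        study = planted_study
        meta = study.metadata.set_index("sample_id")
        post = meta[meta.timepoint == "post"]
        up = [t for t, m in study.truth["effect_map"].items() if m.get("HPLC", 0) > 0]
        down = [t for t, m in study.truth["effect_map"].items() if m.get("HPLC", 0) < 0]
        res = comp.ratio_test(
            study.abundance, up, down,
            {
                "HPLC": list(post.index[post.diet == "HPLC"]),
                "LPHC": list(post.index[post.diet == "LPHC"]),
            },
        )
        assert res["p_value"] < 0.05
        assert np.median(res["groups"]["HPLC"]) > np.median(res["groups"]["LPHC"])

    def test_all_tied_degenerate(self):
        abund = pd.DataFrame(
            {f"s{i}": [0.5, 0.5] for i in range(6)}, index=["a", "b"]
        )
        res = comp.ratio_test(
            abund, ["a"], ["b"],
            {"g1": ["s0", "s1"], "g2": ["s2", "s3"], "g3": ["s4", "s5"]},
        )
        assert res["p_value"] == pytest.approx(1.0)

    def test_empty_taxon_set_rejected(self):
        abund = pd.DataFrame({"s0": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            comp.ratio_test(abund, [], ["a"], {"g": ["s0"]})


class TestLeaveOutRobustness:
    @staticmethod
    def _focal(shifts):
        mask = (shifts.diet == "HPLC") & (shifts.condition == "OW")
        return comp.compare_shift_groups(shifts, mask, ~mask)[1]

    def test_subset_count_combinatorics(self, small_study):
        abund = small_study.abundance.iloc[:4]
        abund = abund.div(abund.sum(axis=0), axis=1)
        report = comp.leave_out_robustness(
            abund, small_study.metadata, self._focal, max_k=3
        )
        assert report["n_subsets"] == 4 + 6 + 4

    def test_jointly_planted_effect_is_robust(self):
        from gutshift import simulate

        # strong effect on 5 of 9 taxa: no single/pair removal can break it
        effect_map = {f"taxon_{i:03d}": {"HPLC": 3.0 if i % 2 else -3.0} for i in range(5)}
        cfg = simulate.StudyConfig(
            n_dogs=48, n_taxa=9, effect_map=effect_map, detection_limit=1e-12,
            noise_sd=0.1, dog_effect_sd=0.2, seed=21,
        )
        study = simulate.simulate_study(cfg)

        def focal(shifts):
            return comp.compare_shift_groups(
                shifts, shifts.diet == "HPLC", shifts.diet == "LPHC"
            )[1]

        report = comp.leave_out_robustness(study.abundance, study.metadata, focal, max_k=2)
        assert report["all_significant"], report["breaking_subsets"]

    def test_single_genus_effect_flagged(self):
        from gutshift import simulate

        effect_map = {"taxon_000": {"HPLC": 4.0}}
        cfg = simulate.StudyConfig(
            n_dogs=40, n_taxa=6, effect_map=effect_map, detection_limit=1e-12,
            noise_sd=0.05, dog_effect_sd=0.1, seed=22,
        )
        study = simulate.simulate_study(cfg)

        def focal(shifts):
            return comp.compare_shift_groups(
                shifts, shifts.diet == "HPLC", shifts.diet == "LPHC"
            )[1]

        report = comp.leave_out_robustness(study.abundance, study.metadata, focal, max_k=1)
        assert not report["all_significant"]
        assert ("taxon_000",) in report["breaking_subsets"]

    def test_too_few_genera_rejected(self, small_study):
        with pytest.raises(ValueError):
            comp.leave_out_robustness(
                small_study.abundance.iloc[:3], small_study.metadata, self._focal, max_k=3
            )
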