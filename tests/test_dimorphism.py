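"""Dimorphic-edge statistics: t, p, FDR, thresholds, scaling, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimflow.dimorphism import (DEFAULT_NOISE_THRESHOLDS, build_paired_table,
                                classify_edges, dimorphism_summary,
                                edge_p_values, estimate_noise_threshold,
                                estimate_scale_factor, fdr_adjust,
                                hemisphere_t_statistic,
                                reconcile_with_type_labels)


def paired_frame(rows):
    cols = ["pre", "post", "male_left", "male_right", "female_left",
            "female_right"]
    df = pd.DataFrame(rows, columns=cols)
    df["male_total"] = df["male_left"] + df["male_right"]
    df["female_total"] = df["female_left"] + df["female_right"]
    df["matched"] = True
    return df


class TestTStatistic:
    def test_published_worked_example(self):
        # male (scaled) hemispheres 5.81/4.64 vs female 12/8:
        # x̄m=5.225, x̄f=10, sm=1.17/√2, sf=4/√2, sp=√4.342225 → t=-2.29148
        t = hemisphere_t_statistic(5.81, 4.64, 12.0, 8.0)
        assert t == pytest.approx(-2.29148, abs=5e-5)

    def test_null_case_is_zero(self):
        assert hemisphere_t_statistic(7, 5, 7, 5) == 0.0

    def test_zero_variance_convention(self):
        assert hemisphere_t_statistic(10, 10, 4, 4) == np.inf
        assert hemisphere_t_statistic(4, 4, 10, 10) == -np.inf
        assert hemisphere_t_statistic(4, 4, 4, 4) == 0.0

    @settings(max_examples=60, deadline=None)
    @given(st.tuples(*[st.floats(0, 1e4) for _ in range(4)]))
    def test_antisymmetric_and_hemisphere_exchange_invariant(self, w):
        ml, mr, fl, fr = w
        t = hemisphere_t_statistic(ml, mr, fl, fr)
        t_swap = hemisphere_t_statistic(fl, fr, ml, mr)
        t_lr = hemisphere_t_statistic(mr, ml, fl, fr)
        if np.isfinite(t):
            assert t_swap == pytest.approx(-t, rel=1e-9, abs=1e-12)
            assert t_lr == pytest.approx(t, rel=1e-9, abs=1e-12)
        else:
            assert t_swap == -t and t_lr == t


class TestPValues:
    def test_central_and_limit_values(self):
        assert edge_p_values(0.0) == 1.0
        assert edge_p_values(np.inf) == 0.0
        assert edge_p_values(-np.inf) == 0.0

    def test_two_sided_five_percent_critical_value(self):
        # 3.1824 is the two-sided 5% critical value of t with 3 df
        assert edge_p_values(3.1824, df=3) == pytest.approx(0.05, abs=1e-4)
        assert edge_p_values(-3.1824, df=3) == pytest.approx(0.05, abs=1e-4)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            edge_p_values(1.0, df=0)


class TestFdrAdjust:
    def test_hand_step_up_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_value_unchanged(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_ties_map_to_common_value(self):
        assert np.allclose(fdr_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_matches_hand_oracle_on_random_lists(self, rng):
        def oracle(p):
            p = np.asarray(p, float)
            n = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(n)
            running = np.inf
            for rank in range(n - 1, -1, -1):
                i = order[rank]
                running = min(running, p[i] * n / (rank + 1))
                q[i] = min(running, 1.0)
            return q

        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(fdr_adjust(p), oracle(p))

    def test_monotone_in_p(self, rng):
        p = rng.random(50)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.5])


class TestScaleFactor:
    def test_exact_proportionality(self):
        rows = [(f"a{i}", "b", 2 * w, 2 * w, w, w)
                for i, w in enumerate(range(10, 60, 4))]
        df = paired_frame(rows)
        for space in ("log", "raw"):
            assert estimate_scale_factor(df, space=space) == pytest.approx(0.5, abs=1e-9)

    def test_identity(self):
        rows = [(f"a{i}", "b", w, w, w, w) for i, w in enumerate(range(10, 60, 4))]
        df = paired_frame(rows)
        for space in ("log", "raw"):
            assert estimate_scale_factor(df, space=space) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_rows_raises(self):
        df = paired_frame([("a", "b", 20, 20, 20, 20)])
        with pytest.raises(Exception, match="usable rows"):
            estimate_scale_factor(df)

    def test_recovery_within_five_percent(self, paired_default):
        male, female, truth = paired_default
        paired = build_paired_table(male, female)
        s = estimate_scale_factor(paired)
        assert abs(s / truth.true_scale - 1) < 0.05


class TestNoiseThreshold:
    def test_perfect_persistence_gives_one(self):
        rows = [(f"a{i}", "b", w, w, w, w) for i, w in enumerate(range(1, 40))]
        df = paired_frame(rows)
        assert estimate_noise_threshold(df, "male") == 1

    def test_zero_persistence_target_gives_one(self):
        rows = [(f"a{i}", "b", w, w, 0, 0) for i, w in enumerate(range(1, 40))]
        df = paired_frame(rows)
        assert estimate_noise_threshold(df, "male", persistence=0.0) == 1

    def test_unreachable_persistence_reports_maximum(self):
        rows = [(f"a{i}", "b", w, w, 0, 0) for i, w in enumerate(range(1, 40))]
        df = paired_frame(rows)
        with pytest.raises(Exception, match="attained maximum"):
            estimate_noise_threshold(df, "male", persistence=0.9)

    def test_matches_direct_counting_oracle_and_is_stable(self, paired_default):
        male, female, _ = paired_default
        paired = build_paired_table(male, female)
        tm = estimate_noise_threshold(paired, "male")
        tf = estimate_noise_threshold(paired, "female")
        assert abs(tm - tf) <= 3
        # direct-counting oracle for the male direction
        sub = paired[paired["matched"] & (paired["male_total"] > 0)]
        src = sub["male_total"].to_numpy()
        oth = sub["female_total"].to_numpy()
        w = 1
        while (oth[src >= w] > 0).mean() < 0.9:
            w += 1
        assert tm == w


class TestClassification:
    def test_below_both_thresholds_is_noisy(self):
        rows = [("a", "b", 2, 1, 1, 1)] + \
               [(f"s{i}", "t", 30, 30, 30, 30) for i in range(12)]
        res = classify_edges(paired_frame(rows), thresholds=(8, 11),
                             scale_factor=1.0)
        assert res.set_index(["pre", "post"]).loc[("a", "b"), "category"] == "noisy"

    def test_strong_identical_edge_is_isomorphic(self):
        rows = [(f"s{i}", "t", 30 + i, 30, 30 + i, 30) for i in range(12)]
        res = classify_edges(paired_frame(rows), scale_factor=1.0)
        assert (res["category"] == "isomorphic").all()
        assert (res["rel_diff"] == 0).all()

    def test_planted_recovery_fdr_and_recall(self):
        # recovery simulation against planted truth, 10 seeds
        from dimflow.synth import PairedGenConfig, generate_paired_connectomes
        recalls, fdrs = [], []
        for seed in range(10):
            m, f, truth = generate_paired_connectomes(PairedGenConfig(seed=seed))
            res = classify_edges(build_paired_table(m, f))
            ok = res[(res["category"] != "noisy") & res["matched"]]
            is_pl = np.array([truth.edge_dimorphism.get((r.pre, r.post), False)
                              for r in ok.itertuples()])
            call = (ok["category"] == "dimorphic").to_numpy()
            recalls.append((call & is_pl).sum() / is_pl.sum())
            fdrs.append((call & ~is_pl).sum() / max(call.sum(), 1))
        assert np.mean(recalls) >= 0.8
        assert np.mean(fdrs) <= 0.2

    def test_null_model_call_rate_controlled(self):
        from dimflow.synth import PairedGenConfig, generate_paired_connectomes
        rates = []
        for seed in range(10):
            cfg = PairedGenConfig(frac_dimorphic_edges=0.0, seed=seed)
            m, f, _ = generate_paired_connectomes(cfg)
            res = classify_edges(build_paired_table(m, f))
            tested = res["category"] != "noisy"
            rates.append((res["category"] == "dimorphic").sum() / tested.sum())
        assert np.mean(rates) <= 0.15


class TestReconciliation:
    def _ann(self):
        return pd.DataFrame({
            "type": ["iso1", "iso2", "dim1", "ss1"],
            "dimorphism": ["isomorphic", "isomorphic", "dimorphic",
                           "sex_specific"]})

    def _results(self, pre, post, category):
        return pd.DataFrame({"pre": [pre], "post": [post],
                             "category": [category]})

    def test_sex_specific_edge_forced_dimorphic(self):
        res = reconcile_with_type_labels(
            self._results("iso1", "ss1", "isomorphic"), self._ann())
        assert res["corrected_category"].iloc[0] == "dimorphic"

    def test_isomorphic_pair_reset_to_isomorphic(self):
        res = reconcile_with_type_labels(
            self._results("iso1", "iso2", "dimorphic"), self._ann())
        assert res["corrected_category"].iloc[0] == "isomorphic"

    def test_dimorphic_type_edge_is_fixed_point(self):
        res = reconcile_with_type_labels(
            self._results("iso1", "dim1", "dimorphic"), self._ann())
        assert res["corrected_category"].iloc[0] == "dimorphic"

    def test_noisy_untouched_even_for_sex_specific(self):
        res = reconcile_with_type_labels(
            self._results("iso1", "ss1", "noisy"), self._ann())
        assert res["corrected_category"].iloc[0] == "noisy"

    def test_missing_annotation_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            reconcile_with_type_labels(
                self._results("iso1", "unknown", "dimorphic"), self._ann())


class TestSummary:
    def _results(self, cats, male_tot, female_tot):
        n = len(cats)
        return pd.DataFrame({
            "pre": [f"p{i}" for i in range(n)],
            "post": [f"q{i}" for i in range(n)],
            "male_total": male_tot, "female_total": female_tot,
            "corrected_category": cats, "category": cats})

    def _ann(self, n):
        types = [f"p{i}" for i in range(n)] + [f"q{i}" for i in range(n)]
        return pd.DataFrame({"type": types, "dimorphism": "isomorphic"})

    def test_no_dimorphic_edges_all_zero(self):
        res = self._results(["isomorphic"] * 4, [10] * 4, [10] * 4)
        s = dimorphism_summary(res, self._ann(4))
        assert s.frac_dimorphic_edges_male == 0.0
        assert s.frac_dimorphic_synapses_female == 0.0
        assert not s.secondarily_dimorphic_types

    def test_all_dimorphic_saturates(self):
        res = self._results(["dimorphic"] * 4, [10] * 4, [10] * 4)
        s = dimorphism_summary(res, self._ann(4))
        assert s.frac_dimorphic_edges_male == 1.0
        assert s.frac_dimorphic_synapses_male == 1.0

    def test_noisy_edges_excluded_from_denominator(self):
        res = self._results(["dimorphic", "noisy", "isomorphic"],
                            [10, 5, 10], [10, 5, 10])
        s = dimorphism_summary(res, self._ann(3))
        assert s.frac_dimorphic_edges_male == pytest.approx(0.5)

    def test_summary_fraction_tracks_planted_fraction(self, paired_default):
        male, female, truth = paired_default
        ann = pd.concat([male.types, female.types], ignore_index=True)
        res = classify_edges(build_paired_table(male, female))
        res = reconcile_with_type_labels(res, ann)
        s = dimorphism_summary(res, ann)
        above = res[(res["category"] != "noisy") & (res["male_total"] > 0)]
        planted = np.array([truth.edge_dimorphism.get((r.pre, r.post), False)
                            for r in above.itertuples()]).mean()
        assert s.frac_dimorphic_edges_male == pytest.approx(planted, rel=0.2)
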