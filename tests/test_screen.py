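import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pathscreen as ps
from pathscreen.activity import ActivityMatrix
from pathscreen.screen import SENSITIVE, NOT_SENSITIVE, EXCLUDED, assign_tiers


class TestZscore:
    def test_hand_values(self):
        np.testing.assert_allclose(
            ps.zscore_transform(np.array([8.0, 12.0, 16.0])), [-1, 0, 1]
        )

    def test_constant_flagged(self):
        with pytest.raises(ValueError, match="zero spread"):
            ps.zscore_transform(np.full(5, 3.0))

    def test_normalization_identity(self):
        z = ps.zscore_transform(np.random.default_rng(0).normal(5, 2, 100))
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1)

    def test_missing_stays_missing(self):
        z = ps.zscore_transform(np.array([1.0, np.nan, 3.0, 5.0]))
        assert np.isnan(z[1]) and np.isfinite(z[[0, 2, 3]]).all()


class TestClassification:
    @pytest.mark.parametrize(
        "z,label",
        [(-1.5, SENSITIVE), (-1.51, SENSITIVE), (0.0, NOT_SENSITIVE),
         (0.2, NOT_SENSITIVE), (-0.7, EXCLUDED), (np.nan, EXCLUDED)],
    )
    def test_boundaries(self, z, label):
        assert ps.classify_sensitivity(np.array([z]))[0] == label

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            ps.classify_sensitivity(np.array([0.0]), sensitive_max=1.0, resistant_min=0.0)


class TestPromiscuityFilter:
    def _labels(self, n_sensitive, n_compounds=100):
        lab = pd.DataFrame(
            NOT_SENSITIVE, index=[f"d{i}" for i in range(n_compounds)],
            columns=["line1", "line2"], dtype=object,
        )
        lab.iloc[:n_sensitive, 0] = SENSITIVE
        return ps.SensitivityLabels(labels=lab)

    def test_over_threshold_removed(self):
        filtered, removed = ps.filter_promiscuous_cell_lines(self._labels(21))
        assert removed == ["line1"]
        assert filtered.cell_line_ids == ["line2"]

    def test_exactly_at_threshold_retained(self):
        _, removed = ps.filter_promiscuous_cell_lines(self._labels(20))
        assert removed == []

    def test_empty_screen_noop(self):
        lab = ps.SensitivityLabels(labels=pd.DataFrame(dtype=object))
        filtered, removed = ps.filter_promiscuous_cell_lines(lab)
        assert removed == [] and filtered.labels.empty


class TestPathwayVarianceFilter:
    def _activity(self, rows):
        df = pd.DataFrame(rows, columns=["s1", "s2"])
        df.index = [f"P{i}" for i in range(len(rows))]
        return ActivityMatrix(df, {p: 1.0 for p in df.index})

    def test_range_boundary(self):
        act = self._activity([[0.40, 0.50], [0.40, 0.501], [0.3, 0.3]])
        kept, dropped = ps.filter_low_variance_pathways(act)
        assert dropped == ["P0", "P2"]  # range 0.10 dropped, 0.101 kept
        assert kept.pathway_ids == ["P1"]


class TestCompoundFilter:
    def _resp(self, rows):
        df = pd.DataFrame(rows, columns=["c1", "c2"])
        df.index = [f"d{i}" for i in range(len(rows))]
        return ps.ResponseMatrix(df, kind="drug", tissue_of={"c1": "lung", "c2": "lung"})

    def test_min_auc_boundary(self):
        resp = self._resp([[8.5, 9.0], [8.0, 12.0], [2.0, 14.0]])
        kept = ps.filter_nonresponsive_compounds(resp, "lung")
        assert kept == ["d1", "d2"]  # min 8.5 omitted; min 8.0 and 2.0 retained

    def test_disabled_filter_keeps_all(self):
        resp = self._resp([[10.0, 12.0]])
        assert ps.filter_nonresponsive_compounds(resp, "lung", None) == ["d0"]


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        mask = np.array([True, True, False, False])
        u, p, direction = ps.mann_whitney_association(vals, mask)
        assert u == 0.0
        assert p == pytest.approx(2 / 6)
        assert direction == "low_activity_sensitive"

    def test_identical_groups_p_one(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        mask = np.array([True] * 3 + [False] * 3)
        _, p, _ = ps.mann_whitney_association(vals, mask)
        assert p == pytest.approx(1.0)

    def test_exact_matches_brute_force_with_ties(self):
        # independent oracle: enumerate all label assignments directly
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.integers(0, 5, size=10).astype(float)  # heavy ties
            mask = np.zeros(10, dtype=bool)
            mask[:4] = True
            u_obs, p, _ = ps.mann_whitney_association(vals, mask)
            from scipy.stats import rankdata

            ranks = rankdata(vals)
            mu = 4 * 6 / 2
            devs = []
            for combo in itertools.combinations(range(10), 4):
                u = ranks[list(combo)].sum() - 4 * 5 / 2
                devs.append(abs(u - mu))
            expected = np.mean(np.array(devs) >= abs(u_obs - mu) - 1e-9)
            assert p == pytest.approx(expected)

    def test_asymptotic_close_to_exact_at_8v8(self):
        # exhaustive over every possible tie-free 8v8 outcome: the
        # continuity-corrected normal approximation deviates from the exact
        # enumeration by at most 0.0109 (attained only at the distribution
        # center, p ~ 0.5); in the decision-relevant region p <= 0.25 the
        # agreement is within 0.01
        from scipy.stats import mannwhitneyu, rankdata

        vals = np.arange(16.0)
        ranks = rankdata(vals)
        mu = 8 * 8 / 2
        us, rep_mask = [], {}
        for combo in itertools.combinations(range(16), 8):
            u = ranks[list(combo)].sum() - 8 * 9 / 2
            us.append(u)
            if u not in rep_mask:
                mask = np.zeros(16, dtype=bool)
                mask[list(combo)] = True
                rep_mask[u] = mask
        us = np.array(us)
        for u, mask in rep_mask.items():
            p_exact = np.mean(np.abs(us - mu) >= abs(u - mu) - 1e-9)
            _, p_asym = mannwhitneyu(
                vals[mask], vals[~mask], alternative="two-sided",
                method="asymptotic", use_continuity=True,
            )
            assert abs(p_exact - p_asym) <= 0.011
            if p_exact <= 0.25:
                assert abs(p_exact - p_asym) < 0.01


class TestBH:
    def test_hand_stepup(self):
        q = ps.bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_p(self):
        assert ps.bh_fdr(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(ps.bh_fdr(np.ones(5)), np.ones(5))

    def test_external_family_size(self):
        np.testing.assert_allclose(ps.bh_fdr(np.array([0.01]), m=10), [0.1])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ps.bh_fdr(np.array([0.1, 1.2]))

    @given(
        p=st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                   min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        q = ps.bh_fdr(np.array(p))
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)

    def test_rejections_match_direct_stepup(self):
        rng = np.random.default_rng(3)
        p = rng.random(50) ** 2
        q = ps.bh_fdr(p)
        for alpha in (0.05, 0.25):
            # direct step-up oracle
            srt = np.sort(p)
            passing = np.nonzero(srt <= alpha * np.arange(1, 51) / 50)[0]
            k = (passing[-1] + 1) if len(passing) else 0
            assert (q <= alpha).sum() == k


class TestRunScreen:
    def test_planted_association_ranks_first(self, planted_pipeline):
        act = planted_pipeline["activity"]
        expr = planted_pipeline["expr"]
        resp, truth = ps.generate_drug_screen(
            act, expr.tissue_of(), n_compounds=10,
            planted=[("tissueA", act.pathway_ids[0], "low_activity_sensitive")],
            seed=11,
        )
        res = ps.run_screen(act, resp).results
        planted = truth.planted_associations[0]
        best = res.sort_values(["q_value", "p_value"]).iloc[0]
        assert (best["pathway_id"], best["entity_id"]) == (
            planted["pathway_id"], planted["entity_id"]
        )
        assert best["direction"] == planted["direction"]

    def test_single_valid_test_q_equals_p(self):
        rng = np.random.default_rng(8)
        act = ActivityMatrix(
            pd.DataFrame([np.r_[rng.uniform(0, 0.3, 5), rng.uniform(0.7, 1.0, 15)]],
                         index=["P0"], columns=[f"c{i}" for i in range(20)]),
            {"P0": 1.0},
        )
        auc = np.r_[rng.normal(4, 0.5, 5), rng.normal(12, 0.5, 15)]
        resp = ps.ResponseMatrix(
            pd.DataFrame([auc], index=["d0"], columns=act.sample_ids),
            kind="drug", tissue_of={c: "lung" for c in act.sample_ids},
        )
        # a one-compound screen makes every sensitive line look promiscuous,
        # so that filter is relaxed to isolate the single-test case
        cfg = ps.ScreenConfig(promiscuity_max_fraction=1.0)
        res = ps.run_screen(act, resp, cfg).results
        assert len(res) == 1
        assert res.loc[0, "q_value"] == pytest.approx(res.loc[0, "p_value"])

    def test_no_overlap_rejected(self, planted_pipeline):
        act = planted_pipeline["activity"]
        resp = ps.ResponseMatrix(
            pd.DataFrame([[1.0]], index=["d"], columns=["other"]),
            kind="drug", tissue_of={"other": "lung"},
        )
        with pytest.raises(ValueError, match="overlap"):
            ps.run_screen(act, resp)

    def test_filter_order_invariance(self, planted_pipeline):
        # pathway-variance filtering commutes with classification
        act = planted_pipeline["activity"]
        expr = planted_pipeline["expr"]
        resp, _ = ps.generate_drug_screen(
            act, expr.tissue_of(), n_compounds=5,
            planted=[("tissueA", act.pathway_ids[1], "high_activity_sensitive")],
            seed=3,
        )
        pre_filtered, _ = ps.filter_low_variance_pathways(act, 0.1)
        res_a = ps.run_screen(act, resp).results
        res_b = ps.run_screen(pre_filtered, resp).results
        pd.testing.assert_frame_equal(res_a, res_b)

    def test_tiers_consistent_with_q(self):
        q = np.array([0.01, 0.05, 0.13, 0.25, 0.251, 0.9])
        assert list(assign_tiers(q)) == [
            "significant", "significant", "near_significant", "near_significant",
            "none", "none",
        ]


class TestFDRControl:
    def test_null_screens_control_fdr(self, planted_pipeline, null_screen_config):
        # null screens on 30 cell lines: activity is real, responses pure
        # noise, so every q <= 0.05 call is a false discovery
        act_full = planted_pipeline["activity"]
        lines = act_full.sample_ids[:30]
        act = ActivityMatrix(act_full.values[lines], act_full.coverage)
        tissue_of = {c: "tissueA" for c in lines}
        fdp = []
        for seed in range(30):
            resp, _ = ps.generate_drug_screen(
                act, tissue_of, n_compounds=20, planted=[], seed=1000 + seed
            )
            res = ps.run_screen(act, resp, null_screen_config).results
            n_disc = int((res["q_value"] <= 0.05).sum()) if len(res) else 0
            fdp.append(n_disc / max(len(res), 1) if n_disc else 0.0)
        assert np.mean(fdp) <= 0.10


class TestIntersect:
    def _table(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["tissue", "pathway_id", "entity_id", "q_value", "direction"],
        )
        df["n_sensitive"] = 5
        df["n_not_sensitive"] = 10
        df["u_statistic"] = 1.0
        df["p_value"] = df["q_value"] / 2
        df["tier"] = "significant"
        return ps.ResultsTable(results=df)

    def test_identical_tables_intersect_to_hits(self):
        t = self._table([["lung", "P1", "d1", 0.01, "low_activity_sensitive"],
                         ["lung", "P2", "d1", 0.5, "low_activity_sensitive"]])
        out = ps.cross_platform_intersect(t, t)
        assert len(out) == 1
        assert out.provenance["n_overlap"] == 1

    def test_opposite_direction_excluded(self):
        a = self._table([["lung", "P1", "d1", 0.01, "low_activity_sensitive"]])
        b = self._table([["lung", "P1", "d1", 0.01, "high_activity_sensitive"]])
        assert len(ps.cross_platform_intersect(a, b)) == 0

    def test_disjoint_hit_sets_empty_with_counts(self):
        a = self._table([["lung", "P1", "d1", 0.01, "low_activity_sensitive"]])
        b = self._table([["skin", "P2", "d2", 0.01, "low_activity_sensitive"]])
        out = ps.cross_platform_intersect(a, b)
        assert len(out) == 0
        assert (out.provenance["n_a"], out.provenance["n_b"]) == (1, 1)
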