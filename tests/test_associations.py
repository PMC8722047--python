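"""Association engine: BH, OLS/logistic screens, filters, network, CERES."""

import numpy as np
import pandas as pd
import pytest

from immunoscreen.associations import (associate_features, bh_adjust,
                                       count_related_features,
                                       filter_functional_regulators,
                                       fit_linear_association,
                                       fit_logistic_association,
                                       og_tsg_network,
                                       proliferation_independent,
                                       subtype_specific_genes)


def _bh_oracle(p):
    """Step-up: sort, multiply by m/rank, running min from the top."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = min(val, 1.0)
        prev = adj[i]
    return adj


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_nan_passes_through(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], _bh_oracle([0.01, 0.04]))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 200)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 157)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestFitLinearAssociation:
    def test_matches_closed_form_ols(self):
        """Slope and t-test p against the normal-equations solution."""
        rng = np.random.default_rng(4)
        from scipy import stats as st

        for _ in range(20):
            n = 40
            status = rng.integers(0, 2, n).astype(float)
            ct = rng.choice(["a", "b"], n)
            y = pd.Series(rng.normal(0, 1, n), index=range(n))
            cov = pd.DataFrame({"cancer_type": ct}, index=y.index)
            res = fit_linear_association(y, status, cov)
            X = np.column_stack([np.ones(n), status, (ct == "a").astype(float)
                                 if (ct == "b").sum() >= (ct == "a").sum()
                                 else (ct == "b").astype(float)])
            beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
            resid = y.to_numpy() - X @ beta
            dof = n - X.shape[1]
            sigma2 = resid @ resid / dof
            cov_beta = sigma2 * np.linalg.inv(X.T @ X)
            t = beta[1] / np.sqrt(cov_beta[1, 1])
            p = 2 * st.t.sf(abs(t), dof)
            assert res["coef"] == pytest.approx(beta[1], abs=1e-8)
            assert res["p"] == pytest.approx(p, abs=1e-8)

    def test_recovers_planted_negative_effect(self):
        """y = -0.8*status + cancer offsets + N(0, 0.1), n=300."""
        rng = np.random.default_rng(8)
        n = 300
        status = (rng.random(n) < 0.3).astype(float)
        ct = rng.choice(["a", "b", "c"], n)
        offsets = {"a": 0.0, "b": 1.0, "c": -0.5}
        y = pd.Series(-0.8 * status + np.vectorize(offsets.get)(ct)
                      + rng.normal(0, 0.1, n))
        res = fit_linear_association(y, status,
                                     pd.DataFrame({"cancer_type": ct}, index=y.index))
        assert res["coef"] == pytest.approx(-0.8, abs=0.1)
        assert res["p"] < 1e-10

    def test_null_effect_calibration(self):
        """Status orthogonal to y: slope within 3 SE of zero in >=95% of seeds."""
        from scipy import stats as st

        hits = 0
        n = 300
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            status = (rng.random(n) < 0.4).astype(float)
            y = pd.Series(rng.normal(0, 1, n))
            res = fit_linear_association(y, status, None)
            # reconstruct SE from the p-value and dof
            t = abs(st.t.isf(res["p"] / 2, n - 2))
            se = abs(res["coef"]) / t if t > 0 else np.inf
            if abs(res["coef"]) < 3 * se:
                hits += 1
        assert hits >= 0.95 * 40

    def test_constant_response_contract(self):
        y = pd.Series([2.0] * 30)
        status = np.array([0, 1] * 15, dtype=float)
        res = fit_linear_association(y, status, None)
        assert res["coef"] == 0.0 and res["p"] == 1.0

    def test_single_class_status_flagged(self):
        y = pd.Series(np.arange(20, dtype=float))
        res = fit_linear_association(y, np.zeros(20), None)
        assert res["flag"] == "insufficient_events" and np.isnan(res["p"])


def _assoc_row(gene, target, coef, adj_p):
    return {"gene": gene, "target": target, "target_class": "signature",
            "coef": coef, "p": adj_p, "adj_p": adj_p, "n": 100, "flag": "ok"}


class TestFilterFunctionalRegulators:
    def _catalog(self, roles):
        from immunoscreen.screens import RegulatorCatalog

        tab = pd.DataFrame({"role": pd.Series(roles),
                            "support": [["A", "B"]] * len(roles),
                            "n_screens": 2})
        tab.index.name = "gene"
        return RegulatorCatalog(table=tab)

    def test_consistent_sensitizer_kept(self):
        assoc = pd.DataFrame([_assoc_row("g", s, c, 0.01) for s, c in
                              [("immune", -0.3), ("CYT", -0.2), ("MHC", -0.4)]])
        kept = filter_functional_regulators(assoc, self._catalog({"g": "sensitizer"}))
        assert list(kept.table.index) == ["g"]

    def test_one_wrong_sign_drops_sensitizer(self):
        assoc = pd.DataFrame([_assoc_row("g", s, c, 0.01) for s, c in
                              [("immune", -0.3), ("CYT", +0.2), ("MHC", -0.4)]])
        kept = filter_functional_regulators(assoc, self._catalog({"g": "sensitizer"}))
        assert len(kept.table) == 0

    def test_one_nonsignificant_drops_resistor(self):
        assoc = pd.DataFrame([_assoc_row("g", s, 0.3, p) for s, p in
                              [("immune", 0.01), ("CYT", 0.01), ("MHC", 0.06)]])
        kept = filter_functional_regulators(assoc, self._catalog({"g": "resistor"}))
        assert len(kept.table) == 0

    def test_missing_signature_record_excludes_gene(self):
        assoc = pd.DataFrame([_assoc_row("g", "immune", -0.3, 0.01)])
        kept = filter_functional_regulators(assoc, self._catalog({"g": "sensitizer"}))
        assert len(kept.table) == 0


class TestSubtypeSpecific:
    def test_planted_subtype_enrichment_recovered(self):
        """Event rate 0.4 in C5 vs 0.05 elsewhere; true log2 OR ~ 3.66."""
        rng = np.random.default_rng(12)
        n = 600
        subtypes = pd.Series(rng.choice(["C1", "C2", "C3", "C4", "C5", "C6"], n),
                             index=[f"s{i}" for i in range(n)])
        rate = np.where(subtypes == "C5", 0.4, 0.05)
        status = pd.DataFrame([(rng.random(n) < rate).astype(int)],
                              index=["g"], columns=subtypes.index)
        tab = subtype_specific_genes(status, subtypes)
        hit = tab[(tab["gene"] == "g") & (tab["target"] == "C5")].iloc[0]
        assert hit["specific"]
        assert hit["log2_or"] == pytest.approx(np.log2((0.4 / 0.6) / (0.05 / 0.95)),
                                               abs=1.0)
        others = tab[(tab["gene"] == "g") & (tab["target"] != "C5")]
        assert not others["specific"].any()

    def test_uniform_event_rate_never_flagged(self):
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            n = 300
            subtypes = pd.Series(rng.choice(["C1", "C2", "C3"], n),
                                 index=[f"s{i}" for i in range(n)])
            status = pd.DataFrame([(rng.random(n) < 0.2).astype(int)],
                                  index=["g"], columns=subtypes.index)
            tab = subtype_specific_genes(status, subtypes)
            assert not tab["specific"].any()

    def test_zero_event_gene_flagged_insufficient(self):
        subtypes = pd.Series(["C1"] * 10 + ["C2"] * 10,
                             index=[f"s{i}" for i in range(20)])
        status = pd.DataFrame([np.zeros(20, dtype=int)], index=["g"],
                              columns=subtypes.index)
        tab = subtype_specific_genes(status, subtypes)
        assert (tab["flag"] == "insufficient_events").all()
        assert not tab["specific"].any()

    def test_perfect_separation_has_no_infinite_or(self):
        res = fit_logistic_association(
            outcome=np.array([1] * 10 + [0] * 10),
            predictor=np.array([1] * 10 + [0] * 10))
        assert res["flag"] == "separation" and np.isnan(res["log2_or"])


class TestCountRelatedFeatures:
    ROLES = {"s1": "sensitizer", "r1": "resistor"}
    POLARITY = pd.Series({"fA": "anti_tumor", "fP": "pro_tumor"})

    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["gene", "target", "cancer_type",
                                           "coef", "adj_p"])

    def test_sensitizer_counts_matching_directions(self):
        assoc = self._assoc([("s1", "fA", "skin", -0.5, 0.01),
                             ("s1", "fP", "skin", +0.3, 0.01)])
        out = count_related_features(assoc, self.ROLES, self.POLARITY)
        assert out.set_index("gene").loc["s1", "n_related"] == 2

    def test_wrong_direction_not_counted(self):
        assoc = self._assoc([("s1", "fA", "skin", +0.5, 0.01)])
        out = count_related_features(assoc, self.ROLES, self.POLARITY)
        assert out.set_index("gene").loc["s1", "n_related"] == 0

    def test_total_is_sum_over_cancer_types(self):
        assoc = self._assoc([("s1", "fA", "skin", -0.5, 0.01),
                             ("s1", "fA", "breast", -0.5, 0.01),
                             ("s1", "fA", "colon", -0.5, 0.5),
                             ("r1", "fA", "skin", +0.4, 0.01)])
        total = count_related_features(assoc, self.ROLES, self.POLARITY)
        per = count_related_features(assoc, self.ROLES, self.POLARITY,
                                     per_cancer=True)
        merged = per.groupby("gene")["n_related"].sum()
        for g in ("s1", "r1"):
            assert total.set_index("gene").loc[g, "n_related"] == merged[g]
        assert total.set_index("gene").loc["s1", "n_related"] == 2

    def test_resistor_mirror_rule(self):
        assoc = self._assoc([("r1", "fA", "skin", +0.4, 0.01),
                             ("r1", "fP", "skin", -0.4, 0.01),
                             ("r1", "fP", "skin", +0.4, 0.01)])
        out = count_related_features(assoc, self.ROLES, self.POLARITY)
        assert out.set_index("gene").loc["r1", "n_related"] == 2


class TestOgTsgNetwork:
    def _setup(self, lfc, seed=0, n=400):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        ev = rng.random(n) < 0.3
        expr = pd.DataFrame([rng.normal(0, 0.5, n) + lfc * ev],
                            index=["REG"], columns=samples)
        status = pd.DataFrame([ev.astype(int)], index=["DRV"], columns=samples)
        return expr, status

    def test_planted_downregulation_gives_sensitizer_edge(self):
        expr, status = self._setup(-0.6)
        net = og_tsg_network(expr, status, {"DRV": "TSG"}, {"REG": "sensitizer"})
        assert net.iloc[0]["edge"]

    def test_small_lfc_below_threshold_gives_no_edge(self):
        expr, status = self._setup(-0.2)
        net = og_tsg_network(expr, status, {"DRV": "TSG"}, {"REG": "sensitizer"})
        assert not net.iloc[0]["edge"]

    def test_upregulated_resistor_edge(self):
        expr, status = self._setup(+0.6)
        net = og_tsg_network(expr, status, {"DRV": "OG"}, {"REG": "resistor"})
        assert net.iloc[0]["edge"]

    def test_direction_mismatch_gives_no_edge(self):
        expr, status = self._setup(+0.6)
        net = og_tsg_network(expr, status, {"DRV": "OG"}, {"REG": "sensitizer"})
        assert not net.iloc[0]["edge"]


class TestProliferationIndependent:
    DEP = pd.DataFrame({"c1": [-0.1, -0.35, 0.25, 0.5],
                        "c2": [0.1, -0.25, 0.25, 0.4]},
                       index=["zero", "essential", "edge", "growth"])

    def test_zero_mean_kept(self):
        assert "zero" in proliferation_independent(self.DEP)

    def test_negative_mean_excluded(self):
        assert "essential" not in proliferation_independent(self.DEP)

    def test_boundary_inclusive(self):
        assert "edge" in proliferation_independent(self.DEP)

    def test_positive_mean_excluded(self):
        assert "growth" not in proliferation_independent(self.DEP)

    def test_bad_interval_errors(self):
        with pytest.raises(ValueError):
            proliferation_independent(self.DEP, low=0.3, high=0.1)
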