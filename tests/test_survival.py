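"""CTIS scoring, Cox screening, log-rank, C-index, AUC, panel search."""

import numpy as np
import pandas as pd
import pytest

from immunoscreen.survival import (CTISPanel, concordance_index, cox_screen,
                                   ctis_score, logrank_test, roc_auc,
                                   select_panel_greedy)
from immunoscreen.simulate import SyntheticSpec, make_survival


def _expr(values: dict, samples):
    return pd.DataFrame(values, index=samples).T


class TestCtisScore:
    PANEL = CTISPanel(sensitizers=("S1", "S2"), resistors=("R1",))

    def test_symmetric_input_is_zero(self):
        expr = _expr({"S1": [2.0, 2.0], "S2": [2.0, 2.0], "R1": [2.0, 2.0]},
                     ["a", "b"])
        out = ctis_score(expr, self.PANEL, scale="raw")
        np.testing.assert_allclose(out, 0.0)

    def test_mean_difference(self):
        expr = _expr({"S1": [3.0], "S2": [3.0], "R1": [1.0]}, ["a"])
        assert ctis_score(expr, self.PANEL, scale="raw")["a"] == pytest.approx(2.0)

    def test_hand_computed_six_gene_vector(self):
        panel = CTISPanel(sensitizers=("A", "B", "C", "D"), resistors=("E", "F"))
        expr = _expr({"A": [1.0], "B": [2.0], "C": [3.0], "D": [4.0],
                      "E": [1.0], "F": [5.0]}, ["x"])
        assert ctis_score(expr, panel, scale="raw")["x"] == pytest.approx(2.5 - 3.0)

    def test_gene_order_within_halves_is_irrelevant(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(8)]
        expr = pd.DataFrame(rng.normal(0, 1, (4, 8)),
                            index=["A", "B", "C", "D"], columns=samples)
        p1 = CTISPanel(sensitizers=("A", "B"), resistors=("C", "D"))
        p2 = CTISPanel(sensitizers=("B", "A"), resistors=("D", "C"))
        np.testing.assert_allclose(ctis_score(expr, p1), ctis_score(expr, p2))

    def test_missing_genes_listed_in_error(self):
        expr = _expr({"S1": [1.0]}, ["a"])
        with pytest.raises(KeyError, match="S2"):
            ctis_score(expr, self.PANEL)

    def test_overlapping_panel_halves_rejected(self):
        with pytest.raises(ValueError):
            CTISPanel(sensitizers=("A",), resistors=("A",))


class TestCoxScreen:
    def test_constant_predictor_errors(self):
        surv = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 0, 1]},
                            index=list("abcd"))
        with pytest.raises(ValueError):
            cox_screen(pd.Series([1.0] * 4, index=list("abcd")), surv,
                       covariate_cols=())

    def test_recovers_planted_log_hazard(self):
        """Mean estimate over 10 seeds within +/-0.15 of the true -0.7."""
        ests = []
        for seed in range(1, 11):
            spec = SyntheticSpec(seed=seed, n_samples=500)
            rng = np.random.default_rng(1000 + seed)
            score = pd.Series(rng.normal(0, 1, 500),
                              index=[f"s{i}" for i in range(500)])
            surv = make_survival(spec, score)
            res = cox_screen(score, surv, covariate_cols=())
            assert res["flag"] == "ok"
            ests.append(res["coef"])
            assert res["coef"] == pytest.approx(-0.7, abs=0.3)  # per-seed sanity
        assert np.mean(ests) == pytest.approx(-0.7, abs=0.15)

    def test_null_predictor_ci_covers_one(self):
        """HR confidence interval contains 1 in >=90% of 20 seeds."""
        covered = 0
        for seed in range(20):
            spec = SyntheticSpec(seed=seed, n_samples=300, log_hr=0.0)
            rng = np.random.default_rng(2000 + seed)
            score = pd.Series(rng.normal(0, 1, 300),
                              index=[f"s{i}" for i in range(300)])
            surv = make_survival(spec, score)
            res = cox_screen(score, surv, covariate_cols=())
            if res["ci_low"] <= 1.0 <= res["ci_high"]:
                covered += 1
        assert covered >= 18

    def test_insufficient_events_flagged(self):
        surv = pd.DataFrame({"time": np.arange(1.0, 21), "event": [0] * 20},
                            index=[f"s{i}" for i in range(20)])
        x = pd.Series(np.random.default_rng(0).normal(size=20), index=surv.index)
        assert cox_screen(x, surv, covariate_cols=())["flag"] == "insufficient_events"


def _logrank_oracle(time, event, group):
    """Risk-table computation of the two-group log-rank statistic."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    g1 = group == np.unique(group)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_give_zero(self):
        time = [1, 2, 3, 1, 2, 3]
        event = [1, 1, 0, 1, 1, 0]
        group = ["a", "a", "a", "b", "b", "b"]
        chi2, p = logrank_test(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_toy_example_matches_risk_table_oracle(self):
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        event = [1, 1, 1, 1, 0, 1]
        group = ["a", "b", "a", "b", "a", "b"]
        chi2, _ = logrank_test(time, event, group)
        assert chi2 == pytest.approx(_logrank_oracle(time, event, group), abs=1e-8)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


def _cindex_oracle(score, time, event):
    num, den = 0.0, 0
    n = len(score)
    for i in range(n):
        for j in range(n):
            if i == j or not event[i] or not (time[i] < time[j]):
                continue
            den += 1
            if score[j] > score[i]:
                num += 1.0
            elif score[j] == score[i]:
                num += 0.5
    return num / den


def _auc_oracle(score, label):
    pos = [s for s, l in zip(score, label) if l]
    neg = [s for s, l in zip(score, label) if not l]
    num = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return num / (len(pos) * len(neg))


class TestConcordanceAndAuc:
    def test_perfectly_concordant_is_one(self):
        assert concordance_index([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_three_subject_half_concordant(self):
        # events at t=1 (score 2) and t=2 (score 1): pair (1,2) discordant,
        # pair (1,3) concordant, pair (2,3) discordant -> need exact toy:
        score = [2.0, 1.0, 3.0]
        time = [1.0, 2.0, 3.0]
        event = [1, 1, 1]
        assert concordance_index(score, time, event) == pytest.approx(
            _cindex_oracle(score, time, event))

    def test_all_tied_scores_give_half(self):
        assert concordance_index([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 0]) == 0.5

    def test_matches_pair_enumeration_on_random_small_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(3, 13))
            score = rng.choice([0.0, 0.5, 1.0, 2.0], n)
            time = rng.choice(np.arange(1.0, 7.0), n)
            event = rng.integers(0, 2, n)
            if not event.any():
                continue
            try:
                ours = concordance_index(score, time, event)
            except ValueError:
                assert _safe_den(time, event) == 0
                continue
            assert ours == pytest.approx(_cindex_oracle(score, time, event),
                                         abs=1e-12)

    def test_matches_lifelines_on_untied_times(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(10)
        score = rng.normal(0, 1, 60)
        time = rng.permutation(np.arange(1.0, 61.0))
        event = rng.integers(0, 2, 60)
        event[0] = 1
        assert concordance_index(score, time, event) == pytest.approx(
            ll_cindex(time, score, event), abs=1e-12)

    def test_perfectly_separated_auc(self):
        assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_constant_score_auc_half(self):
        assert roc_auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_auc_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            score = rng.choice([0.0, 0.5, 1.0], n)
            label = rng.integers(0, 2, n)
            if label.all() or not label.any():
                continue
            assert roc_auc(score, label) == pytest.approx(
                _auc_oracle(score, label), abs=1e-12)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        score = rng.normal(0, 1, 80)
        label = rng.integers(0, 2, 80)
        assert roc_auc(score, label) == pytest.approx(
            roc_auc_score(label, score), abs=1e-12)

    def test_single_class_auc_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


def _safe_den(time, event):
    den = 0
    for i in range(len(time)):
        if event[i]:
            den += int((np.asarray(time) > time[i]).sum())
    return den


class TestSelectPanelGreedy:
    def _cohort(self, seed, beta=2.0, n=600, n_cand=40):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        genes = [f"C{i:02d}" for i in range(n_cand)]
        expr = pd.DataFrame(rng.normal(0, 1, (n_cand, n)), index=genes,
                            columns=samples)
        roles = {g: ("sensitizer" if i % 2 == 0 else "resistor")
                 for i, g in enumerate(genes)}
        sens_pool = [g for i, g in enumerate(genes) if i % 2 == 0]
        res_pool = [g for i, g in enumerate(genes) if i % 2 == 1]
        sens_p = sens_pool[:min(4, len(sens_pool))]
        res_p = res_pool[:min(2, len(res_pool))]
        planted = sens_p + res_p
        score = expr.loc[sens_p].mean(axis=0) - expr.loc[res_p].mean(axis=0)
        spec = SyntheticSpec(seed=seed, n_samples=n, log_hr=beta)
        surv = make_survival(spec, score)
        return genes, roles, expr, surv, planted

    def test_recovers_signal_genes(self):
        """>=5 of the 6 planted survival genes found in >=8 of 10 seeds."""
        good = 0
        for seed in range(10):
            genes, roles, expr, surv, planted = self._cohort(seed)
            panel = select_panel_greedy(genes, roles, expr, surv, k=6, seed=seed)
            found = set(panel.sensitizers) | set(panel.resistors)
            if len(found & set(planted)) >= 5:
                good += 1
        assert good >= 8

    def test_k_equals_pool_returns_everything(self):
        genes, roles, expr, surv, _ = self._cohort(0, n=100, n_cand=6)
        panel = select_panel_greedy(genes, roles, expr, surv, k=6)
        assert set(panel.sensitizers) | set(panel.resistors) == set(genes)

    def test_k_exceeding_pool_errors(self):
        genes, roles, expr, surv, _ = self._cohort(0, n=60, n_cand=4)
        with pytest.raises(ValueError):
            select_panel_greedy(genes, roles, expr, surv, k=10)

    def test_signal_free_cohort_has_chance_level_holdout_cindex(self):
        """Panels picked on noise score ~0.5 held-out C-index on fresh samples."""
        vals = []
        for seed in range(5):
            genes, roles, expr, surv, _ = self._cohort(seed, beta=0.0, n=500)
            train = expr.columns[:250]
            test = expr.columns[250:]
            panel = select_panel_greedy(genes, roles, expr[train],
                                        surv.loc[train], k=6, seed=seed)
            score = ctis_score(expr[test], panel)
            vals.append(concordance_index(score.to_numpy(),
                                          surv.loc[test, "time"].to_numpy(),
                                          surv.loc[test, "event"].to_numpy()))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)
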