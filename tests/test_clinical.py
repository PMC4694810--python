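import networkx as nx
import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from lfsn import ScenarioConfig, generate
from lfsn.clinical import (
    cancer_associated,
    cluster_samples,
    cox_multivariate,
    logrank,
    map_known_lncRNAs,
    mcl,
    prognostic_modules,
)
from lfsn.hallmark import hallmark_subnetworks
from lfsn.io_formats import ClinicalTable, ExpressionMatrix, GenomicInterval


def _clinical(times, events, n_cov=True):
    n = len(times)
    cov = pd.DataFrame({"age": np.linspace(50, 70, n)}) if n_cov else pd.DataFrame(index=range(n))
    return ClinicalTable([f"s{i}" for i in range(n)], np.asarray(times, float),
                         np.asarray(events, int), cov)


class TestCancerAssociated:
    def test_cox_recovers_risk_module_lncs(self, default_bundle):
        res = cancer_associated(default_bundle.lnc_expr, clinical=default_bundle.clinical,
                                mode="cox")
        risk = default_bundle.risk_module_lncs
        recall = len(res.lncs & risk) / len(risk)
        assert recall >= 0.8

    def test_cox_null_selection_near_alpha(self):
        fracs = []
        for seed in (21, 22):
            b = generate(ScenarioConfig(risk_effect=0.0, seed=seed))
            res = cancer_associated(b.lnc_expr, clinical=b.clinical, mode="cox")
            fracs.append(len(res.lncs) / b.lnc_expr.n_entities)
        assert np.mean(fracs) < 0.15  # raw p < 0.05 gate, binomial noise at n=60

    def test_constant_lncRNA_skipped_not_fatal(self, default_bundle):
        vals = default_bundle.lnc_expr.values.copy()
        vals[0, :] = 5.0
        expr = ExpressionMatrix(default_bundle.lnc_expr.entity_ids,
                                default_bundle.lnc_expr.sample_ids, vals)
        res = cancer_associated(expr, clinical=default_bundle.clinical, mode="cox")
        assert expr.entity_ids[0] in res.skipped

    def test_cox_requires_events(self):
        clin = _clinical([5, 6, 7, 8], [0, 0, 0, 0])
        expr = ExpressionMatrix(["l1"], clin.sample_ids, np.arange(4.0)[None, :])
        with pytest.raises(ValueError, match="events"):
            cancer_associated(expr, clinical=clin, mode="cox")

    def test_de_mode_bonferroni(self):
        rng = np.random.default_rng(0)
        n = 40
        labels = {f"s{i}": int(i >= n // 2) for i in range(n)}
        vals = rng.standard_normal((30, n))
        vals[0, n // 2:] += 4.0  # strongly differential lncRNA
        expr = ExpressionMatrix([f"l{i}" for i in range(30)], [f"s{i}" for i in range(n)], vals)
        res = cancer_associated(expr, labels=labels, mode="de")
        assert "l0" in res.lncs
        assert len(res.lncs) <= 3  # null lncRNAs rarely clear Bonferroni 0.01


class TestMapKnown:
    def test_identical_intervals_match(self):
        known = [GenomicInterval("K1", "chr1", 100, 1100)]
        measured = [GenomicInterval("lncA", "chr1", 100, 1100)]
        assert map_known_lncRNAs(known, measured) == {"K1": "lncA"}

    def test_nested_short_interval_fails_reciprocity(self):
        known = [GenomicInterval("K1", "chr1", 0, 1000)]
        measured = [GenomicInterval("lncA", "chr1", 0, 2000)]
        assert map_known_lncRNAs(known, measured) == {}

    def test_90_percent_reciprocal_overlap_matches(self):
        known = [GenomicInterval("K1", "chr1", 0, 1000)]
        measured = [GenomicInterval("lncA", "chr1", 100, 1100)]
        assert map_known_lncRNAs(known, measured) == {"K1": "lncA"}


class TestMCL:
    def test_disjoint_triangles_recovered(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
        clusters = mcl(g)
        assert set(clusters) == {frozenset("abc"), frozenset("xyz")}

    def test_single_edge_single_cluster(self):
        assert mcl(nx.Graph([("a", "b")])) == [frozenset({"a", "b"})]

    def test_deterministic(self):
        g = nx.barabasi_albert_graph(20, 2, seed=7)
        assert mcl(g) == mcl(g)

    def test_every_node_assigned(self):
        g = nx.gnp_random_graph(15, 0.2, seed=4)
        clusters = mcl(g)
        assert set().union(*clusters) == set(g.nodes())


class TestClusterSamples:
    def _expr(self, X):
        return ExpressionMatrix([f"l{i}" for i in range(X.shape[0])],
                                [f"s{j}" for j in range(X.shape[1])], X)

    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        truth = np.array([0] * 30 + [1] * 30)
        X = rng.standard_normal((3, 60)) + 5.0 * truth  # Δmean = 5 sd
        labels = cluster_samples(self._expr(X), seed=0)
        agreement = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
        assert agreement >= 0.95

    def test_duplicated_samples_co_clustered(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((2, 10))
        Xdup = np.hstack([X, X])
        labels = cluster_samples(self._expr(Xdup), seed=0)
        assert np.array_equal(labels[:10], labels[10:])

    def test_two_point_exact_split(self):
        X = np.array([[0.0, 0.0, 5.0, 5.0], [0.0, 0.0, 5.0, 5.0]])
        labels = cluster_samples(self._expr(X), seed=0)
        assert labels.tolist() == [0, 0, 1, 1]

    def test_group_one_is_high_expression(self):
        X = np.array([[0.0, 0.0, 5.0, 5.0, 0.1, 4.9], [0.0, 0.1, 5.0, 5.1, 0.0, 5.0]])
        labels = cluster_samples(self._expr(X), seed=0)
        assert X[:, labels == 1].mean() > X[:, labels == 0].mean()

    def test_identical_samples_rejected(self):
        X = np.ones((2, 6))
        with pytest.raises(ValueError, match="degenerate"):
            cluster_samples(self._expr(X), seed=0)

    def test_ward_variant_available(self):
        rng = np.random.default_rng(2)
        truth = np.array([0] * 20 + [1] * 20)
        X = rng.standard_normal((3, 40)) + 5.0 * truth
        labels = cluster_samples(self._expr(X), seed=0, method="ward")
        agreement = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
        assert agreement >= 0.95


def logrank_oracle(times, events, labels):
    """From-scratch observed-minus-expected log-rank computation."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    labels = np.asarray(labels, int)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n_j = at_risk.sum()
        n1 = (at_risk & (labels == 1)).sum()
        d_j = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (labels == 1)).sum()
        o_minus_e += d1 - d_j * n1 / n_j
        if n_j > 1:
            var += d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_p_one(self):
        times = [3, 5, 7, 3, 5, 7]
        events = [1, 1, 0, 1, 1, 0]
        labels = [0, 0, 0, 1, 1, 1]
        stat, p = logrank(np.array(labels), _clinical(times, events))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_oracle_six_subjects(self):
        times = [2, 4, 5, 6, 9, 11]
        events = [1, 1, 1, 1, 0, 1]
        labels = np.array([1, 0, 1, 0, 1, 0])
        stat, _ = logrank(labels, _clinical(times, events))
        assert stat == pytest.approx(logrank_oracle(times, events, labels), abs=1e-10)

    def test_power_under_strong_hazard_ratio(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_sim = 100
        for _ in range(n_sim):
            labels = np.array([0] * 50 + [1] * 50)
            lam = np.where(labels == 1, 3.0, 1.0)
            times = rng.exponential(1 / lam)
            clin = _clinical(times, np.ones(100))
            _, p = logrank(labels, clin)
            rejections += p < 0.05
        assert rejections / n_sim >= 0.8

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            logrank(np.zeros(4, dtype=int), _clinical([1, 2, 3, 4], [1, 1, 1, 1]))


class TestCoxMultivariate:
    def _simulate(self, seed, n=500, log_hr=-0.43):
        rng = np.random.default_rng(seed)
        group = rng.integers(0, 2, size=n)
        age = rng.normal(60, 10, size=n)
        lam = 0.01 * np.exp(log_hr * group + 0.01 * (age - 60))
        times = rng.exponential(1 / lam)
        clin = ClinicalTable([f"s{i}" for i in range(n)], times, np.ones(n, int),
                             pd.DataFrame({"age": age}))
        return clin, group

    def test_parameter_recovery(self):
        errs = []
        for seed in range(5):
            clin, group = self._simulate(seed)
            res = cox_multivariate(clin, group, covariates=["age"])
            errs.append(np.log(res.hazard_ratio) - (-0.43))
        assert abs(np.mean(errs)) < 0.15

    def test_constant_group_rejected(self):
        clin, _ = self._simulate(1, n=50)
        with pytest.raises(ValueError, match="degenerate"):
            cox_multivariate(clin, np.zeros(50), covariates=["age"])

    def test_no_covariates_matches_univariate_fit(self):
        clin, group = self._simulate(2, n=200)
        res = cox_multivariate(clin, group)
        df = pd.DataFrame({"time": clin.time, "event": clin.event, "group": group})
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        assert np.log(res.hazard_ratio) == pytest.approx(cph.params_["group"], abs=1e-8)

    def test_collinear_covariate_rejected(self):
        clin, group = self._simulate(3, n=60)
        clin.covariates["copy"] = group.astype(float)
        with pytest.raises(ValueError, match="collinear"):
            cox_multivariate(clin, group, covariates=["copy"])


class TestPrognosticPipeline:
    def test_planted_risk_module_flagged(self, default_result, default_bundle):
        sig = [r for r in default_result.prognostic if r.significant]
        assert any(r.members == default_bundle.risk_module_lncs for r in sig)

    def test_small_modules_discarded(self, default_result, default_bundle):
        for r in default_result.prognostic:
            assert len(r.members) >= 3
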