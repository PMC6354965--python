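import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prnfs.simulate import (GeneratorConfig, SurvivalData, generate_grn,
                            generate_multiomics, generate_survival,
                            label_by_thresholds, simulate_study, zscore)


def _group(n, seed=0):
    rng = np.random.default_rng(seed)
    g = np.zeros(n, dtype=int)
    g[: n // 2] = 1
    rng.shuffle(g)
    return pd.Series(g, index=pd.Index([f"s{i}" for i in range(n)]))


class TestGenerateGrn:
    def test_size_connectivity_and_determinism(self):
        a = generate_grn(74, 2, seed=7)
        b = generate_grn(74, 2, seed=7)
        assert a.n_nodes == 74
        import networkx as nx
        assert nx.is_connected(a.graph)
        assert set(a.graph.edges) == set(b.graph.edges)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_grn(1, 1)
        with pytest.raises(ValueError):
            generate_grn(10, 0)

    def test_heavier_tailed_than_matched_erdos_renyi(self):
        import networkx as nx
        ba_max, er_max = [], []
        for seed in range(20):
            ba = generate_grn(100, 2, seed=seed)
            n_edges = ba.n_edges
            er = nx.gnm_random_graph(100, n_edges, seed=seed)
            ba_max.append(max(d for _, d in ba.graph.degree))
            er_max.append(max(d for _, d in er.degree))
        assert np.mean(ba_max) > np.mean(er_max)


class TestGenerateMultiomics:
    def test_null_effect_gives_nominal_false_positive_rate(self):
        net = generate_grn(20, 2, seed=1)
        g = _group(300)
        cfg = GeneratorConfig(
            n_samples=300, n_features_per_level={"GE": 400},
            signature_nodes=tuple(net.nodes[:5]), effect_size=0.0, seed=2,
        )
        data = generate_multiomics(net, cfg, g)
        X = data.levels["GE"]
        t = stats.ttest_ind(X[g == 1], X[g == 0], equal_var=False)
        frac = float(np.mean(t.pvalue < 0.05))
        assert 0.02 < frac < 0.09

    def test_planted_standardized_shift_recovered(self):
        net = generate_grn(20, 2, seed=1)
        smds = []
        for seed in range(20):
            g = _group(500, seed)
            cfg = GeneratorConfig(
                n_samples=500, n_features_per_level={"GE": 50},
                signature_nodes=tuple(net.nodes[:5]), effect_size=1.0,
                level_split={"GE": 1.0}, seed=seed,
            )
            X = generate_multiomics(net, cfg, g).levels["GE"]
            for node in cfg.signature_nodes:
                a, b = X[node][g == 1], X[node][g == 0]
                sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
                smds.append((a.mean() - b.mean()) / sd)
        med = float(np.median(smds))
        # z-scoring a mixture with shift delta deflates the observed SMD to
        # delta/sqrt(1+delta^2/4); for delta=1 that is ~0.894
        assert 0.8 < med < 1.2

    def test_dm_shift_opposes_ge_shift(self):
        net = generate_grn(20, 2, seed=1)
        g = _group(400)
        cfg = GeneratorConfig(
            n_samples=400, n_features_per_level={"GE": 30, "DM": 30},
            signature_nodes=tuple(net.nodes[:5]), effect_size=1.0,
            level_split={"GE": 1.0, "DM": 1.0}, seed=3,
        )
        data = generate_multiomics(net, cfg, g)
        for node in cfg.signature_nodes:
            d_ge = data.levels["GE"][node][g == 1].mean() - \
                data.levels["GE"][node][g == 0].mean()
            d_dm = data.levels["DM"][node][g == 1].mean() - \
                data.levels["DM"][node][g == 0].mean()
            assert d_ge > 0 > d_dm

    def test_sample_ids_aligned_across_levels(self, small_study):
        levels = small_study.dataset.levels
        ids = [frame.index for frame in levels.values()]
        assert all(ids[0].equals(i) for i in ids)

    def test_unknown_signature_node_rejected(self):
        net = generate_grn(10, 2, seed=1)
        cfg = GeneratorConfig(n_samples=20, signature_nodes=("NOPE",))
        with pytest.raises(ValueError, match="NOPE"):
            generate_multiomics(net, cfg, _group(20))


class TestNormalization:
    def test_zscore_moments_and_idempotence(self, rng):
        frame = pd.DataFrame(rng.normal(3.0, 2.5, size=(200, 8)))
        z = zscore(frame)
        assert np.allclose(z.mean(), 0, atol=1e-8)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-8)
        assert np.allclose(zscore(z).values, z.values, atol=1e-8)

    def test_constant_column_survives(self):
        frame = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        z = zscore(frame)
        assert np.allclose(z["a"], 0)


class TestGenerateSurvival:
    def test_no_censoring_observes_every_event(self):
        risk = pd.Series(np.zeros(50), index=[f"s{i}" for i in range(50)])
        cfg = GeneratorConfig(n_samples=50, censor_rate=0.0, seed=4)
        surv = generate_survival(risk, cfg)
        assert (surv.event == 1).all()

    def test_median_time_ratio_matches_exponential_closed_form(self):
        # beta=1, risk 0/1: hazard ratio e, so median-time ratio is e
        ratios = []
        for seed in range(10):
            risk = pd.Series(
                np.repeat([0.0, 1.0], 1000),
                index=[f"s{i}" for i in range(2000)],
            )
            cfg = GeneratorConfig(n_samples=2000, beta=1.0, censor_rate=0.0,
                                  seed=seed)
            surv = generate_survival(risk, cfg)
            m0 = surv.time[risk == 0].median()
            m1 = surv.time[risk == 1].median()
            ratios.append(m0 / m1)
        assert abs(np.median(ratios) - np.e) / np.e < 0.15

    def test_censor_rate_calibrated(self):
        risk = pd.Series(np.repeat([0.0, 1.0], 1500),
                         index=[f"s{i}" for i in range(3000)])
        cfg = GeneratorConfig(n_samples=3000, censor_rate=0.4, seed=5)
        surv = generate_survival(risk, cfg)
        assert abs((surv.event == 0).mean() - 0.4) < 0.05

    def test_risk_anticorrelates_with_event_time(self):
        rng = np.random.default_rng(6)
        risk = pd.Series(rng.normal(size=400),
                         index=[f"s{i}" for i in range(400)])
        cfg = GeneratorConfig(n_samples=400, beta=1.0, censor_rate=0.0, seed=6)
        surv = generate_survival(risk, cfg)
        tau = stats.kendalltau(risk.values, surv.time.values).statistic
        assert tau < -0.1

    def test_null_beta_logrank_p_uniform_over_seeds(self):
        from lifelines.statistics import multivariate_logrank_test
        ps = []
        for seed in range(60):
            risk = pd.Series(np.repeat([0.0, 1.0], 60),
                             index=[f"s{i}" for i in range(120)])
            cfg = GeneratorConfig(n_samples=120, beta=0.0, censor_rate=0.2,
                                  seed=seed)
            surv = generate_survival(risk, cfg)
            res = multivariate_logrank_test(surv.time.values, risk.values,
                                            surv.event.values)
            ps.append(res.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestLabels:
    def test_threshold_example(self):
        idx = pd.Index(["a", "b", "c"])
        surv = SurvivalData(pd.Series([600.0, 1000.0, 1500.0], index=idx),
                            pd.Series([1, 1, 0], index=idx))
        lab = label_by_thresholds(surv, 700, 1400)
        assert list(lab.label) == ["poor", "excluded", "good"]

    def test_all_long_survivors_good(self):
        idx = pd.Index(["a", "b"])
        surv = SurvivalData(pd.Series([1500.0, 2000.0], index=idx),
                            pd.Series([0, 1], index=idx))
        lab = label_by_thresholds(surv, 700, 1400)
        assert (lab.label == "good").all()

    def test_early_censoring_excluded(self):
        idx = pd.Index(["a"])
        surv = SurvivalData(pd.Series([600.0], index=idx),
                            pd.Series([0], index=idx))
        lab = label_by_thresholds(surv, 700, 1400)
        assert lab.label["a"] == "excluded"


class TestRecoverySurface:
    def test_t_ranking_recovers_planted_signature(self):
        from prnfs.selection import ttest_rank
        hits = []
        for seed in range(10):
            net = generate_grn(40, 2, seed=seed)
            cfg = GeneratorConfig(
                n_samples=200, n_features_per_level={"GE": 500},
                signature_nodes=tuple(net.nodes[:20]), effect_size=1.0,
                level_split={"GE": 1.0}, seed=seed,
            )
            g = _group(200, seed)
            X = generate_multiomics(net, cfg, g).levels["GE"]
            top40 = ttest_rank(X, g, k=40).features
            hits.append(len(set(top40) & set(cfg.signature_nodes)))
        assert np.median(hits) >= 15
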