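from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from prnfs.selection import FeatureSet
from prnfs.simulate import MultiOmicsDataset, SurvivalData
from prnfs.survival import (SignatureMatrix, cluster_samples,
                            combine_signatures, km_at, km_estimate,
                            logrank_test, stratify)


def _surv(times, events, prefix="s"):
    idx = pd.Index([f"{prefix}{i}" for i in range(len(times))])
    return SurvivalData(pd.Series(np.asarray(times, float), index=idx),
                        pd.Series(np.asarray(events, int), index=idx))


def _fs(features, level, algorithm="t-test"):
    return FeatureSet(list(features),
                      list(np.arange(len(features), 0, -1.0)),
                      algorithm, {"level": level})


def _dataset(rng, n=60, levels=("GE", "DM"), p=6):
    idx = pd.Index([f"s{i}" for i in range(n)])
    return MultiOmicsDataset({
        lv: pd.DataFrame(rng.standard_normal((n, p)), index=idx,
                         columns=[f"g{j}" for j in range(p)])
        for lv in levels
    })


class TestCombineSignatures:
    def test_single_level_identity_columns(self, rng):
        data = _dataset(rng)
        sig = combine_signatures([_fs(["g0", "g1"], "GE")], data)
        assert list(sig.values.columns) == ["GE:g0", "GE:g1"]
        assert len(sig.values) == 60

    def test_two_levels_concatenate(self, rng):
        data = _dataset(rng)
        sig = combine_signatures(
            [_fs([f"g{j}" for j in range(4)], "GE"),
             _fs([f"g{j}" for j in range(4)], "DM")], data)
        assert sig.values.shape[1] == 8

    def test_duplicates_deduplicated_by_level_feature(self, rng):
        data = _dataset(rng)
        sig = combine_signatures(
            [_fs(["g0", "g1"], "GE"), _fs(["g1", "g2"], "GE")], data)
        assert list(sig.values.columns) == ["GE:g0", "GE:g1", "GE:g2"]

    def test_columns_standardized(self, rng):
        data = _dataset(rng)
        sig = combine_signatures([_fs(["g0", "g1", "g2"], "GE")], data)
        assert np.allclose(sig.values.mean(), 0, atol=1e-8)
        assert np.allclose(sig.values.std(ddof=1), 1, atol=1e-8)


class TestClustering:
    def test_separated_blobs_partition_perfectly(self, rng):
        x = np.vstack([rng.normal(-5, 0.3, (30, 4)),
                       rng.normal(5, 0.3, (30, 4))])
        sig = SignatureMatrix(
            pd.DataFrame(x, index=[f"s{i}" for i in range(60)]), ("test",))
        for method in ("kmeans", "spectral", "hierarchical"):
            lab = cluster_samples(sig, method, k=2, seed=0)
            first, second = lab.values[:30], lab.values[30:]
            assert len(set(first)) == 1 and len(set(second)) == 1
            assert first[0] != second[0]

    def test_deterministic_under_seed(self, rng):
        x = rng.standard_normal((40, 5))
        sig = SignatureMatrix(
            pd.DataFrame(x, index=[f"s{i}" for i in range(40)]), ("test",))
        a = cluster_samples(sig, "kmeans", 3, seed=5)
        b = cluster_samples(sig, "kmeans", 3, seed=5)
        assert a.equals(b)

    def test_more_clusters_than_samples_rejected(self, rng):
        sig = SignatureMatrix(
            pd.DataFrame(rng.standard_normal((4, 2)),
                         index=list("abcd")), ("test",))
        with pytest.raises(ValueError):
            cluster_samples(sig, "kmeans", 5)


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survival(self):
        curve = km_estimate(_surv([1, 2, 3, 4], [1, 1, 1, 1]))
        assert km_at(curve, 2.5) == pytest.approx(0.5)
        assert km_at(curve, 0.5) == 1.0
        assert km_at(curve, 4.0) == 0.0

    def test_censoring_rescales_risk_set(self):
        curve = km_estimate(_surv([1, 2, 3], [1, 0, 1]))
        assert km_at(curve, 1.0) == pytest.approx(2 / 3, abs=1e-12)
        assert km_at(curve, 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_all_censored_flat_curve(self):
        curve = km_estimate(_surv([5, 6, 7], [0, 0, 0]))
        assert (curve["survival"] == 1.0).all()


class TestLogRank:
    def test_identical_halves_give_null_statistic(self):
        times = [3, 5, 8, 13, 3, 5, 8, 13]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        surv = _surv(times, events)
        groups = pd.Series([0] * 4 + [1] * 4, index=surv.samples)
        stat, df, p = logrank_test(surv, groups)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_computed_two_group_example(self):
        # interleaved uncensored groups A=[1,3,5,7], B=[2,4,6,8]; per death
        # time E_A += nA/n and V += nA*nB/n^2 (single deaths), so
        # E_A = 1/2+3/7+1/2+2/5+1/2+1/3+1/2+0 = 332/105,
        # V = 1/4+12/49+1/4+6/25+1/4+2/9+1/4 = 18821/11025,
        # chi2 = (4-332/105)^2 / V = 7744/18821 (checked against R survdiff)
        surv = _surv([1, 3, 5, 7, 2, 4, 6, 8], [1] * 8)
        groups = pd.Series([0] * 4 + [1] * 4, index=surv.samples)
        stat, df, _ = logrank_test(surv, groups)
        expected = float(Fraction(7744, 18821))
        assert stat == pytest.approx(expected, abs=1e-10)
        assert df == 1

    def test_invariant_to_group_relabeling(self, rng):
        surv = _surv(rng.exponential(100, 60), rng.integers(0, 2, 60))
        if surv.event.sum() == 0:
            pytest.skip("degenerate draw")
        g = pd.Series(rng.integers(0, 3, 60), index=surv.samples)
        stat1, _, p1 = logrank_test(surv, g)
        stat2, _, p2 = logrank_test(surv, g.map({0: 2, 1: 0, 2: 1}))
        assert stat1 == pytest.approx(stat2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_two_group_closed_form_agreement(self, rng):
        # k=2 chi-square equals (O-E)^2/V computed directly
        times = rng.exponential(50, 30)
        events = np.ones(30, dtype=int)
        surv = _surv(times, events)
        g = pd.Series(np.repeat([0, 1], 15), index=surv.samples)
        stat, _, _ = logrank_test(surv, g)
        o_a = e_a = v = 0.0
        order = np.argsort(times)
        for i in order:
            t = times[i]
            at_risk = times >= t
            n, na = at_risk.sum(), (at_risk & (g.values == 0)).sum()
            o_a += int(g.values[i] == 0)
            e_a += na / n
            if n > 1:
                v += na * (n - na) * (n - 1) / (n**2 * (n - 1))
        assert stat == pytest.approx((o_a - e_a) ** 2 / v, abs=1e-8)

    def test_all_censored_rejected(self):
        surv = _surv([3, 4, 5, 6], [0, 0, 0, 0])
        g = pd.Series([0, 0, 1, 1], index=surv.samples)
        with pytest.raises(ValueError):
            logrank_test(surv, g)

    def test_null_p_values_uniform(self):
        from scipy import stats as sps
        ps = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            surv = _surv(rng.exponential(100, 80),
                         (rng.random(80) < 0.8).astype(int))
            g = pd.Series(rng.integers(0, 2, 80), index=surv.samples)
            if g.nunique() < 2 or surv.event.sum() == 0:
                continue
            ps.append(logrank_test(surv, g)[2])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestStratify:
    def _risky_dataset(self, rng, n=150, tiers=3):
        idx = pd.Index([f"s{i}" for i in range(n)])
        tier = np.repeat(np.arange(tiers), n // tiers + 1)[:n]
        x = rng.standard_normal((n, 6)) + 2.5 * tier[:, None]
        frame = pd.DataFrame(x, index=idx,
                             columns=[f"g{j}" for j in range(6)])
        t = rng.exponential(1.0 / (0.002 * np.exp(0.9 * tier)))
        surv = SurvivalData(pd.Series(np.maximum(t, 1e-3), index=idx),
                            pd.Series(np.ones(n, dtype=int), index=idx))
        return MultiOmicsDataset({"GE": frame}), surv

    def test_planted_risk_tiers_yield_tiny_p(self):
        ps = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            data, surv = self._risky_dataset(rng)
            sig = combine_signatures(
                [_fs([f"g{j}" for j in range(6)], "GE")], data)
            res = stratify(sig, surv, method="kmeans", k=3, seed=seed)
            ps.append(res.p_value)
        assert np.median(ps) < 1e-3

    def test_noise_signature_is_null(self):
        ps = []
        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            data, surv = self._risky_dataset(rng)
            noise = MultiOmicsDataset({
                "GE": pd.DataFrame(
                    rng.standard_normal((len(surv.time), 6)),
                    index=surv.samples,
                    columns=[f"g{j}" for j in range(6)])
            })
            sig = combine_signatures(
                [_fs([f"g{j}" for j in range(6)], "GE")], noise)
            res = stratify(sig, surv, method="kmeans", k=3, seed=seed)
            ps.append(res.p_value)
        assert np.median(ps) > 0.05

    def test_result_contract(self, rng):
        data, surv = self._risky_dataset(rng)
        sig = combine_signatures([_fs([f"g{j}" for j in range(6)], "GE")],
                                 data)
        res = stratify(sig, surv, method="hierarchical", k=3, seed=0)
        assert res.df == 2
        assert 0 < res.p_value <= 1
        assert set(res.km_curves) == set(res.assignments.unique())
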