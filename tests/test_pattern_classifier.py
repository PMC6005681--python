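import numpy as np
import pytest

from amdetect.pattern_classifier import (
    TAU_GRID_MS, ClassifierConfig, classify_template, filtered_vectors,
    optimize_tau, rcorr, van_rossum_distance,
)
from amdetect.psychometrics import MAX_DPRIME

from conftest import make_unit_from_counts


def numeric_vr_distance(a, b, tau, dt=1e-5, t_max=2.0):
    """Independent numerical-integration oracle for the van Rossum distance."""
    t = np.arange(0.0, t_max, dt)
    fa = np.zeros_like(t)
    fb = np.zeros_like(t)
    for s in a:
        fa += np.where(t >= s, np.exp(-(t - s) / tau), 0.0)
    for s in b:
        fb += np.where(t >= s, np.exp(-(t - s) / tau), 0.0)
    return np.sqrt(np.sum((fa - fb) ** 2) * dt)


def numeric_inner(a, b, tau, dt=1e-5, t_max=2.0):
    t = np.arange(0.0, t_max, dt)
    fa = np.zeros_like(t)
    fb = np.zeros_like(t)
    for s in a:
        fa += np.where(t >= s, np.exp(-(t - s) / tau), 0.0)
    for s in b:
        fb += np.where(t >= s, np.exp(-(t - s) / tau), 0.0)
    return np.sum(fa * fb) * dt


class TestVanRossum:
    def test_identical_trains_zero(self):
        train = [0.01, 0.05, 0.2]
        assert van_rossum_distance(train, train, 0.008) == 0.0

    def test_two_spike_closed_form(self):
        tau, dt_sep = 0.01, 0.004
        expect = np.sqrt(tau * (1 - np.exp(-dt_sep / tau)))
        assert van_rossum_distance([0.1], [0.1 + dt_sep], tau) == pytest.approx(expect)

    def test_against_numerical_integration(self):
        rng = np.random.default_rng(0)
        a = np.sort(rng.uniform(0, 0.5, 7))
        b = np.sort(rng.uniform(0, 0.5, 5))
        tau = 0.02
        got = van_rossum_distance(a, b, tau)
        oracle = numeric_vr_distance(a, b, tau)
        assert got == pytest.approx(oracle, rel=1e-2)

    def test_large_separation_saturates(self):
        tau = 0.005
        d = van_rossum_distance([0.0], [1.0], tau)
        assert d == pytest.approx(np.sqrt(tau), rel=1e-6)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            van_rossum_distance([0.1], [0.2], 0.0)

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(1)
        a = np.sort(rng.uniform(0, 0.3, 6))
        b = np.sort(rng.uniform(0, 0.3, 6))
        assert van_rossum_distance(a, b, 0.01) == pytest.approx(
            van_rossum_distance(a + 0.5, b + 0.5, 0.01))


class TestRcorr:
    def test_identical_trains_one(self):
        rng = np.random.default_rng(2)
        train = np.sort(rng.uniform(0, 1, 20))
        assert rcorr(train, train, 0.008) == pytest.approx(1.0)

    def test_distant_spikes_near_zero(self):
        assert rcorr([0.0], [1.0], 0.005) < 1e-10

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = np.sort(rng.uniform(0, 1, 15))
        b = np.sort(rng.uniform(0, 1, 12))
        assert rcorr(a, b, 0.01) == pytest.approx(rcorr(b, a, 0.01), abs=1e-12)

    def test_against_numerical_integration(self):
        rng = np.random.default_rng(4)
        a = np.sort(rng.uniform(0, 0.5, 6))
        b = np.sort(rng.uniform(0, 0.5, 8))
        tau = 0.015
        oracle = numeric_inner(a, b, tau) / np.sqrt(
            numeric_inner(a, a, tau) * numeric_inner(b, b, tau))
        assert rcorr(a, b, tau) == pytest.approx(oracle, rel=1e-2)

    def test_empty_train_raises(self):
        with pytest.raises(ValueError):
            rcorr([], [0.1], 0.01)

    def test_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = np.sort(rng.uniform(0, 1, rng.integers(1, 20)))
            b = np.sort(rng.uniform(0, 1, rng.integers(1, 20)))
            assert 0.0 <= rcorr(a, b, 0.01) <= 1.0 + 1e-12


def test_filtered_vectors_converge_to_continuous_norm():
    # grid-based norm^2 * dt approaches the closed-form inner product
    rng = np.random.default_rng(6)
    train = np.sort(rng.uniform(0, 0.5, 10))
    tau = 0.004
    v, dt = filtered_vectors([train], tau, 1.0)
    approx = float(np.sum(v[0] ** 2) * dt)
    exact = tau / 2 * np.sum(np.exp(-np.abs(train[:, None] - train[None, :]) / tau))
    assert approx == pytest.approx(exact, rel=0.05)


def _two_comb_unit(seed, jitter=0.003):
    """Equal-rate classes locked to combs offset by 10 ms."""
    import pandas as pd
    from amdetect.synthetic import UnitRecording

    rng = np.random.default_rng(100 + seed)
    spikes, rows = [], []
    for cls, phase in (("go", 0.005), ("nogo", 0.015)):
        for _ in range(16):
            base = np.arange(phase, 0.3, 0.02)
            spikes.append(np.sort(base + rng.normal(0, jitter, base.size)))
            rows.append({"type": cls,
                         "depth_db": 0.0 if cls == "go" else np.nan,
                         "response": "spout", "outcome": "hit"})
    return UnitRecording(unit_id="t", animal_id="a", hearing_status="ctl",
                         rate_hz=256.0, isolation="multi", spikes=spikes,
                         trials=pd.DataFrame(rows))


def brute_force_nearest_mean(go_tpl, nogo_tpl, test_counts):
    mu_g, mu_n = np.mean(go_tpl), np.mean(nogo_tpl)
    return np.array([abs(c - mu_g) < abs(c - mu_n) for c in test_counts])


class TestClassifyTemplate:
    def _separable_unit(self, hi=100, lo=1, n=24, seed=0):
        rng = np.random.default_rng(seed)
        return make_unit_from_counts({0.0: rng.poisson(hi, n)},
                                     rng.poisson(lo, n), seed=seed)

    @pytest.mark.parametrize("metric,tau", [("fr", 8), ("vanrossum", 8),
                                            ("kmeans", 32)])
    def test_separable_reaches_ceiling(self, metric, tau):
        unit = self._separable_unit()
        cfg = ClassifierConfig(metric=metric, tau_ms=tau, n_iterations=20, seed=1)
        res = classify_template(unit, 0.0, cfg)
        assert res.dprime == pytest.approx(MAX_DPRIME, abs=1e-9)

    def test_rcorr_ceiling_on_timing_separable_classes(self):
        # Rcorr normalizes away rate, so its ceiling case uses two reliable
        # spike-timing patterns offset by 10 ms rather than a rate contrast
        unit = _two_comb_unit(seed=0)
        cfg = ClassifierConfig(metric="rcorr", tau_ms=4, n_iterations=20,
                               window_s=0.3, seed=1)
        res = classify_template(unit, 0.0, cfg)
        assert res.dprime == pytest.approx(MAX_DPRIME, abs=1e-9)

    def test_uninformative_near_zero(self):
        rng = np.random.default_rng(7)
        unit = make_unit_from_counts({0.0: rng.poisson(15, 30)},
                                     rng.poisson(15, 30), seed=8)
        cfg = ClassifierConfig(metric="fr", n_iterations=1000, seed=2)
        res = classify_template(unit, 0.0, cfg)
        assert abs(res.dprime) < 0.3

    def test_fr_metric_matches_brute_force(self):
        # single iteration with known split must equal nearest-class-mean
        rng = np.random.default_rng(9)
        go = rng.poisson(12, 8)
        nogo = rng.poisson(6, 8)
        unit = make_unit_from_counts({0.0: go}, nogo, seed=10)
        cfg = ClassifierConfig(metric="fr", n_iterations=1, seed=3)
        res = classify_template(unit, 0.0, cfg)
        # replicate the iteration's split with the same generator stream
        counts = np.array([len(s) for s in unit.spikes], float)
        go_counts, nogo_counts = counts[:8], counts[8:]
        rng2 = np.random.default_rng(3)
        g_idx = rng2.permutation(8)
        n_idx = rng2.permutation(8)
        g_tpl, g_out = g_idx[:4], g_idx[4:]
        n_tpl, n_out = n_idx[:4], n_idx[4:]
        hits = brute_force_nearest_mean(go_counts[g_tpl], nogo_counts[n_tpl],
                                        go_counts[g_out]).sum()
        fas = brute_force_nearest_mean(go_counts[g_tpl], nogo_counts[n_tpl],
                                       nogo_counts[n_out]).sum()
        assert res.hit_rate == hits / 4 and res.fa_rate == fas / 4

    def test_too_few_trials_refused(self):
        unit = make_unit_from_counts({0.0: [5, 6, 7]}, [1, 2, 3, 4], seed=11)
        with pytest.raises(ValueError, match=">=4"):
            classify_template(unit, 0.0, ClassifierConfig(metric="fr"))

    def test_dprime_never_exceeds_ceiling(self):
        unit = self._separable_unit(hi=300, lo=0)
        for metric in ("fr", "vanrossum"):
            res = classify_template(
                unit, 0.0, ClassifierConfig(metric=metric, n_iterations=10, seed=4))
            assert res.dprime <= MAX_DPRIME + 1e-12

    def test_monotone_in_separation(self):
        # increasing rate offset never decreases d' (3-point ladder)
        dps = []
        for hi in (16, 30, 60):
            unit = self._separable_unit(hi=hi, lo=15, n=30, seed=12)
            res = classify_template(
                unit, 0.0, ClassifierConfig(metric="fr", n_iterations=300, seed=5))
            dps.append(res.dprime)
        assert dps[0] <= dps[1] + 0.1 and dps[1] <= dps[2] + 0.1

    def test_per_iteration_pooling_option(self):
        unit = self._separable_unit(hi=40, lo=10)
        cfg = ClassifierConfig(metric="fr", n_iterations=50, seed=6,
                               pooling="per-iteration")
        res = classify_template(unit, 0.0, cfg)
        assert res.per_iteration_dprime.shape == (50,)


class TestOptimizeTau:
    def test_single_value_grid(self):
        unit = make_unit_from_counts(
            {0.0: np.random.default_rng(13).poisson(40, 12)},
            np.random.default_rng(14).poisson(5, 12), seed=15)
        cfg = ClassifierConfig(metric="vanrossum", tau_grid_ms=(16,),
                               n_iterations=5, seed=7)
        tau, res = optimize_tau(unit, 0.0, cfg)
        assert tau == 16

    def test_rate_separable_tie_breaks_to_smallest(self):
        rng = np.random.default_rng(16)
        unit = make_unit_from_counts({0.0: rng.poisson(150, 16)},
                                     rng.poisson(1, 16), seed=17)
        cfg = ClassifierConfig(metric="vanrossum", tau_grid_ms=(2, 8, 32),
                               n_iterations=5, seed=8)
        tau, res = optimize_tau(unit, 0.0, cfg)
        assert tau == 2.0 and res.dprime == pytest.approx(MAX_DPRIME, abs=1e-9)

    def test_fr_metric_rejected(self):
        unit = make_unit_from_counts({0.0: [5] * 8}, [5] * 8, seed=18)
        with pytest.raises(ValueError, match="tau"):
            optimize_tau(unit, 0.0, ClassifierConfig(metric="fr"))

    def test_timing_code_prefers_matching_tau(self):
        # equal-rate classes locked to combs offset by 25 ms with 8 ms
        # jitter: too much jitter for tau = 2 ms, too little contrast for
        # tau >= 64 ms, so the optimum falls in the 4-32 ms band
        import pandas as pd
        from amdetect.synthetic import UnitRecording

        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            spikes, rows = [], []
            for cls, phase in (("go", 0.005), ("nogo", 0.030)):
                for _ in range(12):
                    base = np.arange(phase, 0.4, 0.05)
                    keep = rng.random(base.size) < 0.8
                    s = base[keep] + rng.normal(0, 0.008, int(keep.sum()))
                    s = np.concatenate([s, rng.uniform(0, 0.4, 4)])
                    spikes.append(np.sort(np.clip(s, 0, 0.4)))
                    rows.append({"type": cls,
                                 "depth_db": 0.0 if cls == "go" else np.nan,
                                 "response": "spout", "outcome": "hit"})
            unit = UnitRecording(unit_id="t", animal_id="a",
                                 hearing_status="ctl", rate_hz=256.0,
                                 isolation="multi", spikes=spikes,
                                 trials=pd.DataFrame(rows))
            cfg = ClassifierConfig(metric="vanrossum", n_iterations=15,
                                   window_s=0.4, seed=seed)
            tau, _ = optimize_tau(unit, 0.0, cfg)
            if 4 <= tau <= 32:
                hits += 1
        assert hits >= 6
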