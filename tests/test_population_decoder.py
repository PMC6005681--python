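import numpy as np
import pytest
from scipy import stats

from amdetect.population_decoder import (
    DecoderConfig, bin_unit_counts, build_population_tensor, decode,
    mi_subpopulation_decode, population_cv, unit_count_curve,
)
from amdetect.psychometrics import MAX_DPRIME
from amdetect.synthetic import (
    default_config, draw_tuning, generate_session, generate_unit,
)

from conftest import make_unit_from_counts


def _cohort_units(group="ctl", rate=256.0, n_units=12, n_trials=200, seed=0,
                  tuning_override=None):
    cfg = default_config()
    sess = generate_session(cfg, "a", group, rate, n_trials, seed=seed)
    rng = np.random.default_rng(seed)
    units = []
    for i in range(n_units):
        tuning = draw_tuning(cfg.tuning[group], rate, rng)
        if tuning_override:
            tuning.update(tuning_override)
        units.append(generate_unit(cfg, sess, tuning, seed=1000 * seed + i,
                                   unit_id=f"u{i}"))
    return cfg, sess, units


class TestBinning:
    def test_edge_spike_lands_in_later_bin(self):
        counts = bin_unit_counts([np.array([0.001])], (0.0, 0.01), 1.0)
        assert counts[0, 1] == 1.0 and counts[0, 0] == 0.0

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        spikes = [np.sort(rng.uniform(0, 0.4, 37))]
        counts = bin_unit_counts(spikes, (0.0, 0.4), 1.0)
        assert counts.sum() == 37

    def test_bin_count_matches_window(self):
        counts = bin_unit_counts([np.array([])], (0.0, 0.4), 1.0)
        assert counts.shape == (1, 400)


class TestBuildTensor:
    def test_single_unit_identity(self):
        _, _, units = _cohort_units(n_units=1, seed=3)
        t = build_population_tensor(units, [0.0], require_threshold=False, seed=0)
        assert t.counts.shape[0] == 1
        # raw counts sum equals the spike count in the window
        trial0 = t.counts[0, 0]
        assert trial0.sum() == int(trial0.sum())

    def test_balanced_classes(self):
        _, sess, units = _cohort_units(n_units=4, seed=4)
        t = build_population_tensor(units, list(sess.go_depths[:2]) + [0.0],
                                    require_threshold=False, seed=0)
        labels, counts = np.unique(t.labels, return_counts=True)
        assert len(set(counts)) == 1

    def test_threshold_requirement_filters_units(self):
        _, _, units = _cohort_units(n_units=8, seed=5,
                                    tuning_override={"depth_gain_hz": 0.0,
                                                     "kappa": 0.0})
        with pytest.raises(ValueError, match="no units qualify"):
            build_population_tensor(units, [0.0], require_threshold=True, seed=0)

    def test_missing_condition_raises(self):
        _, _, units = _cohort_units(n_units=2, seed=6)
        with pytest.raises(ValueError, match="lacks"):
            build_population_tensor(units, [-2.34], require_threshold=False, seed=0)

    def test_normalized_nonnegative(self):
        _, _, units = _cohort_units(n_units=3, seed=7)
        t = build_population_tensor(units, [0.0], require_threshold=False, seed=0)
        assert np.all(t.normalized >= 0)


@pytest.fixture(scope="module")
def ctl_tensor():
    _, sess, units = _cohort_units(n_units=14, n_trials=240, seed=8)
    return build_population_tensor(units, list(sess.go_depths),
                                   require_threshold=False, seed=0)


class TestDecode:
    def test_shuffled_labels_near_zero(self, ctl_tensor):
        # shuffling is equivalent to decoding two draws of the same class:
        # compare Nogo against itself by relabeling half the Nogo trials
        _, sess, units = _cohort_units(n_units=10, n_trials=300, seed=9)
        for u in units:
            nogo_idx = u.trials.index[u.trials["type"] == "nogo"]
            half = nogo_idx[: len(nogo_idx) // 2]
            u.trials.loc[half, "type"] = "go"
            u.trials.loc[half, "depth_db"] = 0.0
            u.trials.loc[u.trials["type"] == "go", "depth_db"] = 0.0
        t = build_population_tensor(units, [0.0], require_threshold=False, seed=0)
        res = decode(t, 0.0, DecoderConfig(n_iterations=30, seed=1))
        assert abs(res.mean_dprime) < 0.3

    def test_separable_population_hits_ceiling(self):
        _, sess, units = _cohort_units(
            n_units=10, n_trials=150, seed=10,
            tuning_override={"monotonic": "inc", "depth_gain_hz": 80.0,
                             "gain_cv": 0.05, "kappa": 0.0})
        t = build_population_tensor(units, [0.0], require_threshold=False, seed=0)
        res = decode(t, 0.0, DecoderConfig(n_iterations=20, seed=2))
        assert res.mean_dprime == pytest.approx(MAX_DPRIME, abs=1e-9)

    def test_fine_bins_beat_coarse_on_phase_locked_population(self):
        # timing-only code: equal mean rates, strong phase locking
        _, sess, units = _cohort_units(
            n_units=12, n_trials=240, seed=11, rate=256.0,
            tuning_override={"depth_gain_hz": 0.0, "kappa": 0.9,
                             "driven_base_hz": 40.0, "gain_cv": 0.2})
        t1 = build_population_tensor(units, [0.0], bin_width_ms=1.0,
                                     require_threshold=False, seed=0)
        t100 = build_population_tensor(units, [0.0], bin_width_ms=100.0,
                                       require_threshold=False, seed=0)
        d1 = decode(t1, 0.0, DecoderConfig(n_iterations=25, seed=3)).mean_dprime
        d100 = decode(t100, 0.0, DecoderConfig(n_iterations=25, seed=3)).mean_dprime
        assert d1 > d100 + 0.5

    def test_unknown_depth_raises(self, ctl_tensor):
        with pytest.raises(KeyError):
            decode(ctl_tensor, -99.0, DecoderConfig(n_iterations=2, seed=0))

    def test_trial_permutation_invariance(self):
        _, sess, units = _cohort_units(n_units=6, n_trials=160, seed=12)
        t = build_population_tensor(units, [0.0], require_threshold=False, seed=0)
        r1 = decode(t, 0.0, DecoderConfig(n_iterations=40, seed=4))
        for u in units:
            perm = np.random.default_rng(0).permutation(len(u.trials))
            u.spikes = [u.spikes[i] for i in perm]
            u.trials = u.trials.iloc[perm].reset_index(drop=True)
        t2 = build_population_tensor(units, [0.0], require_threshold=False, seed=0)
        r2 = decode(t2, 0.0, DecoderConfig(n_iterations=40, seed=4))
        assert abs(r1.mean_dprime - r2.mean_dprime) < 0.5

    def test_noise_units_do_not_raise_dprime(self):
        cfg, sess, units = _cohort_units(
            n_units=8, n_trials=160, seed=13,
            tuning_override={"monotonic": "inc", "depth_gain_hz": 25.0,
                             "kappa": 0.0, "gain_cv": 0.2})
        _, _, noise = _cohort_units(
            n_units=8, n_trials=160, seed=13,
            tuning_override={"depth_gain_hz": 0.0, "kappa": 0.0,
                             "gain_cv": 0.2})
        t_sig = build_population_tensor(units, [0.0], require_threshold=False,
                                        seed=0)
        t_all = build_population_tensor(units + noise, [0.0],
                                        require_threshold=False, seed=0)
        d_sig = decode(t_sig, 0.0, DecoderConfig(n_iterations=30, seed=5)).mean_dprime
        d_all = decode(t_all, 0.0, DecoderConfig(n_iterations=30, seed=5)).mean_dprime
        assert d_all <= d_sig + 0.4


class TestUnitCountCurve:
    def test_monotone_with_unit_count(self):
        _, sess, units = _cohort_units(
            n_units=12, n_trials=200, seed=14,
            tuning_override={"monotonic": "inc", "depth_gain_hz": 10.0,
                             "kappa": 0.3, "gain_cv": 0.3})
        t = build_population_tensor(units, [0.0], require_threshold=False, seed=0)
        rows = unit_count_curve(t, 0.0, fractions=[0.1, 0.25, 0.5, 0.75, 1.0],
                                config=DecoderConfig(n_iterations=20, seed=6))
        d = [r["mean_dprime"] for r in rows]
        rho, _ = stats.spearmanr(np.arange(len(d)), d)
        assert rho >= 0.8

    def test_full_fraction_matches_decode(self):
        _, sess, units = _cohort_units(n_units=10, n_trials=160, seed=15)
        t = build_population_tensor(units, [0.0], require_threshold=False, seed=0)
        cfg = DecoderConfig(n_iterations=30, seed=7)
        full = unit_count_curve(t, 0.0, fractions=[1.0], config=cfg)[0]
        base = decode(t, 0.0, cfg)
        assert full["mean_dprime"] == pytest.approx(
            base.mean_dprime, abs=3 * base.sd_dprime / np.sqrt(30) + 0.3)

    def test_too_few_units(self):
        _, sess, units = _cohort_units(n_units=4, seed=16)
        t = build_population_tensor(units, [0.0], require_threshold=False, seed=0)
        with pytest.raises(ValueError):
            unit_count_curve(t, 0.0)


class TestMISubpopulation:
    def test_class_too_small_raises(self):
        _, sess, units = _cohort_units(n_units=6, seed=17)
        with pytest.raises(ValueError, match="units"):
            mi_subpopulation_decode(units, "increasing", 0.0, n=50)

    def test_symmetric_construction_indistinguishable(self):
        # gain well above base rate so measured MI separates the two
        # generator classes cleanly and symmetrically
        _, sess, units = _cohort_units(n_units=16, n_trials=160, seed=18,
                                       tuning_override={"depth_gain_hz": 25.0,
                                                        "driven_base_hz": 8.0})
        res = {}
        for klass in ("increasing", "decreasing"):
            res[klass] = mi_subpopulation_decode(
                units, klass, 0.0, n=4,
                config=DecoderConfig(n_iterations=20, seed=8))
        lo = res["increasing"].mean_dprime - res["increasing"].sd_dprime
        hi = res["increasing"].mean_dprime + res["increasing"].sd_dprime
        assert (res["decreasing"].mean_dprime - res["decreasing"].sd_dprime <= hi
                and res["decreasing"].mean_dprime + res["decreasing"].sd_dprime >= lo)


class TestPopulationCV:
    def test_identical_bins_zero(self):
        unit = make_unit_from_counts({0.0: [0] * 10}, [0] * 10, seed=19)
        # constant one spike per bin: construct manually
        t = build_population_tensor([unit], [0.0], require_threshold=False,
                                    seed=0, window=(0.0, 0.01), bin_width_ms=1.0)
        t.counts = np.ones_like(t.counts)
        out = population_cv(t)
        assert np.nanmax(out["per_trial_cv"]) == 0.0

    def test_poisson_oracle(self):
        rng = np.random.default_rng(20)
        lam = 40.0
        counts = rng.poisson(lam, size=(1, 200, 100)).astype(float)
        class Dummy:
            pass
        t = Dummy()
        t.counts = counts
        t.classes = ["go:0"]
        t.labels = np.array(["go:0"] * 200)
        out = population_cv(t)
        med = np.nanmedian(out["per_trial_cv"])
        assert med == pytest.approx(1 / np.sqrt(lam), rel=0.1)

    def test_hl_exceeds_ctl(self):
        meds = {}
        for group in ("ctl", "hl"):
            _, sess, units = _cohort_units(group=group, rate=256.0, n_units=8,
                                           n_trials=160, seed=21)
            t = build_population_tensor(units, [0.0], require_threshold=False,
                                        seed=0, window=(0.0, 0.4),
                                        bin_width_ms=25.0)
            meds[group] = np.nanmedian(population_cv(t)["per_trial_cv"])
        assert meds["hl"] > meds["ctl"]
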