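"""Likelihood fusion, thresholding, combinatorial logic and the MDS decision."""

import numpy as np
import pytest

from mandown.detectors import (
    DOWN_FEATURES,
    FALL_FEATURES,
    IMMOBILITY_FEATURES,
    CombinatorialConfig,
    DetectorBank,
    DetectorConfig,
    FeatureSpec,
    combinatorial_state,
    detect_down,
    detect_fall,
    detect_immobility,
    detect_mds,
    fall_likelihood,
    feature_threshold_detect,
    immobility_likelihood,
)
from mandown.errors import WindowTooLongError
from mandown.features import ExtremeValueSignal
from mandown.statmodels import DistributionModel, normalized_pdf

FS = 1000.0  # 1 ms per sample


def make_E(spec: FeatureSpec, values) -> ExtremeValueSignal:
    values = np.asarray(values, dtype=float)
    return ExtremeValueSignal(source=spec.source, statistic=spec.statistic,
                              extremum=spec.extremum, tau_ms=spec.tau_ms,
                              fs=FS, values=values, span=1)


def fall_cfg(tau_L=4.0, gamma=0.5, locs=(0.6, 2.0, 3.0, 2.6)):
    features = tuple(FeatureSpec(f.source, f.statistic, f.extremum, 10.0)
                     for f in FALL_FEATURES)
    models = {f.key: DistributionModel("normal", loc, 0.5)
              for f, loc in zip(features, locs)}
    return DetectorConfig("F", features, gamma=gamma, fusion_ms=tau_L,
                          models=models)


def imm_cfg(tau_L=4.0, gamma=0.5):
    features = tuple(FeatureSpec(f.source, f.statistic, f.extremum, 10.0)
                     for f in IMMOBILITY_FEATURES)
    models = {f.key: DistributionModel("normal", -4.0, 0.5)
              for f in features}
    return DetectorConfig("I", features, gamma=gamma, fusion_ms=tau_L,
                          models=models)


def oracle_fused(weight_arrays, n, agg):
    length = min(len(w) for w in weight_arrays)
    L = np.ones(length)
    for w in weight_arrays:
        out = np.empty(length)
        for t in range(length):
            win = w[:length][t:t + n]
            out[t] = win.max() if agg == "max" else win.mean()
        L *= out
    return L


class TestConfigContracts:
    def test_feature_count_enforced(self):
        with pytest.raises(ValueError):
            DetectorConfig("F", FALL_FEATURES[:3], gamma=0.1, fusion_ms=100.0)
        with pytest.raises(ValueError):
            DetectorConfig("D", FALL_FEATURES, gamma=0.1)

    def test_bank_yaml_round_trip(self, tmp_path):
        cfg = fall_cfg()
        bank = DetectorBank(fall=cfg, immobility=imm_cfg(),
                            down=DetectorConfig("D", DOWN_FEATURES, gamma=0.87),
                            comb=CombinatorialConfig(1000.0, 2000.0, 1500.0))
        path = tmp_path / "bank.yaml"
        bank.save(path)
        back = DetectorBank.load(path)
        assert back.to_dict() == bank.to_dict()

    def test_partial_bank_round_trip(self, tmp_path):
        bank = DetectorBank(fall=None, immobility=imm_cfg(),
                            down=DetectorConfig("D", DOWN_FEATURES, gamma=0.5))
        path = tmp_path / "bank.yaml"
        bank.save(path)
        assert DetectorBank.load(path).fall is None


class TestFallLikelihood:
    def test_all_modes_gives_unit_likelihood(self):
        cfg = fall_cfg()
        E = [make_E(f, np.full(20, m.loc))
             for f, m in zip(cfg.features, cfg.models.values())]
        L = fall_likelihood(E, cfg, FS)
        assert np.allclose(L, 1.0)

    def test_one_deep_tail_feature_dominates_the_product(self):
        cfg = fall_cfg()
        E = []
        for i, (f, m) in enumerate(zip(cfg.features, cfg.models.values())):
            value = m.loc if i else m.loc + 10 * m.scale
            E.append(make_E(f, np.full(20, value)))
        L = fall_likelihood(E, cfg, FS)
        tail = normalized_pdf(list(cfg.models.values())[0],
                              list(cfg.models.values())[0].loc + 5.0)
        assert np.allclose(L, tail, rtol=1e-10)
        assert L.max() < 1e-20

    def test_matches_brute_force_oracle(self, rng):
        cfg = fall_cfg(tau_L=5.0)
        for _ in range(25):
            E = [make_E(f, rng.normal(m.loc, 2 * m.scale,
                                      int(rng.integers(12, 30))))
                 for f, m in zip(cfg.features, cfg.models.values())]
            L = fall_likelihood(E, cfg, FS)
            weights = [normalized_pdf(cfg.models[f.key], e.values)
                       for f, e in zip(cfg.features, E)]
            assert np.allclose(L, oracle_fused(weights, 5, "max"), atol=1e-12)

    def test_fusion_window_too_long(self):
        cfg = fall_cfg(tau_L=50.0)
        E = [make_E(f, np.zeros(10)) for f in cfg.features]
        with pytest.raises(WindowTooLongError):
            fall_likelihood(E, cfg, FS)


class TestImmobilityLikelihood:
    def test_constant_modes_gives_unit_likelihood(self):
        cfg = imm_cfg()
        E = [make_E(f, np.full(15, -4.0)) for f in cfg.features]
        assert np.allclose(immobility_likelihood(E, cfg, FS), 1.0)

    def test_half_weight_feature_scales_the_product(self):
        cfg = imm_cfg()
        half_x = -4.0 + 0.5 * np.sqrt(2 * np.log(2.0))  # weight exactly 0.5
        E = [make_E(cfg.features[0], np.full(15, half_x))]
        E += [make_E(f, np.full(15, -4.0)) for f in cfg.features[1:]]
        assert np.allclose(immobility_likelihood(E, cfg, FS), 0.5)

    def test_matches_brute_force_oracle(self, rng):
        cfg = imm_cfg(tau_L=6.0)
        for _ in range(25):
            E = [make_E(f, rng.normal(-4.0, 1.0, int(rng.integers(12, 30))))
                 for f in cfg.features]
            L = immobility_likelihood(E, cfg, FS)
            weights = [normalized_pdf(cfg.models[f.key], e.values)
                       for f, e in zip(cfg.features, E)]
            assert np.allclose(L, oracle_fused(weights, 6, "mean"), atol=1e-12)


class TestThresholding:
    def test_zero_likelihood_never_fires(self):
        assert not detect_fall(np.zeros(10), 0.0).any()

    def test_boundary_equality_does_not_fire(self):
        L = np.array([0.1, 0.5, 0.9])
        assert list(detect_fall(L, 0.5)) == [False, False, True]
        assert list(detect_immobility(L, 0.9)) == [False, False, False]

    def test_down_strict_inequality(self):
        E = make_E(DOWN_FEATURES[0], [0.5, 0.87, 1.2])
        assert list(detect_down(E, 0.87)) == [False, False, True]

    def test_raising_gamma_never_creates_detections(self, rng):
        L = rng.random(200)
        low = detect_fall(L, 0.3)
        high = detect_fall(L, 0.7)
        assert not np.any(high & ~low)

    def test_gamma_range_validation(self):
        with pytest.raises(ValueError):
            detect_fall(np.zeros(3), 1.5)
        with pytest.raises(ValueError):
            detect_down(make_E(DOWN_FEATURES[0], [0.0]), 4.0)

    def test_per_feature_diagnostic_direction(self):
        lo = make_E(FALL_FEATURES[0], [0.5, 0.9])   # min-extremum feature
        hi = make_E(FALL_FEATURES[1], [1.0, 3.0])   # max-extremum feature
        assert list(feature_threshold_detect(lo, 0.859)) == [True, False]
        assert list(feature_threshold_detect(hi, 2.08)) == [False, True]


def oracle_combinatorial(ya, yb, n):
    out = np.zeros(len(ya), dtype=bool)
    for t in range(len(ya)):
        out[t] = ya[t:t + n].any() and yb[t:t + n].any()
    return out


class TestCombinatorialLogic:
    def test_both_events_inside_window(self):
        ya = np.zeros(100, dtype=bool)
        yb = np.zeros(100, dtype=bool)
        ya[40] = True
        yb[55] = True  # 15 ms later with a 30 ms window
        y = combinatorial_state(ya, yb, 30.0, FS)
        assert y[40]
        assert y[25] and not y[24]  # window [t, t+30] reaches sample t+30

    def test_events_too_far_apart(self):
        ya = np.zeros(200, dtype=bool)
        yb = np.zeros(200, dtype=bool)
        ya[10] = True
        yb[100] = True
        assert not combinatorial_state(ya, yb, 50.0, FS).any()

    def test_order_is_irrelevant(self, rng):
        ya = rng.random(150) < 0.05
        yb = rng.random(150) < 0.05
        ab = combinatorial_state(ya, yb, 20.0, FS)
        ba = combinatorial_state(yb, ya, 20.0, FS)
        assert np.array_equal(ab, ba)

    def test_matches_double_any_oracle(self, rng):
        for _ in range(25):
            m = int(rng.integers(30, 120))
            ya = rng.random(m) < 0.1
            yb = rng.random(m) < 0.1
            tau = float(rng.integers(5, 25))
            got = combinatorial_state(ya, yb, tau, FS)
            assert np.array_equal(got, oracle_combinatorial(ya, yb, int(tau) + 1))

    def test_window_longer_than_signal(self):
        with pytest.raises(WindowTooLongError):
            combinatorial_state(np.zeros(5, bool), np.zeros(5, bool), 10.0, FS)


class TestMdsDecision:
    def test_all_silent(self):
        z = np.zeros(10, dtype=bool)
        assert not detect_mds(z, z, z).any()

    def test_any_single_pathway_fires(self):
        z = np.zeros(10, dtype=bool)
        y = z.copy()
        y[3] = True
        for args in ((y, z, z), (z, y, z), (z, z, y)):
            assert detect_mds(*args)[3]

    def test_is_pointwise_or(self, rng):
        a, b, c = (rng.random(100) < 0.3 for _ in range(3))
        assert np.array_equal(detect_mds(a, b, c), a | b | c)

    def test_triple_cooccurrence_implies_all_pairwise_and_mds(self, rng):
        """A window containing F, I and D triggers every pairwise state,
        so the triple combination needs no detector of its own."""
        n, tau = 300, 40.0
        win = int(tau) + 1
        for _ in range(10):
            yf = rng.random(n) < 0.05
            yi = rng.random(n) < 0.05
            yd = rng.random(n) < 0.05
            fd = combinatorial_state(yf, yd, tau, FS)
            fi = combinatorial_state(yf, yi, tau, FS)
            id_ = combinatorial_state(yi, yd, tau, FS)
            mds = detect_mds(fd, fi, id_)
            for t in range(n):
                if yf[t:t + win].any() and yi[t:t + win].any() \
                        and yd[t:t + win].any():
                    assert fd[t] and fi[t] and id_[t] and mds[t]
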