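"""MSPC engine: cycle matrix, PCA against independent oracles, T²/DModX,
univariate charts, detection power and false-alarm calibration."""

import numpy as np
import pytest

from mabtrain.historian import CycleRecord
from mabtrain.monitor import (
    CHROM_SENSORS,
    Monitor,
    MonitorError,
    assess_cycle,
    build_cycle_matrix,
    fit_pca,
    merge_cycle_records,
    monitor_campaign,
    scale_vector,
    univariate_limits,
)


def _cycle(cid, sensors, n=30, duration=60.0, fn=None, unit="u"):
    rec = CycleRecord(cycle_id=cid, unit_id=unit, start=0.0, end=duration)
    t = np.arange(n) * duration / n
    for i, s in enumerate(sensors):
        v = fn(cid, s, t) if fn else np.full(n, float(i))
        rec.traces[s] = (t, v)
    return rec


class TestCycleMatrix:
    def test_feature_count_two_sensors_three_landmarks(self):
        cycles = [_cycle(1, ["a", "b"]), _cycle(2, ["a", "b"])]
        m = build_cycle_matrix(cycles, ["a", "b"], L=3)
        assert m.X.shape == (2, 6)

    def test_resampling_identity_on_landmark_grid(self):
        L = 10
        rec = CycleRecord(cycle_id=1, unit_id="u", start=0.0, end=100.0)
        t = np.arange(L) * 100.0 / L
        v = np.sin(t)
        rec.traces["a"] = (t, v)
        rec2 = CycleRecord(cycle_id=2, unit_id="u", start=0.0, end=100.0)
        rec2.traces["a"] = (t, v + 1.0)
        m = build_cycle_matrix([rec, rec2], ["a"], L=L)
        raw = m.X * m.sd + m.mean
        np.testing.assert_allclose(raw[0], v, atol=1e-12)

    def test_reference_columns_centred(self):
        rng = np.random.default_rng(0)
        cycles = [_cycle(i, ["a", "b"], fn=lambda c, s, t: rng.normal(size=t.size))
                  for i in range(1, 9)]
        m = build_cycle_matrix(cycles, ["a", "b"], L=5, ref_ids=[1, 2, 3, 4, 5])
        ref_rows = m.X[:5]
        np.testing.assert_allclose(ref_rows.mean(axis=0), 0.0, atol=1e-10)

    def test_missing_sensor_reported(self):
        cycles = [_cycle(1, ["a"]), _cycle(2, ["a"])]
        with pytest.raises(MonitorError, match="cycle 1: missing sensor 'b'"):
            build_cycle_matrix(cycles, ["a", "b"], L=3)

    def test_zero_variance_column_flagged(self):
        cycles = [_cycle(i, ["a"], fn=lambda c, s, t: np.ones(t.size)) for i in (1, 2, 3)]
        m = build_cycle_matrix(cycles, ["a"], L=4)
        assert m.zero_variance.all()
        assert np.all(m.sd == 1.0)

    def test_merge_joins_on_cycle_id(self):
        pa = [_cycle(i, ["uv"], unit="proa") for i in (1, 2, 3)]
        cx = [_cycle(i, ["uv"], unit="cex") for i in (2, 3)]
        merged = merge_cycle_records([pa, cx])
        assert [m.cycle_id for m in merged] == [2, 3]
        assert set(merged[0].traces) == {"proa:uv", "cex:uv"}


def _random_matrix(n=20, p=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
    cycles = []
    for i in range(n):
        rec = CycleRecord(cycle_id=i + 1, unit_id="u", start=0.0, end=1.0)
        t = np.arange(p, dtype=float) / p
        rec.traces["s"] = (t, X[i])
        cycles.append(rec)
    return build_cycle_matrix(cycles, ["s"], L=p)


class TestFitPCA:
    def test_rank_one_data(self):
        cycles = []
        for i in range(6):
            rec = CycleRecord(cycle_id=i + 1, unit_id="u", start=0.0, end=1.0)
            t = np.array([0.0, 0.5])
            rec.traces["s"] = (t, np.array([float(i), 2.0 * i]))  # perfectly correlated
            cycles.append(rec)
        m = build_cycle_matrix(cycles, ["s"], L=2)
        model = fit_pca(m, k=2)
        assert model.explained[0] == pytest.approx(1.0)
        assert model.score_sd[1] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_loadings_match_covariance_eigendecomposition(self, seed):
        """Brute-force oracle: eigenvectors of the sample covariance matrix."""
        m = _random_matrix(seed=seed)
        model = fit_pca(m, k=3)
        C = np.cov(m.X, rowvar=False, ddof=1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        for a in range(3):
            v = V[:, a]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(model.loadings[:, a], v, atol=1e-8)
            np.testing.assert_allclose(model.score_sd[a] ** 2, w[a], atol=1e-8)

    def test_matches_sklearn_pca(self):
        """Independent library oracle on the same reference matrix."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        m = _random_matrix(seed=7)
        model = fit_pca(m, k=3)
        sk = sklearn.PCA(n_components=3).fit(m.X)
        for a in range(3):
            v = sk.components_[a]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(model.loadings[:, a], v, atol=1e-8)
        np.testing.assert_allclose(model.score_sd**2, sk.explained_variance_, atol=1e-8)

    def test_loadings_orthonormal(self):
        model = fit_pca(_random_matrix(seed=3), k=4)
        G = model.loadings.T @ model.loadings
        np.testing.assert_allclose(G, np.eye(4), atol=1e-8)

    def test_variance_fraction_rule(self):
        # construct data with exact component variance shares 0.70/0.25/0.05
        rng = np.random.default_rng(5)
        n, p = 40, 5
        Q, _ = np.linalg.qr(rng.normal(size=(n, 3)) - 0)
        scores = Q[:, :3] * np.sqrt((n - 1) * np.array([0.70, 0.25, 0.05]))
        V, _ = np.linalg.qr(rng.normal(size=(p, 3)))
        X = scores @ V.T
        cycles = []
        for i in range(n):
            rec = CycleRecord(cycle_id=i + 1, unit_id="u", start=0.0, end=1.0)
            rec.traces["s"] = (np.arange(p, dtype=float), X[i])
            cycles.append(rec)
        m = build_cycle_matrix(cycles, ["s"], L=p)
        m.X = X  # bypass autoscaling to keep the variance shares exact
        assert fit_pca(m, k=0.90).k == 2
        assert fit_pca(m, k=0.69).k == 1

    def test_too_few_reference_cycles(self):
        with pytest.raises(MonitorError, match="reference"):
            fit_pca(_random_matrix(n=4), k=3)


class TestAssess:
    def test_reference_mean_is_origin(self):
        model = fit_pca(_random_matrix(), k=3)
        a = assess_cycle(model, np.zeros(model.p))
        assert a.t2 == 0.0 and a.dmodx == 0.0 and a.status == "in_control"

    def test_reference_reassessment_calibration(self):
        m = _random_matrix(n=30, p=8, seed=2)
        model = fit_pca(m, k=3)
        flagged = sum(assess_cycle(model, x).out_of_control for x in m.X)
        assert flagged <= int(np.ceil(0.05 * 30)) + 1

    def test_large_shift_flags_and_attributes(self):
        m = _random_matrix(n=20, p=6, seed=4)
        model = fit_pca(m, k=2)
        x = m.X[0].copy()
        x[3] += 10.0  # +10 reference SDs on one feature
        a = assess_cycle(model, x)
        assert a.out_of_control
        # brute-force residual of the perturbed vector dominates at feature 3
        resid = x - model.loadings @ (model.loadings.T @ x)
        np.testing.assert_allclose(a.contributions, resid**2, atol=1e-10)
        assert np.argmax(a.contributions) == 3

    def test_wrong_length_rejected(self):
        model = fit_pca(_random_matrix(), k=2)
        with pytest.raises(MonitorError):
            assess_cycle(model, np.zeros(model.p + 1))


class TestScaleEquivariance:
    def test_unit_change_leaves_assessments_unchanged(self):
        rng = np.random.default_rng(9)

        def make(scale):
            cycles = []
            for i in range(12):
                r = np.random.default_rng(100 + i)
                rec = CycleRecord(cycle_id=i + 1, unit_id="u", start=0.0, end=1.0)
                t = np.linspace(0, 0.9, 20)
                rec.traces["a"] = (t, scale * r.normal(5, 1, 20))
                rec.traces["b"] = (t, r.normal(0, 2, 20))
                cycles.append(rec)
            m = build_cycle_matrix(cycles, ["a", "b"], L=10, ref_ids=list(range(1, 11)))
            model = fit_pca(m, k=2)
            return [assess_cycle(model, x) for x in m.X]

        base, scaled = make(1.0), make(1000.0)
        for a, b in zip(base, scaled):
            assert a.t2 == pytest.approx(b.t2, rel=1e-8)
            assert a.dmodx == pytest.approx(b.dmodx, rel=1e-8)
            assert a.status == b.status


class TestUnivariateLimits:
    def test_constant_series_collapses(self):
        (mu, lo, hi), flags = univariate_limits([3.0, 3.0, 3.0], k_sd=1.0)
        assert mu == lo == hi == 3.0
        assert not flags.any()

    def test_normal_coverage_one_sd(self):
        x = np.random.default_rng(0).normal(size=10_000)
        (_, _, _), flags = univariate_limits(x, k_sd=1.0)
        inside = 1.0 - flags.mean()
        assert abs(inside - 0.6827) < 0.02

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            univariate_limits([1.0])


class TestMonitorStreaming:
    def test_refresh_before_fit_errors(self):
        mon = Monitor(["u:a"], L=4)
        with pytest.raises(MonitorError, match="before fit"):
            mon.refresh(_cycle(1, ["u:a"]))

    def test_in_control_refresh_keeps_cluster(self, nominal_campaign):
        s = monitor_campaign(nominal_campaign.chrom_cycles["proa"],
                             nominal_campaign.chrom_cycles["cex"])
        mon = s["chrom"]["monitor"]
        in_ctrl = [a for a in mon.assessments if a.cycle_id > 42 and not a.out_of_control]
        assert in_ctrl, "nominal monitored cycles should mostly stay in control"
        for a in in_ctrl:
            assert a.t2 <= mon.model.t2_limit

    def test_chart_export_writes_files(self, deviated_summary, tmp_path):
        from mabtrain.monitor import export_charts

        mon = deviated_summary["chrom"]["monitor"]
        files = export_charts(mon.assessments, mon.model, tmp_path,
                              ref_ids=mon.matrix.ref_ids)
        assert len(files) == 3
        for f in files:
            assert (tmp_path / f.split("/")[-1]).stat().st_size > 0


class TestDetectionAndCalibration:
    def test_detection_power_five_sigma(self, nominal_campaign):
        """A >=5 reference-SD shift on any one sensor's trace is flagged with
        probability >= 0.95 over 100 seeded replicates."""
        s = monitor_campaign(nominal_campaign.chrom_cycles["proa"],
                             nominal_campaign.chrom_cycles["cex"])
        mon = s["chrom"]["monitor"]
        m, model = mon.matrix, mon.model
        L = m.L
        rng = np.random.default_rng(123)
        hits = 0
        for rep in range(100):
            base = m.X[rng.integers(0, model.n_ref)].copy()
            sensor = rng.integers(0, len(CHROM_SENSORS))
            base[sensor * L:(sensor + 1) * L] += 5.0  # +5 SD in scaled units
            hits += assess_cycle(model, base).out_of_control
        assert hits >= 95

    def test_false_alarm_rate_nominal_campaigns(self):
        """<= 2*alpha of steady-state chromatography cycles flagged across 20
        seeded nominal campaigns."""
        from mabtrain import run_campaign

        flagged = total = 0
        for seed in range(1, 21):
            res = run_campaign(schedule=[], seed=seed)
            s = monitor_campaign(res.chrom_cycles["proa"], res.chrom_cycles["cex"])
            flagged += len(s["chrom"]["flagged_cycles"])
            flagged += len(s["chrom"]["flagged_reference_cycles"])
            total += 47  # steady-state cycles 7..53
        assert flagged / total <= 0.10
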