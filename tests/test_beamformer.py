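"""DICS/LCMV beamforming: unit gain, localization, virtual sensors."""

import numpy as np
import pytest

from speechtrack.beamformer import (dics_filter, lcmv_virtual_sensor,
                                    source_coherence_map)
from speechtrack.coherence import csd
from speechtrack.forward import make_grid, make_sensor_array, sphere_leadfield
from speechtrack.preprocess import EpochSet
from speechtrack.simulate import (SimulationConfig, SimulationContext,
                                  condition_subset, synth_subject)


@pytest.fixture(scope="module")
def geometry():
    sensors = make_sensor_array(32, 0.12)
    grid = make_grid(0.02, 0.09)
    return sphere_leadfield(grid, sensors)


@pytest.fixture(scope="module")
def band_csd(geometry):
    rng = np.random.default_rng(0)
    n = geometry.sensors.n_sensors
    eps = rng.standard_normal((40, n, 256))
    c = csd(EpochSet(epochs=eps, rate=256.0))
    return c.band_average(4.0, 9.0)


@pytest.fixture(scope="module")
def single_source_ctx():
    cfg = SimulationConfig(n_trials_per_condition=30, conditions=("nat",),
                           source_positions={"SRC": (0.045, 0.0, 0.03)},
                           coupling_alpha={(g, "nat", "SRC"): 0.7
                                           for g in ("EB", "SI")},
                           lag_tau_ms={"SRC": 20.0},
                           n_sensors=32, grid_spacing=0.02, seed=21)
    return cfg, SimulationContext(cfg)


class TestDicsFilter:
    def test_unit_gain(self, band_csd, geometry):
        point = geometry.grid.nearest_inside([0.04, 0.0, 0.02])
        f = dics_filter(band_csd, geometry, point)
        gain = f.weights[0] @ (geometry.L[point] @ f.orientation)
        assert gain == pytest.approx(1.0, abs=1e-8)

    def test_vector_filter_unit_gain_on_tangential_subspace(self, band_csd, geometry):
        point = geometry.grid.nearest_inside([0.04, 0.0, 0.02])
        f = dics_filter(band_csd, geometry, point, scalar=False)
        L = geometry.L[point]
        WL = f.weights @ L
        # the sphere is blind to radial dipoles: W L is the projector onto
        # the visible 2-D subspace, identity there
        evals = np.sort(np.linalg.eigvals(WL).real)
        np.testing.assert_allclose(evals, [0.0, 1.0, 1.0], atol=1e-6)

    def test_zero_lambda_matches_analytic_solution(self, geometry):
        rng = np.random.default_rng(5)
        n = geometry.sensors.n_sensors
        A = rng.standard_normal((n, n))
        S = A @ A.T + n * np.eye(n)  # well-conditioned
        point = geometry.grid.nearest_inside([0.04, 0.0, 0.02])
        f = dics_filter(S, geometry, point, lam=0.0)
        Sinv = np.linalg.inv(S)
        lo = geometry.L[point] @ f.orientation
        expected = (Sinv @ lo) / (lo @ Sinv @ lo)
        np.testing.assert_allclose(f.weights[0], expected, rtol=1e-8)

    def test_output_power_peaks_at_source(self, single_source_ctx):
        cfg, ctx = single_source_ctx
        subj = synth_subject(cfg, "EB", 4, ctx=ctx)
        c = csd(subj)
        Sband = c.band_average(4.0, 9.0)[:ctx.sensors.n_sensors,
                                         :ctx.sensors.n_sensors]
        true_pt = ctx.grid.nearest_inside(cfg.source_positions["SRC"])
        def power(pt):
            f = dics_filter(Sband, ctx.leadfield, pt)
            return np.real(f.weights[0] @ Sband @ np.conj(f.weights[0]))
        p_true = power(true_pt)
        far = [i for i in range(ctx.grid.n_inside)
               if np.linalg.norm(ctx.grid.masked_points[i]
                                 - ctx.grid.masked_points[true_pt]) >= 0.04]
        assert all(power(i) < p_true for i in far[::7])


class TestSourceCoherenceMap:
    def test_band_label(self, single_source_ctx):
        cfg, ctx = single_source_ctx
        subj = synth_subject(cfg, "EB", 4, ctx=ctx)
        m = source_coherence_map(subj, ctx.leadfield)
        assert m.band_label == "4-9 Hz"

    def test_planted_source_recovered(self, single_source_ctx):
        cfg, ctx = single_source_ctx
        subj = synth_subject(cfg, "EB", 8, ctx=ctx)
        m = source_coherence_map(subj, ctx.leadfield)
        true_pos = ctx.grid.masked_points[
            ctx.grid.nearest_inside(cfg.source_positions["SRC"])]
        assert np.linalg.norm(m.argmax_point() - true_pos) <= cfg.grid_spacing + 1e-12

    def test_uncoupled_data_stays_at_null_level(self, single_source_ctx):
        cfg, ctx = single_source_ctx
        import dataclasses
        cfg0 = dataclasses.replace(
            cfg, coupling_alpha={(g, "nat", "SRC"): 0.0 for g in ("EB", "SI")})
        subj = synth_subject(cfg0, "EB", 9, ctx=ctx)
        m = source_coherence_map(subj, ctx.leadfield)
        # permutation null: envelope trials shuffled relative to data
        rng = np.random.default_rng(0)
        null_max = []
        for _ in range(20):
            shuffled = EpochSet(epochs=subj.epochs, rate=subj.rate,
                                envelope_epochs=subj.envelope_epochs[
                                    rng.permutation(subj.n_trials)])
            null_max.append(source_coherence_map(shuffled, ctx.leadfield).values.max())
        assert m.values.max() <= np.quantile(null_max, 0.95) * 1.25

    def test_map_invariant_to_global_sensor_gain(self, single_source_ctx):
        cfg, ctx = single_source_ctx
        subj = synth_subject(cfg, "EB", 10, ctx=ctx)
        m1 = source_coherence_map(subj, ctx.leadfield)
        scaled = EpochSet(epochs=subj.epochs * 25.0, rate=subj.rate,
                          envelope_epochs=subj.envelope_epochs)
        m2 = source_coherence_map(scaled, ctx.leadfield)
        np.testing.assert_allclose(m2.values, m1.values, atol=1e-9)

    def test_window_outside_range_rejected(self, single_source_ctx):
        cfg, ctx = single_source_ctx
        subj = synth_subject(cfg, "EB", 4, ctx=ctx)
        with pytest.raises(ValueError):
            source_coherence_map(subj, ctx.leadfield, windows=((35.0, 2.0),))


class TestLcmvVirtualSensor:
    def test_waveform_recovered_at_snr_zero(self, single_source_ctx):
        from speechtrack.simulate import _pink_noise, _theta_component
        cfg, ctx = single_source_ctx
        seed = 77
        subj = synth_subject(cfg, "EB", seed, ctx=ctx)
        pt = ctx.grid.nearest_inside(cfg.source_positions["SRC"])
        vs = lcmv_virtual_sensor(subj, ctx.leadfield, pt)
        # reconstruct the true source series from the generator's recipe
        fs = cfg.meg_rate
        n = vs.epochs.size
        env = ctx.envelopes["nat"].samples[:n]
        drv = np.roll(_theta_component(env, fs), int(round(20 * fs / 1000)))
        rng = np.random.default_rng(seed)
        s_true = 0.7 * drv + np.sqrt(1 - 0.49) * _pink_noise(n, rng)
        s_tr = s_true.reshape(vs.epochs.shape)
        s_dm = (s_tr - s_tr.mean(axis=1, keepdims=True)).ravel()
        r = np.corrcoef(vs.epochs.ravel(), s_dm)[0, 1]
        assert abs(r) > 0.9

    def test_rank_one_source_svd_gain(self, geometry):
        # purely 1-D oriented source: SVD keeps ~all variance
        rng = np.random.default_rng(3)
        pt = geometry.grid.nearest_inside([0.04, 0.0, 0.02])
        ori = np.array([0.0, 1.0, 0.0])
        gain = geometry.L[pt] @ ori
        s = rng.standard_normal((20, 256))
        eps = gain[None, :, None] * s[:, None, :]
        eps += 1e-6 * np.abs(gain).max() * rng.standard_normal(eps.shape)
        e = EpochSet(epochs=eps, rate=256.0)
        vs = lcmv_virtual_sensor(e, geometry, pt)
        assert vs.svd_gain >= 0.99

    def test_common_filter_equals_average_covariance_filter(self, geometry):
        # the filter is built once from the trial-averaged covariance;
        # recomputing from the same pooled covariance is identical
        rng = np.random.default_rng(4)
        n = geometry.sensors.n_sensors
        eps = rng.standard_normal((10, n, 128))
        e = EpochSet(epochs=eps, rate=128.0)
        pt = geometry.grid.nearest_inside([0.04, 0.0, 0.02])
        v1 = lcmv_virtual_sensor(e, geometry, pt)
        v2 = lcmv_virtual_sensor(e, geometry, pt)
        np.testing.assert_array_equal(v1.epochs, v2.epochs)


class TestCrossMethodConsistency:
    def test_dics_matches_lcmv_bandpassed_coherence(self, single_source_ctx):
        # frequency-domain DICS coherence at the source point vs coherence
        # of the LCMV virtual sensor with the envelope over the same band
        from speechtrack.coherence import coherence
        cfg, ctx = single_source_ctx
        subj = synth_subject(cfg, "EB", 15, ctx=ctx)
        pt = ctx.grid.nearest_inside(cfg.source_positions["SRC"])
        m = source_coherence_map(subj, ctx.leadfield, windows=((6.5, 2.5),))
        z_dics = m.values[pt]

        vs = lcmv_virtual_sensor(subj, ctx.leadfield, pt)
        e2 = EpochSet(epochs=vs.epochs[:, None, :], rate=subj.rate,
                      envelope_epochs=subj.envelope_epochs)
        c = csd(e2)
        S = c.band_average(4.0, 9.0)  # same band averaging as DICS
        coh_lcmv = abs(S[0, 1]) / np.sqrt(S[0, 0].real * S[1, 1].real)
        assert abs(np.tanh(z_dics) - coh_lcmv) <= 0.05
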