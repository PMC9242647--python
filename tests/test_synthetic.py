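import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pmindex.synthetic import (DEFAULT_SENSORS, GeometryError, KineticModel,
                               SensorKinetics, default_model, generate_geometry,
                               half_time, jittered_model, render_stack,
                               roi_for_cell, simulate_index_series,
                               simulate_occupancy, simulate_puncta_occupancy)


def simple_model(**overrides) -> KineticModel:
    kw = dict(depletion_delay=0.0, depletion_rate=0.002, floor=0.1,
              recovery_delay=0.0, recovery_rate=0.01, plateau=0.9)
    kw.update(overrides)
    return KineticModel(t_hypoxia=0.0, t_reoxy=1e7, sensors={"x": SensorKinetics(**kw)})


class TestOccupancy:
    def test_baseline_before_stress(self):
        model = default_model()
        assert simulate_occupancy(model, "PIP2", 0.0) == 1.0
        assert simulate_occupancy(model, "Lgl", model.t_hypoxia - 1.0) == 1.0

    def test_limit_is_floor_without_reoxygenation(self):
        model = simple_model()
        assert simulate_occupancy(model, "x", 1e6) == pytest.approx(0.1, abs=1e-9)

    def test_closed_form_decay_value(self):
        # floor + (1 - floor) * exp(-rate * dt) at dt = 500 s
        model = simple_model()
        value = simulate_occupancy(model, "x", 500.0)
        assert value == pytest.approx(0.1 + 0.9 * np.exp(-1.0), rel=1e-12)

    def test_decay_matches_ode_integration(self):
        # independent oracle: integrate df/dt = -k (f - floor) numerically
        model = simple_model()
        sol = solve_ivp(lambda t, f: -0.002 * (f - 0.1), (0.0, 500.0), [1.0],
                        rtol=1e-10, atol=1e-12)
        assert simulate_occupancy(model, "x", 500.0) == pytest.approx(
            sol.y[0, -1], rel=1e-6)

    def test_unknown_sensor_raises(self):
        with pytest.raises(KeyError, match="unknown sensor"):
            simulate_occupancy(default_model(), "nope", 0.0)

    def test_continuity_everywhere(self):
        model = default_model()
        t = np.linspace(0.0, 5400.0, 20000)
        for sensor in DEFAULT_SENSORS:
            f = simulate_occupancy(model, sensor, t)
            assert np.max(np.abs(np.diff(f))) < 5e-3

    def test_bounded_by_one_plus_overshoot(self):
        model = default_model()
        t = np.linspace(0.0, 5400.0, 5000)
        for sensor in DEFAULT_SENSORS:
            amp = model.sensor(sensor).overshoot_amp
            f = simulate_occupancy(model, sensor, t)
            assert np.all(f >= 0.0) and np.all(f <= 1.0 + amp + 1e-12)

    def test_overshoot_transient_present_for_pi4p(self):
        model = default_model()
        t = np.linspace(model.t_hypoxia, model.t_hypoxia + 400.0, 500)
        f = simulate_occupancy(model, "PI4P", t)
        assert f.max() > 1.05
        assert simulate_occupancy(model, "PI4P", model.t_hypoxia) == pytest.approx(1.0)

    def test_half_time_ordering_shipped_defaults(self):
        # independent check on dense grids rather than via half_time internals
        model = default_model()
        grid = np.arange(model.t_hypoxia, model.t_reoxy, 1.0)

        def crossing(sensor):
            k = model.sensor(sensor)
            f = simulate_occupancy(model, sensor, grid)
            return grid[np.nonzero(f <= (1.0 + k.floor) / 2.0)[0][0]]

        assert crossing("Lgl") < crossing("PIP2") < crossing("PI4P")

    def test_recovery_ordering_shipped_defaults(self):
        model = default_model()
        order = [half_time(model, s, "recovery") for s in ("PI4P", "PIP2", "Lgl")]
        assert order[0] < order[1] < order[2]

    def test_half_time_monotone_in_depletion_rate(self):
        t50 = []
        for rate in (0.001, 0.002, 0.004, 0.008):
            model = simple_model(depletion_rate=rate)
            t50.append(half_time(model, "x", "depletion", dt=0.25))
        assert all(a > b for a, b in zip(t50, t50[1:]))

    def test_puncta_pool_depletes_before_pm(self):
        model = default_model()
        grid = np.arange(model.t_hypoxia, model.t_reoxy, 1.0)
        pm = simulate_occupancy(model, "PI4P", grid)
        pu = simulate_puncta_occupancy(model, "PI4P", grid)
        k = model.sensor("PI4P")
        cross_pm = grid[np.nonzero(pm <= (1 + k.floor) / 2)[0][0]]
        cross_pu = grid[np.nonzero(pu <= (1 + k.floor) / 2)[0][0]]
        assert cross_pu < cross_pm


class TestModelValidation:
    def test_floor_above_plateau_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            simple_model(floor=0.95, plateau=0.9)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            simple_model(depletion_rate=-1e-3)

    def test_hypoxia_must_precede_reoxygenation(self):
        with pytest.raises(ValueError, match="precede"):
            KineticModel(t_hypoxia=100.0, t_reoxy=100.0, sensors={})


class TestGeometry:
    def test_single_cell_single_region(self):
        geo = generate_geometry(1, (128, 128), mode="single_cell", seed=7)
        assert list(geo.labels) == [1]
        # membrane band forms a closed ring: the cell interior is not
        # connected to the outside without crossing the band
        from scipy import ndimage
        interior = geo.cell_mask(1) & ~geo.membrane_mask
        filled = ndimage.binary_fill_holes(geo.membrane_mask)
        assert (interior <= filled).all()

    def test_tissue_membrane_adjacent_to_boundaries(self):
        geo = generate_geometry(16, (256, 256), mode="tissue", seed=1)
        assert len(geo.labels) == 16
        # every membrane pixel lies within the band width of a label change
        from scipy import ndimage
        from skimage.segmentation import find_boundaries
        boundary = find_boundaries(geo.cell_label_image, mode="thick")
        near = ndimage.binary_dilation(boundary, iterations=geo.membrane_width_px)
        assert (geo.membrane_mask <= near).all()

    def test_deterministic_for_seed(self):
        a = generate_geometry(16, (256, 256), mode="tissue", seed=1)
        b = generate_geometry(16, (256, 256), mode="tissue", seed=1)
        assert np.array_equal(a.cell_label_image, b.cell_label_image)
        assert np.array_equal(a.nuclei_mask, b.nuclei_mask)

    def test_membrane_disjoint_from_nuclei(self, tissue_geometry):
        assert not (tissue_geometry.membrane_mask & tissue_geometry.nuclei_mask).any()

    def test_every_cell_at_least_200_px(self, tissue_geometry):
        areas = np.bincount(tissue_geometry.cell_label_image.ravel())[1:]
        assert (areas >= 200).all()

    def test_impossible_packing_raises(self):
        with pytest.raises(GeometryError):
            generate_geometry(100, (64, 64), mode="tissue", seed=0)
        with pytest.raises(GeometryError):
            generate_geometry(50, (96, 96), mode="single_cell", seed=0)

    def test_roi_for_cell_covers_cell(self, tissue_geometry):
        roi = roi_for_cell(tissue_geometry, 1)
        roi.validate(tissue_geometry.cell_label_image.shape)
        mask = roi.mask(tissue_geometry.cell_label_image.shape)
        cell = tissue_geometry.cell_mask(1)
        assert (mask & cell).sum() / cell.sum() > 0.9


class TestRender:
    def test_degenerate_noise_equals_ground_truth_render(self):
        geo = generate_geometry(4, (128, 128), mode="tissue", seed=3)
        model = default_model(t_hypoxia=120.0, t_reoxy=480.0)
        stack, gt = render_stack(geo, model, n_frames=3, seed=0,
                                 noise={"gain": 0.0, "read_sigma": 0.0},
                                 drift={"step_sigma": 0.0}, keep_noiseless=True)
        assert np.array_equal(stack.data, gt.noiseless.data)

    def test_mass_conservation_noiseless(self, small_sim):
        gt = small_sim["gt"]
        geo = small_sim["geometry"]
        clean = gt.noiseless.data.astype(np.float64) - gt.background
        for ci, ch in enumerate(gt.noiseless.channels):
            if ch == "ATP":
                continue
            for lab in geo.labels:
                cell = geo.cell_mask(lab)
                totals = clean[:, ci][:, cell].sum(axis=1)
                assert np.ptp(totals) / totals[0] < 1e-3

    def test_determinism_bit_identical(self):
        geo = generate_geometry(2, (96, 96), mode="tissue", seed=5)
        model = default_model(t_hypoxia=60.0, t_reoxy=240.0)
        a, _ = render_stack(geo, model, n_frames=4, seed=9,
                            drift={"step_sigma": 0.3})
        b, _ = render_stack(geo, model, n_frames=4, seed=9,
                            drift={"step_sigma": 0.3})
        assert np.array_equal(a.data, b.data)

    def test_pip2_half_depletes_before_pi4p_in_truth(self, default_sim):
        gt = default_sim["gt"]

        def halfway_frame(channel):
            tr = gt.series(1, channel)
            lo = tr.min()
            target = (tr[0] + lo) / 2.0
            return np.nonzero(tr <= target)[0][0]

        assert halfway_frame("PIP2") < halfway_frame("PI4P")

    def test_ground_truth_index_identity(self, small_sim):
        gt = small_sim["gt"].per_cell
        sel = gt[gt.channel != "ATP"]
        lhs = sel.pm_index
        rhs = (sel.pm_mean - sel.background) / (sel.cyto_mean - sel.background)
        assert np.allclose(lhs, rhs, rtol=1e-9)

    def test_bad_amplitude_rejected(self, tissue_geometry):
        with pytest.raises(ValueError, match="amplitude"):
            render_stack(tissue_geometry, default_model(), n_frames=2,
                         amplitudes={"PIP2": -5.0})

    def test_nonfinite_noise_rejected(self, tissue_geometry):
        with pytest.raises(ValueError, match="finite"):
            render_stack(tissue_geometry, default_model(), n_frames=2,
                         noise={"gain": np.nan})

    def test_unknown_channel_rejected(self, tissue_geometry):
        with pytest.raises(KeyError, match="unknown sensor"):
            render_stack(tissue_geometry, default_model(), channels=["bogus"],
                         n_frames=2)

    def test_drift_recorded_matches_applied(self):
        geo = generate_geometry(2, (96, 96), mode="tissue", seed=5)
        model = default_model(t_hypoxia=60.0, t_reoxy=240.0)
        _, gt = render_stack(geo, model, n_frames=6, seed=11,
                             drift={"step_sigma": 0.4})
        assert np.allclose(gt.drift[["dy", "dx"]].iloc[0], 0.0)
        assert gt.drift.shape == (6, 3)
        assert gt.drift[["dy", "dx"]].abs().to_numpy().max() > 0


class TestSeriesSimulator:
    def test_matches_render_arithmetic(self, small_sim):
        # at occupancy 1 the index implied by the area fractions matches the
        # analytic formula
        model = default_model()
        t, y = simulate_index_series(model, "PIP2", n_frames=5,
                                     area_fractions=(0.2, 0.7))
        k = model.sensor("PIP2")
        expected = (k.pm_fraction / 0.2) / ((1 - k.pm_fraction) / 0.7)
        assert y[0] == pytest.approx(expected)

    def test_noise_reproducible(self):
        model = default_model()
        _, y1 = simulate_index_series(model, "PIP2", noise_sigma=0.1,
                                      rng=np.random.default_rng(5))
        _, y2 = simulate_index_series(model, "PIP2", noise_sigma=0.1,
                                      rng=np.random.default_rng(5))
        assert np.array_equal(y1, y2)

    def test_jittered_model_varies_but_validates(self):
        model = default_model()
        jit = jittered_model(model, np.random.default_rng(0))
        assert jit.sensor("PIP2").depletion_rate != model.sensor("PIP2").depletion_rate
        for name, k in jit.sensors.items():
            k.validate(name)
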