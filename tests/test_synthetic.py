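"""Synthetic microscopy generator: placement, rendering, time-lapse."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import linregress

import smfoci as m
from smfoci.errors import ConfigError, ConsistencyError


class TestPlaceFoci:
    def test_zero_foci_gives_empty_list(self, small_cell):
        assert m.place_foci(small_cell, 0, "central", seed=0) == []

    def test_negative_count_rejected(self, small_cell):
        with pytest.raises(ConfigError):
            m.place_foci(small_cell, -1, "central", seed=0)

    def test_unknown_mode_rejected(self, small_cell):
        with pytest.raises(ConfigError):
            m.place_foci(small_cell, 5, "ring", seed=0)

    def test_central_mode_concentrates_within_200nm(self, small_cell):
        foci = m.place_foci(small_cell, 1000, "central", seed=1)
        w = np.array([f.width_coordinate for f in foci])
        assert np.mean(np.abs(w) <= 0.2) >= 0.90

    def test_peripheral_mode_is_bimodal_at_300nm(self, small_cell):
        foci = m.place_foci(small_cell, 1000, "peripheral", seed=1)
        w = np.array([f.width_coordinate for f in foci])
        profile = m.width_histogram(w, bin_width=0.1)
        top2 = np.argsort(profile.histogram)[::-1][:2]
        assert sorted(np.round(profile.bin_centres[top2], 2)) == [-0.3, 0.3]

    def test_all_positions_inside_polygon(self, small_cell):
        for mode in ("central", "peripheral", "uniform"):
            for f in m.place_foci(small_cell, 300, mode, seed=3):
                assert small_cell.contains(*f.position)
                assert abs(f.width_coordinate) <= small_cell.width / 2


class TestRenderFrame:
    def test_empty_frame_mean_near_offset(self, small_config):
        img = m.render_frame([], [], small_config, seed=0)
        assert img.mean() == pytest.approx(small_config.offset, abs=1.0)

    def test_single_focus_flux_matches_unit_intensity(self, small_cell,
                                                      small_config):
        foci = m.place_foci(small_cell, 1, "central", seed=2)
        img = m.render_frame([small_cell], foci, small_config, noise=False)
        excess = img.sum() - small_config.offset * img.size
        expected = (1 + small_config.copies_per_cell
                    + small_config.autofluorescence_equiv)
        assert excess == pytest.approx(
            expected * small_config.unit_intensity, rel=0.05)

    def test_focus_outside_cells_rejected(self, small_cell, small_config):
        stray = m.GroundTruthFocus(0, "A", 0.0, (0.2, 0.2), 1, 0.0)
        with pytest.raises(ConsistencyError):
            m.render_frame([small_cell], [stray], small_config, seed=0)

    def test_seed_determinism(self, small_cell, small_config):
        foci = m.place_foci(small_cell, 2, "uniform", seed=5)
        a = m.render_frame([small_cell], foci, small_config, seed=9)
        b = m.render_frame([small_cell], foci, small_config, seed=9)
        assert np.array_equal(a, b)

    def test_render_detect_round_trip(self, small_cell, small_config):
        """Rendered foci are recovered within 1 px at default SNR."""
        hits = total = 0
        for seed in range(50):
            foci = m.place_foci(small_cell, 2, "uniform", seed=200 + seed)
            img = m.render_frame([small_cell], foci, small_config, seed=seed)
            records = m.detect_foci(img, [small_cell], 3.0)
            det = np.array([[r.x_um, r.y_um] for r in records])
            gt = np.array([f.position for f in foci])
            total += len(gt)
            if len(det):
                d, _ = cKDTree(det).query(gt, k=1)
                hits += int(np.sum(d <= 0.1))
        assert hits / total >= 0.95


class TestGenerateTimelapse:
    def test_duration_shorter_than_interval_rejected(self):
        with pytest.raises(ConfigError):
            m.TimelapseConfig(duration=5, interval=10)

    def test_zero_growth_keeps_lengths_constant(self):
        config = m.TimelapseConfig(n_cells=10, duration=60, interval=30,
                                   growth_rate=0.0, seed=1)
        result = m.generate_timelapse(config)
        by_time = result.cell_table.pivot_table(
            index="cell_id", columns="time_point", values="length_um")
        assert np.allclose(by_time.std(axis=1), 0.0)

    def test_filamentation_after_onset(self, short_timelapse):
        config = m.TimelapseConfig(n_cells=10, duration=90, interval=30,
                                   seed=1)
        result = m.generate_timelapse(config)
        tbl = result.cell_table
        t0 = tbl[tbl.time_point == 0].set_index("cell_id").length_um
        t90 = tbl[tbl.time_point == 90].set_index("cell_id").length_um
        assert (t90 > t0).all()
        # exponential growth for 60 min past onset
        assert np.allclose(t90 / t0, np.exp(config.growth_rate * 60),
                           rtol=1e-6)

    def test_seed_determinism_bit_identical(self):
        config = m.TimelapseConfig(n_cells=8, duration=10, interval=10,
                                   seed=77)
        a = m.generate_timelapse(config)
        b = m.generate_timelapse(config)
        for ch in a.stacks:
            assert np.array_equal(a.stacks[ch], b.stacks[ch])
        assert a.foci.equals(b.foci)

    def test_foci_inside_cells_at_every_time_point(self, short_timelapse):
        cells = {
            (t, c.cell_id): c
            for t, cl in short_timelapse.cells.items() for c in cl
        }
        for f in short_timelapse.foci.itertuples():
            cell = cells[(f.time_point, f.cell_id)]
            assert cell.contains(f.x_um, f.y_um, tol=1e-6)

    def test_constant_density_scaling(self):
        """Ground-truth foci counts scale with cell area at the
        configured density (slope within 10%, intercept near 0)."""
        config = m.TimelapseConfig(n_cells=60, duration=90, interval=30,
                                   seed=6)
        result = m.generate_timelapse(config)
        foci = result.foci[result.foci.channel == "A"]
        counts = foci.groupby(["time_point", "cell_id"]).size()
        tbl = result.cell_table.set_index(["time_point", "cell_id"])
        areas = tbl.area_um2
        n = counts.reindex(areas.index, fill_value=0)
        assert len(n) >= 200
        fit = linregress(areas.to_numpy(), n.to_numpy())
        assert fit.slope == pytest.approx(config.focus_density["A"],
                                          rel=0.10)
        assert abs(fit.intercept) < 0.35

    def test_dimer_switch_doubles_molecules_per_focus(self, short_timelapse):
        foci = short_timelapse.foci
        a = foci[foci.channel == "A"]
        assert set(a[a.time_point < 30].n_molecules) == {1}
        config = m.TimelapseConfig(n_cells=10, duration=40, interval=20,
                                   seed=3)
        late = m.generate_timelapse(config).foci.query(
            "channel == 'A' and time_point >= 30")
        assert set(late.n_molecules) == {2}

    def test_replication_shutdown_preset_decays_density(self):
        config = m.replication_shutdown_preset(n_cells=40, duration=60,
                                               interval=30, seed=8)
        result = m.generate_timelapse(config)
        foci = result.foci[result.foci.channel == "A"]
        tbl = result.cell_table.set_index(["time_point", "cell_id"])
        dens = {
            t: len(foci[foci.time_point == t])
            / tbl.loc[t].area_um2.sum()
            for t in result.time_points
        }
        assert dens[60.0] < 0.5 * dens[0.0]
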