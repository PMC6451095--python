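"""Directional colocalization, chance baseline, area-shell histograms."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

import smfoci as m
from smfoci.errors import ConfigError, ConsistencyError


def _table(rows):
    return pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um",
                                       "time_point"])


class TestColocalize:
    def test_identical_coordinates_fully_colocalized(self):
        a = _table([(0, 1.0, 1.0, 0.0), (0, 2.0, 1.0, 0.0)])
        summary, pairs = m.colocalize(a, a.copy())
        assert summary.pct_a_with_b == 100.0
        assert summary.pct_b_with_a == 100.0
        assert len(pairs) == 2

    def test_radius_boundary_inclusive_at_218nm(self):
        a = _table([(0, 1.0, 1.0, 0.0)])
        at_radius = _table([(0, 1.218, 1.0, 0.0)])
        beyond = _table([(0, 1.219, 1.0, 0.0)])
        assert m.colocalize(a, at_radius)[0].pct_a_with_b == 100.0
        assert m.colocalize(a, beyond)[0].pct_a_with_b == 0.0

    def test_directional_percentage(self):
        a = _table([(0, float(i), 0.5, 0.0) for i in range(10)])
        b = _table([(0, 0.05, 0.5, 0.0), (0, 1.1, 0.5, 0.0),
                    (0, 2.05, 0.5, 0.0)])
        summary, _ = m.colocalize(a, b)
        assert summary.pct_a_with_b == pytest.approx(30.0)
        assert summary.pct_b_with_a == pytest.approx(100.0)

    def test_cross_cell_matches_disallowed(self):
        a = _table([(0, 1.0, 1.0, 0.0)])
        b = _table([(1, 1.0, 1.0, 0.0)])
        assert m.colocalize(a, b)[0].pct_a_with_b == 0.0

    def test_mixed_time_points_rejected(self):
        a = _table([(0, 1.0, 1.0, 0.0)])
        b = _table([(0, 1.0, 1.0, 10.0)])
        with pytest.raises(ConsistencyError):
            m.colocalize(a, b)

    def test_match_symmetry_and_radius_monotonicity(self):
        rng = np.random.default_rng(3)
        a = _table([(0, x, y, 0.0) for x, y in rng.uniform(0, 3, (20, 2))])
        b = _table([(0, x, y, 0.0) for x, y in rng.uniform(0, 3, (15, 2))])
        prev = -1.0
        for radius in (50, 150, 218, 400):
            sa, pa = m.colocalize(a, b, radius)
            sb, pb = m.colocalize(b, a, radius)
            matched_ab = {(r.index_a, r.index_b) for r in pa.itertuples()}
            matched_ba = {(r.index_b, r.index_a) for r in pb.itertuples()}
            assert matched_ab == matched_ba
            assert sa.pct_a_with_b >= prev
            prev = sa.pct_a_with_b


class TestChanceColocalization:
    def test_closed_form_single_cell(self):
        cell = m.generate_cell(3.945, 1.0, cell_id=0, centre=(5, 5))
        assert cell.area == pytest.approx(3.73, abs=0.01)
        b = _table([(0, 5.0, 5.0, 0.0)])
        chance = m.chance_colocalization([cell], b)
        assert chance == pytest.approx(
            100 * np.pi * 0.218**2 / cell.area, rel=1e-6)
        assert chance == pytest.approx(4.0, abs=0.2)

    def test_no_partner_foci_zero_chance(self):
        cell = m.generate_cell(3.0, 1.0, cell_id=0, centre=(5, 5))
        assert m.chance_colocalization([cell], _table([])) == 0.0

    def test_analytic_matches_monte_carlo_within_half_point(self):
        """Uniformly placed query foci colocalize with fixed partner
        foci at the analytic area-fraction rate (10^4 placements)."""
        rng = np.random.default_rng(11)
        cells = [m.generate_cell(3.945, 1.0, cell_id=i, centre=(5, 5))
                 for i in range(100)]
        b_rows, hits, n_mc = [], 0, 0
        for cell in cells:
            b = m.place_foci(cell, 1, "central", rng=rng, channel="B")[0]
            b_rows.append((cell.cell_id, *b.position, 0.0))
            queries = m.place_foci(cell, 100, "uniform", rng=rng)
            for q in queries:
                n_mc += 1
                hits += np.hypot(q.position[0] - b.position[0],
                                 q.position[1] - b.position[1]) <= 0.218
        mc_pct = 100 * hits / n_mc
        analytic = m.chance_colocalization(cells, _table(b_rows))
        assert n_mc == 10_000
        assert abs(analytic - mc_pct) <= 0.5


class TestAreaShellHistogram:
    def test_equal_area_edges_closed_form(self):
        _, edges = m.area_shell_histogram([], radius_max_nm=218, n_bins=4)
        assert np.allclose(edges, [0.0, 109.0, 154.149, 188.794, 218.0],
                           atol=0.05)

    def test_empty_input_all_zero_bins(self):
        counts, _ = m.area_shell_histogram([], n_bins=6)
        assert counts.sum() == 0

    def test_invalid_bins_rejected(self):
        with pytest.raises(ConfigError):
            m.area_shell_histogram([1.0], n_bins=0)

    def test_uniform_density_gives_flat_histogram(self):
        """Uniform points around references fill equal-area annuli
        evenly (chi-square p > 0.01 at n = 10^4)."""
        rng = np.random.default_rng(5)
        r = 218 * np.sqrt(rng.uniform(0, 1, 10_000))
        counts, _ = m.area_shell_histogram(r, n_bins=10)
        assert chisquare(counts).pvalue > 0.01


class TestTimecourse:
    def test_single_time_point_matches_colocalize(self, short_timelapse):
        foci = short_timelapse.foci
        a = foci.query("channel == 'A' and time_point == 0")
        b = foci.query("channel == 'B' and time_point == 0")
        table = m.colocalization_timecourse(a, b,
                                            {0.0: short_timelapse.cells[0.0]})
        summary, _ = m.colocalize(a, b)
        assert len(table) == 1
        assert table.pct_a_with_b[0] == pytest.approx(summary.pct_a_with_b)

    def test_missing_channel_skipped_with_warning(self):
        a = _table([(0, 1.0, 1.0, 0.0), (0, 1.0, 1.0, 10.0)])
        b = _table([(0, 1.0, 1.0, 0.0)])
        with pytest.warns(UserWarning):
            table = m.colocalization_timecourse(a, b, {})
        assert list(table.time_point) == [0.0]

    def test_forced_coplacement_recovered(self):
        """Ground truth generated with 25% forced co-placement (among
        cells holding partner foci) recovers ~25% plus chance."""
        config = m.TimelapseConfig(
            n_cells=60, duration=10, interval=10, seed=21,
            coloc_fraction=0.25,
            focus_density={"A": 0.8, "B": 0.4},
        )
        result = m.generate_timelapse(config)
        foci = result.foci.query("time_point == 0")
        b = foci[foci.channel == "B"]
        cells_with_b = set(b.cell_id)
        a = foci[(foci.channel == "A")
                 & foci.cell_id.isin(cells_with_b)]
        summary, _ = m.colocalize(a, b)
        chance = m.chance_colocalization(
            [c for c in result.cells[0.0] if c.cell_id in cells_with_b], b)
        expected = 25 + 0.75 * chance  # the unforced 75% still hit by chance
        assert summary.pct_a_with_b == pytest.approx(expected, abs=5.0)

    def test_independent_placement_matches_chance(self):
        """With independent channels the observed directional
        percentage sits at the analytic chance baseline."""
        config = m.TimelapseConfig(
            n_cells=60, duration=10, interval=10, seed=22,
            focus_density={"A": 3.0, "B": 0.4},
            spatial_mode={"A": "uniform", "B": "uniform"},
            stoichiometry_schedule={"A": (1, 1, None), "B": (1, 1, None)},
        )
        result = m.generate_timelapse(config)
        foci = result.foci.query("time_point == 0")
        a = foci[foci.channel == "A"]
        b = foci[foci.channel == "B"]
        summary, _ = m.colocalize(a, b)
        chance = m.chance_colocalization(result.cells[0.0], b)
        sem = np.sqrt(chance * (100 - chance) / len(a))
        assert abs(summary.pct_a_with_b - chance) <= 3 * sem + 0.5
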