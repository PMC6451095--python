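"""Unit-intensity calibration, copy numbers and bound fractions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smfoci as m
from smfoci.errors import CalibrationError, ConfigError
from smfoci.stoichiometry import (find_steps, radial_illumination_profile,
                                  unit_intensity_from_steps)


class TestFlattenField:
    def test_uniform_profile_is_identity(self):
        img = np.random.default_rng(0).uniform(50, 150, (32, 32))
        assert np.allclose(m.flatten_field(img, np.ones((32, 32))), img)

    def test_corner_scaled_up_by_profile_ratio(self):
        profile = radial_illumination_profile((64, 64), 1.12)
        img = np.full((64, 64), 100.0)
        flat = m.flatten_field(img, profile)
        assert flat[0, 0] == pytest.approx(112.0, rel=0.01)

    def test_render_flatten_round_trip(self):
        profile = radial_illumination_profile((64, 64), 1.12)
        truth = np.random.default_rng(1).uniform(80, 120, (64, 64))
        # normalization is to the sampled maximum, so agreement is to
        # within the grid-sampling error of the profile peak
        assert np.allclose(m.flatten_field(truth * profile, profile),
                           truth, rtol=1e-3)

    def test_nonpositive_profile_rejected(self):
        with pytest.raises(ConfigError):
            m.flatten_field(np.ones((4, 4)), np.zeros((4, 4)))


class TestUnitIntensityFromSteps:
    def test_noiseless_staircase_unit_100(self):
        stair = m.Trajectory(np.repeat([300.0, 200.0, 100.0, 0.0], 25))
        cal = unit_intensity_from_steps([stair] * 10)
        assert cal.unit_intensity == pytest.approx(100.0, rel=1e-6)

    def test_constant_trajectories_raise_calibration_error(self):
        flat = m.Trajectory(np.full(300, 50.0))
        with pytest.raises(CalibrationError):
            unit_intensity_from_steps([flat] * 10)

    def test_too_few_trajectories_rejected(self):
        stair = m.Trajectory(np.repeat([200.0, 100.0, 0.0], 30))
        with pytest.raises(CalibrationError):
            unit_intensity_from_steps([stair] * 5)

    def test_simulated_bleaching_recovers_unit_within_10pct(self):
        """Photobleaching trajectories at SNR 3 with unit 100 calibrate
        back to 100 within 10%."""
        config = m.SimulationConfig(
            n_mol_per_complex=3, k_on_complex=1.0, k_off_complex=0.0,
            k_off_molecule=0.0, tau_bleach=3.0, snr=3.0, seed=5,
        )
        scaled = [m.Trajectory(t.intensities * 100.0)
                  for t in m.simulate_ensemble(config, 60)]
        cal = unit_intensity_from_steps(scaled)
        assert cal.unit_intensity == pytest.approx(100.0, rel=0.10)

    def test_find_steps_locates_noiseless_changes(self):
        y = np.repeat([5.0, 3.0, 0.0], 20)
        assert find_steps(y) == [20, 40]


class TestCopyNumber:
    def test_paper_style_inversion(self):
        # 20.6 integrated units with 2.5 autofluorescence -> 18.1 copies
        est = m.copy_number(20.6, 1.0, 2.5, 1.0)
        assert est.n_molecules == pytest.approx(18.1)

    def test_autofluorescence_exactly_cancels(self):
        assert m.copy_number(2.5, 1.0, 2.5, 1.0).n_molecules == 0.0

    def test_negative_clamps_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            est = m.copy_number(1.0, 1.0, 2.5, 1.0)
        assert est.n_molecules == 0.0

    def test_invalid_unit_rejected(self):
        with pytest.raises(ConfigError):
            m.copy_number(10.0, 1.0, 2.5, 0.0)


class TestConcentration:
    def test_one_molecule_in_1p66_fl_is_one_nanomolar(self):
        assert m.concentration(1, 1.66) == pytest.approx(1.0, rel=0.01)

    def test_zero_molecules_zero_concentration(self):
        assert m.concentration(0, 2.0) == 0.0

    def test_printed_pair_inversion(self):
        # 18.1 molecules at 5.4 nM implies V ~ 5.57 fL
        volume = 18.1 / (5.4e-9 * 6.02214076e23 * 1e-15)
        assert m.concentration(18.1, volume) == pytest.approx(5.4, rel=1e-9)

    def test_homogeneity(self):
        assert m.concentration(3, 2.0) == pytest.approx(
            m.concentration(6, 4.0))

    def test_invalid_volume_rejected(self):
        with pytest.raises(ConfigError):
            m.concentration(1, 0.0)


class TestMoleculesPerFocus:
    def test_unit_intensity_is_one_molecule(self):
        assert m.molecules_per_focus(100.0, 100.0) == (1.0, 1)

    def test_double_unit_is_a_dimer(self):
        assert m.molecules_per_focus(200.0, 100.0)[1] == 2

    def test_negative_intensity_rejected(self):
        with pytest.raises(ConfigError):
            m.molecules_per_focus(-1.0, 100.0)

    def test_timelapse_dimer_switch_recovered_from_rendered_frames(
            self, short_timelapse):
        """Modal molecules per focus is 1 before the dimerization
        switch; a post-switch frame yields mode 2."""
        config = short_timelapse.config
        img = short_timelapse.stacks["A"][0].astype(float)
        cells = short_timelapse.cells[0.0]
        records = m.detect_foci(img, cells, 3.0)
        counts = [
            m.molecules_per_focus(r.integrated_intensity,
                                  config.unit_intensity)[1]
            for r in records
        ]
        values, freq = np.unique(counts, return_counts=True)
        assert values[np.argmax(freq)] == 1

        late_cfg = m.TimelapseConfig(n_cells=40, duration=40, interval=40,
                                     seed=13)
        late = m.generate_timelapse(late_cfg)
        img2 = late.stacks["A"][1].astype(float)
        cells2 = late.cells[40.0]
        records2 = m.detect_foci(img2, cells2, 3.0)
        counts2 = [
            m.molecules_per_focus(r.integrated_intensity,
                                  late_cfg.unit_intensity)[1]
            for r in records2
        ]
        values2, freq2 = np.unique(counts2, return_counts=True)
        assert values2[np.argmax(freq2)] == 2


class TestBoundFraction:
    def test_monomeric_undamaged_cells(self):
        assert m.bound_fraction(2, 1, 18) == pytest.approx(100 * 2 / 18)

    def test_dimeric_damaged_cells_double(self):
        assert m.bound_fraction(2, 2, 18) == pytest.approx(100 * 4 / 18)

    def test_zero_foci_zero_bound(self):
        assert m.bound_fraction(0, 1, 18) == 0.0

    def test_invalid_copies_rejected(self):
        with pytest.raises(ConfigError):
            m.bound_fraction(2, 1, 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(foci=st.floats(0, 10), mol=st.floats(0.1, 4),
           copies=st.floats(1, 100))
    def test_doubling_molecules_doubles_fraction(self, foci, mol, copies):
        assert m.bound_fraction(foci, 2 * mol, copies) == pytest.approx(
            2 * m.bound_fraction(foci, mol, copies))


def test_copy_number_round_trip_on_rendered_cells(short_timelapse):
    """Cells rendered at 18 copies with autofluorescence 2.5 give back
    a mean copy number within 10% of 18 over >= 50 cells."""
    from smfoci.detection import per_cell_stats

    config = short_timelapse.config
    img = short_timelapse.stacks["A"][0].astype(float)
    cells = short_timelapse.cells[0.0]
    assert len(cells) >= 50
    stats, _ = per_cell_stats([], cells, img)
    estimates = [
        m.copy_number(
            s.mean_cell_intensity, s.area / config.pixel_size**2,
            config.autofluorescence_equiv, config.unit_intensity,
            cell_id=s.cell_id,
        ).n_molecules
        for s in stats
    ]
    assert np.mean(estimates) == pytest.approx(18.0, rel=0.10)
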