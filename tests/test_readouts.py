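"""Quadrant statistics, thresholds, ΔMFI and the per-sample readouts."""

import numpy as np
import pytest

import flowfect as ff
from flowfect.errors import ConfigurationError, InsufficientDataError

from conftest import lognormal, make_table


def _viable_table(dna, protein, **extra):
    n = len(dna)
    return make_table(fsc_a=np.full(n, 100.0), fsc_h=np.full(n, 95.0),
                      ssc_a=np.full(n, 50.0), dna_label=dna, protein=protein,
                      **extra)


class TestPositivityThreshold:
    def test_linear_interpolation_order_statistics(self):
        t = _viable_table(np.arange(1, 1001, dtype=float), np.ones(1000))
        thr = ff.positivity_threshold(t, "dna_label", pct=99.9)
        assert thr == pytest.approx(999.001)

    def test_median_at_pct_50(self):
        t = _viable_table(np.array([1.0, 2, 3, 4, 5]), np.ones(5))
        assert ff.positivity_threshold(t, "dna_label", pct=50) == 3.0

    def test_constant_control(self):
        t = _viable_table(np.full(300, 42.0), np.ones(300))
        assert ff.positivity_threshold(t, "dna_label") == 42.0

    def test_empty_control_raises(self):
        t = _viable_table(np.array([]), np.array([]))
        with pytest.raises(InsufficientDataError):
            ff.positivity_threshold(t, "dna_label")


class TestQuadrants:
    def test_one_event_per_quadrant(self):
        t = _viable_table(np.array([2.0, 2.0, 0.5, 0.5]),
                          np.array([0.5, 2.0, 2.0, 0.5]))
        q = ff.quadrant_stats(t, 1.0, 1.0)
        assert q.as_tuple() == (25.0, 25.0, 25.0, 25.0)

    def test_ties_fall_non_positive(self):
        t = _viable_table(np.full(10, 1.0), np.full(10, 1.0))
        q = ff.quadrant_stats(t, 1.0, 1.0)
        assert q.q4 == 100.0

    def test_equal_brute_force_counts(self):
        rng = np.random.default_rng(8)
        n = 10000
        x, y = rng.lognormal(5, 1, n), rng.lognormal(5, 1, n)
        t = _viable_table(x, y)
        tx, ty = float(np.median(x)), float(np.median(y))
        q = ff.quadrant_stats(t, tx, ty)
        bf = [100 * np.sum((x > tx) & (y <= ty)) / n,
              100 * np.sum((x > tx) & (y > ty)) / n,
              100 * np.sum((x <= tx) & (y > ty)) / n,
              100 * np.sum((x <= tx) & (y <= ty)) / n]
        assert list(q.as_tuple()) == bf
        assert sum(q.as_tuple()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_sample_gives_nan_sentinel(self):
        t = _viable_table(np.array([]), np.array([]))
        q = ff.quadrant_stats(t, 1.0, 1.0)
        assert all(np.isnan(v) for v in q.as_tuple())


class TestBlankCorrectedMfi:
    def test_self_subtraction_is_zero(self):
        t = _viable_table(np.array([1.0, 5, 9]), np.ones(3))
        assert ff.blank_corrected_mfi(t, t, "dna_label") == 0.0

    def test_direct_arithmetic(self):
        s = _viable_table(np.array([400.0, 500, 600]), np.ones(3))
        c = _viable_table(np.array([100.0, 120, 140]), np.ones(3))
        assert ff.blank_corrected_mfi(s, c, "dna_label") == 380.0

    def test_negative_value_returned_not_clipped(self):
        s = _viable_table(np.array([50.0, 60, 70]), np.ones(3))
        c = _viable_table(np.array([100.0, 120, 140]), np.ones(3))
        assert ff.blank_corrected_mfi(s, c, "dna_label") == -60.0


class TestTransfectionReadouts:
    def test_transfected_fraction_recovered(self):
        cfg = ff.SimulationConfig(n_events=20000, seed=11,
                                  transfected_fraction=0.30)
        sample, _ = ff.simulate_sample(cfg)
        controls = ff.simulate_controls(cfg)
        ro = ff.transfection_readouts(sample, controls)
        assert ro.pct_dna_pos == pytest.approx(30.0, abs=2.0)
        assert ro.pct_dna_pos == pytest.approx(ro.quadrants.q1 + ro.quadrants.q2)
        assert ro.pct_protein_pos == pytest.approx(ro.quadrants.q2 + ro.quadrants.q3)

    def test_null_case_control_as_sample(self, default_controls):
        u = default_controls.untransfected
        nullset = ff.ControlSet(untransfected=u, unlabeled_plasmid=u,
                                zero_timepoint=u)
        ro = ff.transfection_readouts(u, nullset)
        assert ro.pct_dna_pos <= 0.5
        assert ro.pct_protein_pos <= 0.5
        assert ro.dmfi_dna == 0.0
        assert ro.dmfi_protein == 0.0

    def test_protein_only_subpopulation_appears_in_q3(self):
        cfg = ff.SimulationConfig(n_events=20000, seed=13,
                                  transfected_fraction=0.30,
                                  protein_only_fraction=0.15)
        sample, _ = ff.simulate_sample(cfg)
        controls = ff.simulate_controls(cfg)
        ro = ff.transfection_readouts(sample, controls)
        assert ro.quadrants.q3 == pytest.approx(15.0, abs=2.0)
        assert ro.pct_protein_pos == pytest.approx(45.0, abs=3.0)
        assert ro.pct_dna_pos == pytest.approx(30.0, abs=2.0)

    def test_missing_control_named_in_error(self, default_sample,
                                            default_controls):
        table, _ = default_sample
        broken = ff.ControlSet(untransfected=default_controls.untransfected,
                               unlabeled_plasmid=None,
                               zero_timepoint=default_controls.zero_timepoint)
        with pytest.raises(ConfigurationError, match="unlabeled_plasmid"):
            ff.transfection_readouts(table, broken)

    def test_brightness_shift_monotone_in_pct_dna_pos(self):
        controls = ff.simulate_controls(
            ff.SimulationConfig(n_events=10000, seed=17,
                                transfected_fraction=0.30))
        prev = -1.0
        for shift in (2.0, 5.0, 15.0, 30.0, 60.0):
            cfg = ff.SimulationConfig(n_events=10000, seed=17,
                                      transfected_fraction=0.30,
                                      fitc_shift=shift)
            sample, _ = ff.simulate_sample(cfg)
            ro = ff.transfection_readouts(sample, controls)
            assert ro.pct_dna_pos >= prev
            prev = ro.pct_dna_pos

    def test_mesf_emitted_with_calibration(self):
        cfg = ff.SimulationConfig(n_events=20000, seed=19)
        sample, _ = ff.simulate_sample(cfg)
        controls = ff.simulate_controls(cfg)
        beads = ff.simulate_beads(1.0, 2.0, [50, 200, 800, 3200, 12800],
                                  cv_per_peak=0.05, seed=19)
        cal = ff.calibrate_beads(beads)
        ro = ff.transfection_readouts(sample, controls, calibration=cal)
        assert ro.mesf_dna is not None
        # slope 1, intercept 2: MESF = 100 * MFI
        assert ro.mesf_dna == pytest.approx(100 * ro.dmfi_dna, rel=0.15)
        assert ro.mesf_protein is None  # no protein kit supplied


class TestToxicity:
    def test_sample_equal_to_control_zero_excess(self, default_controls):
        u = default_controls.untransfected
        tox = ff.toxicity_readout(u, u,
                                  dye_reference=default_controls.zero_timepoint)
        assert tox.excess_death == 0.0

    def test_dye_positive_fraction_recovered(self):
        cfg = ff.SimulationConfig(n_events=20000, seed=23, dead_fraction=0.20)
        sample, _ = ff.simulate_sample(cfg)
        controls = ff.simulate_controls(cfg)
        tox = ff.toxicity_readout(sample, controls.untransfected,
                                  dye_reference=controls.zero_timepoint)
        assert tox.pct_dead == pytest.approx(20.0, abs=2.0)
        assert tox.excess_death > 0

    def test_death_confined_to_dna_positive_cells(self):
        rng = np.random.default_rng(29)
        n = 10000
        dna = lognormal(rng, 100, 0.18, n)
        dye = lognormal(rng, 150, 0.15, n)
        fitc_pos = rng.random(n) < 0.40
        dna[fitc_pos] = lognormal(rng, 3000, 0.30, int(fitc_pos.sum()))
        dead = fitc_pos & (rng.random(n) < 0.30)  # death only among FITC+
        dye[dead] = lognormal(rng, 15000, 0.20, int(dead.sum()))
        sample = _viable_table(dna, lognormal(rng, 120, 0.18, n), viability=dye)
        control = _viable_table(lognormal(rng, 100, 0.18, n),
                                lognormal(rng, 120, 0.18, n),
                                viability=lognormal(rng, 150, 0.15, n))
        tox = ff.toxicity_readout(sample, control, dye_reference=control)
        assert tox.pct_dead_among_dna_pos is not None
        assert tox.pct_dead_among_dna_pos > tox.pct_dead
        assert tox.pct_dead_among_dna_pos == pytest.approx(30.0, abs=3.0)
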