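"""Gating hierarchy: singlet band, intact box, viability gates, nesting."""

import numpy as np
import pytest

import flowfect as ff
from flowfect.errors import InsufficientDataError

from conftest import lognormal, make_table


def brute_force_gate(gate, table):
    """Independent per-event re-evaluation of a gate predicate."""
    out = []
    for i in range(table.n_events):
        row = {c.role: float(table.values[i, j])
               for j, c in enumerate(table.channels)}
        if gate.kind == "ratio_band":
            a, h = row["fsc_a"], row["fsc_h"]
            ok = a > 0 and gate.params["ratio_lo"] <= h / a <= gate.params["ratio_hi"]
        elif gate.kind == "percentile_box":
            ok = all(gate.params[f"{r}_lo"] <= row[r] <= gate.params[f"{r}_hi"]
                     for r in gate.channels)
        elif gate.kind == "threshold_above":
            ok = row[gate.channels[0]] > gate.params["threshold"]
        else:
            ok = row[gate.channels[0]] <= gate.params["threshold"]
        out.append(ok)
    return np.array(out, dtype=bool)


class TestSingletGate:
    def test_doublet_like_ratio_excluded(self):
        n = 100
        fsc_a = np.full(n, 100.0)
        fsc_h = np.full(n, 90.0)  # ratio 0.9
        fsc_h[0] = 45.0           # ratio 0.45 < 0.9 * 0.85
        t = make_table(fsc_a=fsc_a, fsc_h=fsc_h, ssc_a=np.full(n, 50.0))
        gate = ff.fit_singlet_gate(t, band_width=0.15)
        mask = gate.mask(t)
        assert not mask[0]
        assert mask[1:].all()

    def test_identical_events_all_pass(self):
        t = make_table(fsc_a=np.full(60, 100.0), fsc_h=np.full(60, 95.0),
                       ssc_a=np.full(60, 50.0))
        assert ff.fit_singlet_gate(t).mask(t).all()

    def test_too_few_events(self):
        t = make_table(fsc_a=np.ones(10), fsc_h=np.ones(10), ssc_a=np.ones(10))
        with pytest.raises(InsufficientDataError):
            ff.fit_singlet_gate(t)

    def test_simulated_doublets_recall_and_leak(self):
        # Pure viable population with 10% doublets; label-aware confusion.
        cfg = ff.SimulationConfig(n_events=20000, seed=5, dead_fraction=0.0,
                                  debris_fraction=0.0, doublet_fraction=0.10)
        table, truth = ff.simulate_sample(cfg)
        gate = ff.fit_singlet_gate(table, band_width=0.15)
        mask = gate.mask(table)
        singlet = ~truth.is_doublet.values
        recall = mask[singlet].mean()
        leak = mask[~singlet].mean()
        assert recall >= 0.99
        assert leak <= 0.05


class TestIntactGate:
    def test_debris_excluded_with_reference_percentiles(self):
        rng = np.random.default_rng(3)
        n_main, n_debris = 9000, 1000
        main_fsc = lognormal(rng, 1e5, 0.11, n_main)
        debris_fsc = lognormal(rng, 0.05 * 1e5, 0.11, n_debris)
        t = make_table(fsc_a=np.r_[main_fsc, debris_fsc],
                       fsc_h=np.r_[main_fsc, debris_fsc] * 0.95,
                       ssc_a=lognormal(rng, 5e4, 0.13, n_main + n_debris))
        clean = make_table(fsc_a=lognormal(rng, 1e5, 0.11, 5000),
                           fsc_h=np.ones(5000),
                           ssc_a=lognormal(rng, 5e4, 0.13, 5000))
        gate = ff.fit_intact_gate(t, reference=clean)
        mask = gate.mask(t)
        assert mask[n_main:].mean() <= 0.05  # >= 95% of debris excluded

    def test_uniform_population_kept_fraction(self):
        rng = np.random.default_rng(4)
        n = 20000
        t = make_table(fsc_a=lognormal(rng, 1e5, 0.11, n),
                       fsc_h=np.ones(n),
                       ssc_a=lognormal(rng, 5e4, 0.13, n))
        kept = ff.fit_intact_gate(t).mask(t).mean()
        expected = (0.995 - 0.02) ** 2
        assert kept == pytest.approx(expected, abs=0.01)

    def test_identical_events_all_kept(self):
        t = make_table(fsc_a=np.full(50, 7.0), fsc_h=np.full(50, 7.0),
                       ssc_a=np.full(50, 3.0))
        assert ff.fit_intact_gate(t).mask(t).all()


class TestViabilityDye:
    def _table(self, dye):
        n = len(dye)
        return make_table(fsc_a=np.full(n, 100.0), fsc_h=np.full(n, 95.0),
                          ssc_a=np.full(n, 50.0), viability=dye)

    def test_control_vs_itself_dead_fraction(self):
        rng = np.random.default_rng(0)
        t = self._table(lognormal(rng, 150, 0.15, 20000))
        gate = ff.viability_gate_dye(t, t, pct=99.5)
        dead = gate.mask(t).mean()
        assert dead == pytest.approx(1 - 0.995, abs=0.002)

    def test_spiked_dead_population_recovered(self):
        rng = np.random.default_rng(1)
        control = self._table(lognormal(rng, 150, 0.15, 10000))
        dye = lognormal(rng, 150, 0.15, 10000)
        dead_idx = rng.random(10000) < 0.20
        dye[dead_idx] = lognormal(rng, 150 * 100, 0.15, int(dead_idx.sum()))
        sample = self._table(dye)
        gate = ff.viability_gate_dye(sample, control, pct=99.5)
        mask = gate.mask(sample)
        assert gate.selects == "dead"
        assert mask.mean() == pytest.approx(dead_idx.mean(), abs=0.02)

    def test_pct_100_gives_zero_dead(self):
        rng = np.random.default_rng(2)
        t = self._table(lognormal(rng, 150, 0.15, 1000))
        gate = ff.viability_gate_dye(t, t, pct=100.0)
        assert gate.mask(t).sum() == 0


class TestViabilityScatter:
    def test_sample_identical_to_reference_bounded(self):
        rng = np.random.default_rng(5)
        n = 20000
        t = make_table(fsc_a=lognormal(rng, 1e5, 0.11, n), fsc_h=np.ones(n),
                       ssc_a=lognormal(rng, 5e4, 0.13, n))
        gate = ff.viability_gate_scatter(t, t)
        # at most the joint tail mass: P(fsc < p10) * anything <= 0.10
        assert gate.mask(t).mean() <= 0.10

    def test_simulated_dead_population_recovered(self):
        # fsc shrunk x0.5, ssc inflated x1.6, 25% abundance (label-aware).
        rng = np.random.default_rng(6)
        n_live, n_dead = 15000, 5000
        fsc = np.r_[lognormal(rng, 1e5, 0.11, n_live),
                    lognormal(rng, 0.5e5, 0.11, n_dead)]
        ssc = np.r_[lognormal(rng, 5e4, 0.13, n_live),
                    lognormal(rng, 1.6 * 5e4, 0.13, n_dead)]
        sample = make_table(fsc_a=fsc, fsc_h=fsc * 0.95, ssc_a=ssc)
        ref = make_table(fsc_a=lognormal(rng, 1e5, 0.11, 10000),
                         fsc_h=np.ones(10000),
                         ssc_a=lognormal(rng, 5e4, 0.13, 10000))
        gate = ff.viability_gate_scatter(sample, ref)
        dead_pct = 100 * gate.mask(sample).mean()
        assert dead_pct == pytest.approx(25.0, abs=5.0)

    def test_no_dead_population_bounded_by_joint_tail(self):
        rng = np.random.default_rng(7)
        n = 10000
        ref = make_table(fsc_a=lognormal(rng, 1e5, 0.11, n), fsc_h=np.ones(n),
                         ssc_a=lognormal(rng, 5e4, 0.13, n))
        gate = ff.viability_gate_scatter(ref, ref)
        # independent axes: joint tail mass ~ 0.10 * 0.25
        assert gate.mask(ref).mean() <= 0.10 * 0.25 + 0.01


class TestHierarchy:
    def test_all_pass_gates(self):
        t = make_table(fsc_a=np.full(100, 10.0), fsc_h=np.full(100, 9.5),
                       ssc_a=np.full(100, 5.0))
        res = ff.apply_hierarchy(t, ff.fit_singlet_gate(t), ff.fit_intact_gate(t))
        assert all(res.masks[k].all() for k in ("singlet", "intact", "viable"))
        assert res.counts == {"singlet": 100, "intact": 100, "viable": 100}

    def test_masks_equal_brute_force_oracle(self, default_cfg):
        import dataclasses
        cfg = dataclasses.replace(default_cfg, n_events=1000)
        table, _ = ff.simulate_sample(cfg)
        controls = ff.simulate_controls(cfg)
        singlet = ff.fit_singlet_gate(table)
        intact = ff.fit_intact_gate(table)
        dye = ff.viability_gate_dye(table, controls.zero_timepoint)
        res = ff.apply_hierarchy(table, singlet, intact, dye)
        bf_singlet = brute_force_gate(singlet, table)
        bf_intact = bf_singlet & brute_force_gate(intact, table)
        bf_viable = bf_intact & ~brute_force_gate(dye, table)
        np.testing.assert_array_equal(res.masks["singlet"], bf_singlet)
        np.testing.assert_array_equal(res.masks["intact"], bf_intact)
        np.testing.assert_array_equal(res.masks["viable"], bf_viable)

    def test_empty_table(self):
        t = make_table(fsc_a=[], fsc_h=[], ssc_a=[])
        gate = ff.Gate(kind="threshold_above", channels=("fsc_a",),
                       params={"threshold": 0.0})
        box = ff.Gate(kind="percentile_box", channels=("fsc_a",),
                      params={"fsc_a_lo": -np.inf, "fsc_a_hi": np.inf})
        res = ff.apply_hierarchy(t, gate, box)
        assert res.counts == {"singlet": 0, "intact": 0, "viable": 0}
        assert np.isnan(res.fractions["singlet"])

    def test_nesting_invariant_on_default_simulation(self, default_sample,
                                                     default_controls):
        table, _ = default_sample
        res = ff.gate_sample(table, ff.PipelineParams(),
                             default_controls.untransfected,
                             dye_reference=default_controls.zero_timepoint)
        v, i, s = (res.masks[k] for k in ("viable", "intact", "singlet"))
        assert not (v & ~i).any()
        assert not (i & ~s).any()

    def test_gates_deterministic(self, default_sample):
        table, _ = default_sample
        g1 = ff.fit_singlet_gate(table)
        g2 = ff.fit_singlet_gate(table)
        assert g1.params == g2.params

    def test_dye_and_scatter_viability_agree(self, default_sample,
                                             default_controls):
        """The two death-quantification routes agree within 5 points."""
        table, _ = default_sample
        tox_dye = ff.toxicity_readout(table, default_controls.untransfected,
                                      dye_reference=default_controls.zero_timepoint)
        keep = [i for i, c in enumerate(table.channels) if c.role != "viability"]
        no_dye = ff.EventTable(values=table.values[:, keep],
                               channels=[table.channels[i] for i in keep],
                               sample_id=table.sample_id)
        ctrl = default_controls.untransfected
        keep_c = [i for i, c in enumerate(ctrl.channels) if c.role != "viability"]
        ctrl_no_dye = ff.EventTable(values=ctrl.values[:, keep_c],
                                    channels=[ctrl.channels[i] for i in keep_c],
                                    sample_id=ctrl.sample_id)
        tox_scatter = ff.toxicity_readout(no_dye, ctrl_no_dye)
        assert tox_dye.method == "dye" and tox_scatter.method == "scatter"
        assert abs(tox_dye.pct_dead - tox_scatter.pct_dead) <= 5.0
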