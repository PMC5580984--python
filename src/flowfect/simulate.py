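"""Seeded synthetic cytometry: cell samples, controls, time courses, beads.

The generator emulates the event structure of a chemical-transfection
experiment in an adherent cell line: a viable cloud (part transfected, with
correlated labeled-DNA and protein fluorescence), a dead population with
shrunken forward scatter, inflated side scatter and a bright viability dye,
a low-scatter debris cloud, and area-additive doublets whose pulse height
tracks the larger member — the geometry that makes FSC-H/FSC-A doublet
discrimination work on real instruments.

Fluorescence is lognormal per population.  The DNA/protein association in
transfected cells is produced by a Gaussian copula whose correlation is set
so the emitted Spearman rank correlation matches the configured target
(rho_gauss = 2 sin(pi * rho_s / 6)).  Time courses modulate the brightness
shifts with a gamma-shaped uptake pulse and a Hill-type protein rise.

Every draw is governed by one root seed; per-event ground-truth labels
(population, doublet flag) are returned alongside each table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .event_io import Channel, EventTable
from .mesf import BeadSet
from .readouts import ControlSet

_FRACTION_TOL = 1e-9


def load_default_parameters() -> dict:
    """The versioned default simulation parameters shipped with the package."""
    with resources.files("flowfect.data").joinpath(
            "default_simulation.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class FluorSpec:
    """Lognormal location/spread: median (linear units), sigma (log10)."""

    median: float
    sigma: float


@dataclass
class PopulationModel:
    """One mixture component with its scatter and fluorescence model."""

    name: str
    fraction: float
    fsc_a: FluorSpec
    ssc_a: FluorSpec
    hw_ratio: float = 0.95
    hw_ratio_cv: float = 0.03
    fluor: dict[str, FluorSpec] = field(default_factory=dict)
    dna_protein_rank_corr: float = 0.0
    dye_positive: bool = False


@dataclass
class Kinetics:
    """Uptake pulse and protein-expression rise over hours post-transfection."""

    uptake_peak_h: float = 12.0
    uptake_shape: float = 2.0
    protein_t50_h: float = 16.0
    protein_hill: float = 2.0
    protein_saturation_h: float = 48.0

    def uptake_pulse(self, t: float) -> float:
        """Gamma-shaped pulse, normalized to 1 at the configured peak."""
        if t <= 0:
            return 0.0
        k, tp = self.uptake_shape, self.uptake_peak_h
        return float((t / tp) ** k * np.exp(k * (1 - t / tp)))

    def protein_rise(self, t: float) -> float:
        """Hill rise in [0, 1), monotone non-decreasing."""
        if t <= 0:
            return 0.0
        h, t50 = self.protein_hill, self.protein_t50_h
        return float(t ** h / (t50 ** h + t ** h))


@dataclass
class SimulationConfig:
    """Scientific knobs for one simulated acquisition.

    Fractions are over all (singlet) events; ``transfected_fraction`` and
    ``protein_only_fraction`` are fractions of the *viable* compartment, so
    they remain the ground truth for readouts computed on viable cells.
    """

    n_events: int = 20000
    seed: int = 0
    transfected_fraction: float | None = None
    protein_only_fraction: float | None = None
    dead_fraction: float | None = None
    debris_fraction: float | None = None
    doublet_fraction: float | None = None
    fitc_shift: float | None = None
    protein_shift: float | None = None
    dna_protein_rank_corr: float | None = None
    include_viability: bool = True
    timepoint_h: float | None = 24.0
    kinetics: Kinetics = field(default_factory=Kinetics)
    parameters: dict = field(default_factory=load_default_parameters)

    def __post_init__(self) -> None:
        d = self.parameters["defaults"]
        for name, key in (("transfected_fraction", "transfected_fraction"),
                          ("protein_only_fraction", "protein_only_fraction"),
                          ("dead_fraction", "dead_fraction"),
                          ("debris_fraction", "debris_fraction"),
                          ("doublet_fraction", "doublet_fraction"),
                          ("fitc_shift", "fitc_shift"),
                          ("protein_shift", "protein_shift"),
                          ("dna_protein_rank_corr", "dna_protein_rank_corr")):
            if getattr(self, name) is None:
                setattr(self, name, float(d[key]))
        if self.n_events < 1:
            raise ConfigurationError("n_events must be >= 1")
        if not 0 <= self.doublet_fraction < 0.5:
            raise ConfigurationError("doublet_fraction must be in [0, 0.5)")
        if self.dead_fraction + self.debris_fraction >= 1:
            raise ConfigurationError("dead + debris fractions must be < 1")
        if not 0 <= self.transfected_fraction + self.protein_only_fraction <= 1:
            raise ConfigurationError(
                "transfected + protein-only fractions must lie in [0, 1]")


def build_populations(cfg: SimulationConfig) -> list[PopulationModel]:
    """Expand a config into explicit mixture components.

    Components: transfected (DNA+ protein+), protein_only (DNA- protein+),
    untransfected-viable, dead, debris.  Fractions sum to 1.
    """
    p = cfg.parameters["baseline"]
    auto_dna = FluorSpec(*p["autofluor_dna_label"])
    auto_prot = FluorSpec(*p["autofluor_protein"])
    dye_neg = FluorSpec(*p["dye_negative"])
    dye_dead = FluorSpec(*p["dye_dead"])
    viable_fsc = FluorSpec(*p["viable_fsc_a"])
    viable_ssc = FluorSpec(*p["viable_ssc_a"])
    # A shift of 1 means no label / no expression: the channel shows pure
    # autofluorescence, with the (narrower) autofluorescence spread.
    pos_dna = FluorSpec(auto_dna.median * cfg.fitc_shift,
                        p["positive_sigma_dna_label"]
                        if cfg.fitc_shift > 1 else auto_dna.sigma)
    pos_prot = FluorSpec(auto_prot.median * cfg.protein_shift,
                         p["positive_sigma_protein"]
                         if cfg.protein_shift > 1 else auto_prot.sigma)

    viable_total = 1.0 - cfg.dead_fraction - cfg.debris_fraction
    f_trans = viable_total * cfg.transfected_fraction
    f_ponly = viable_total * cfg.protein_only_fraction
    f_untrans = viable_total - f_trans - f_ponly

    common = dict(fsc_a=viable_fsc, ssc_a=viable_ssc,
                  hw_ratio=p["hw_ratio"], hw_ratio_cv=p["hw_ratio_cv"])
    pops = [
        PopulationModel(name="transfected", fraction=f_trans,
                        fluor={"dna_label": pos_dna, "protein": pos_prot,
                               "viability": dye_neg},
                        dna_protein_rank_corr=cfg.dna_protein_rank_corr,
                        **common),
        PopulationModel(name="protein_only", fraction=f_ponly,
                        fluor={"dna_label": auto_dna, "protein": pos_prot,
                               "viability": dye_neg}, **common),
        PopulationModel(name="untransfected", fraction=f_untrans,
                        fluor={"dna_label": auto_dna, "protein": auto_prot,
                               "viability": dye_neg}, **common),
        PopulationModel(
            name="dead", fraction=cfg.dead_fraction,
            fsc_a=FluorSpec(viable_fsc.median * p["dead_fsc_scale"],
                            viable_fsc.sigma),
            ssc_a=FluorSpec(viable_ssc.median * p["dead_ssc_scale"],
                            viable_ssc.sigma),
            hw_ratio=p["hw_ratio"], hw_ratio_cv=p["hw_ratio_cv"],
            fluor={"dna_label": auto_dna, "protein": auto_prot,
                   "viability": dye_dead},
            dye_positive=True),
        PopulationModel(
            name="debris", fraction=cfg.debris_fraction,
            fsc_a=FluorSpec(*p["debris_fsc_a"]),
            ssc_a=FluorSpec(*p["debris_ssc_a"]),
            hw_ratio=p["hw_ratio"], hw_ratio_cv=p["hw_ratio_cv"],
            fluor={"dna_label": auto_dna, "protein": auto_prot,
                   "viability": dye_neg}),
    ]
    pops = [pop for pop in pops if pop.fraction > 0]
    total = sum(pop.fraction for pop in pops)
    if abs(total - 1.0) > _FRACTION_TOL:
        raise ConfigurationError(f"population fractions sum to {total}, not 1")
    return pops


def _draw_singlets(rng: np.random.Generator, pops: Sequence[PopulationModel],
                   n: int, roles: Sequence[str]) -> tuple[dict, np.ndarray]:
    fractions = np.array([p.fraction for p in pops])
    pop_idx = rng.choice(len(pops), size=n, p=fractions)
    cols = {role: np.empty(n) for role in roles}
    cols["fsc_a"] = np.empty(n)
    cols["fsc_h"] = np.empty(n)
    cols["ssc_a"] = np.empty(n)
    for j, pop in enumerate(pops):
        sel = pop_idx == j
        m = int(sel.sum())
        if m == 0:
            continue
        fsc = 10.0 ** rng.normal(np.log10(pop.fsc_a.median), pop.fsc_a.sigma, m)
        ssc = 10.0 ** rng.normal(np.log10(pop.ssc_a.median), pop.ssc_a.sigma, m)
        ratio = pop.hw_ratio * (1 + pop.hw_ratio_cv * rng.standard_normal(m))
        cols["fsc_a"][sel] = fsc
        cols["ssc_a"][sel] = ssc
        cols["fsc_h"][sel] = ratio * fsc
        # Gaussian copula between the two fluorescence readouts.
        rho_s = np.clip(pop.dna_protein_rank_corr, -1.0, 1.0)
        rho_g = 2.0 * np.sin(np.pi * rho_s / 6.0)
        z1 = rng.standard_normal(m)
        z_shared = rng.standard_normal(m)
        z2 = rho_g * z1 + np.sqrt(max(0.0, 1 - rho_g ** 2)) * z_shared
        zs = {"dna_label": z1, "protein": z2}
        for role in roles:
            if role in ("fsc_a", "fsc_h", "ssc_a"):
                continue
            spec = pop.fluor[role]
            z = zs.get(role)
            if z is None:
                z = rng.standard_normal(m)
            cols[role][sel] = 10.0 ** (np.log10(spec.median) + spec.sigma * z)
    return cols, pop_idx


def simulate_sample(cfg: SimulationConfig
                    ) -> tuple[EventTable, pd.DataFrame]:
    """Draw one acquisition: event table plus per-event ground truth.

    Doublets are formed from two independently drawn singlets: all area
    channels (scatter and fluorescence) add, pulse height is the larger
    member's.  The truth frame carries the first member's population label
    and an ``is_doublet`` flag.
    """
    pops = build_populations(cfg)
    rng = np.random.default_rng(cfg.seed)
    roles = ["dna_label", "protein"] + (
        ["viability"] if cfg.include_viability else [])
    n_doublets = int(round(cfg.doublet_fraction * cfg.n_events))
    n_singlets = cfg.n_events - n_doublets
    cols, pop_idx = _draw_singlets(rng, pops, n_singlets + 2 * n_doublets, roles)

    area_roles = ["fsc_a", "ssc_a"] + roles
    out = {role: cols[role][:n_singlets].copy() for role in area_roles}
    out["fsc_h"] = cols["fsc_h"][:n_singlets].copy()
    labels = [pops[j].name for j in pop_idx[:n_singlets]]
    is_doublet = [False] * n_singlets
    if n_doublets:
        a = slice(n_singlets, n_singlets + n_doublets)
        b = slice(n_singlets + n_doublets, None)
        for role in area_roles:
            out[role] = np.concatenate([out[role], cols[role][a] + cols[role][b]])
        out["fsc_h"] = np.concatenate(
            [out["fsc_h"], np.maximum(cols["fsc_h"][a], cols["fsc_h"][b])])
        labels += [pops[j].name for j in pop_idx[a]]
        is_doublet += [True] * n_doublets

    perm = rng.permutation(cfg.n_events)
    names = cfg.parameters["channels"]
    channel_roles = ["fsc_a", "fsc_h", "ssc_a"] + roles
    values = np.column_stack([out[r][perm] for r in channel_roles])
    channels = [Channel(name=names[r], role=r) for r in channel_roles]
    table = EventTable(values=values, channels=channels,
                       sample_id=f"sim-seed{cfg.seed}",
                       timepoint_h=cfg.timepoint_h)
    truth = pd.DataFrame({
        "population": np.array(labels, dtype=object)[perm],
        "is_doublet": np.array(is_doublet)[perm],
    })
    return table, truth


def simulate_controls(cfg: SimulationConfig) -> ControlSet:
    """The three negative controls matched to a sample config.

    untransfected: no plasmid, baseline culture death; unlabeled_plasmid:
    the same transfection without the FITC label (protein expressed, FITC at
    autofluorescence, same toxicity); zero_timepoint: labeled plasmid
    harvested at t=0 — uptake signal without protein and, being
    pre-toxicity, free of dead cells.
    """
    d = cfg.parameters["defaults"]
    untransfected, _ = simulate_sample(replace(
        cfg, seed=_subseed(cfg.seed, 101), transfected_fraction=0.0,
        protein_only_fraction=0.0,
        dead_fraction=float(d["untransfected_dead_fraction"])))
    unlabeled, _ = simulate_sample(replace(
        cfg, seed=_subseed(cfg.seed, 102), fitc_shift=1.0))
    zero_tp, _ = simulate_sample(replace(
        cfg, seed=_subseed(cfg.seed, 103), protein_shift=1.0,
        dead_fraction=0.0, timepoint_h=0.0))
    untransfected.sample_id = "control-untransfected"
    unlabeled.sample_id = "control-unlabeled-plasmid"
    zero_tp.sample_id = "control-zero-timepoint"
    return ControlSet(untransfected=untransfected, unlabeled_plasmid=unlabeled,
                      zero_timepoint=zero_tp)


def _subseed(seed: int, offset: int) -> int:
    return (seed * 1000 + offset) % (2 ** 31 - 1)


def simulate_timecourse(cfg: SimulationConfig, timepoints: Sequence[float]
                        ) -> list[tuple[float, EventTable, pd.DataFrame]]:
    """Samples along a kinetic trajectory.

    The FITC brightness shift follows the gamma-shaped uptake pulse (peak at
    the configured time) and the protein shift the Hill rise; each timepoint
    uses a seed-derived substream.
    """
    times = list(timepoints)
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ConfigurationError("timepoints must be strictly increasing")
    out = []
    for i, t in enumerate(times):
        fitc = 1.0 + (cfg.fitc_shift - 1.0) * cfg.kinetics.uptake_pulse(t)
        prot = 1.0 + (cfg.protein_shift - 1.0) * cfg.kinetics.protein_rise(t)
        sub = replace(cfg, seed=_subseed(cfg.seed, 200 + i), fitc_shift=fitc,
                      protein_shift=prot, timepoint_h=float(t))
        table, truth = simulate_sample(sub)
        table.sample_id = f"sim-seed{cfg.seed}-t{t:g}h"
        out.append((float(t), table, truth))
    return out


def simulate_beads(true_slope: float, true_intercept: float,
                   peak_mfis: Sequence[float], cv_per_peak: float = 0.08,
                   n_per_peak: int = 1000, seed: int = 0,
                   has_blank: bool = False, blank_mfi: float = 5.0,
                   channel_name: str = "FITC-A") -> BeadSet:
    """A bead acquisition drawn from a known power-law standard curve.

    ``known_mesf`` is computed from the true log-log line, so recovering the
    curve from the emitted events is a closed-loop check on the whole
    calibration path.  Events are lognormal around each peak median with the
    stated coefficient of variation.
    """
    peaks = np.asarray(peak_mfis, dtype=float)
    if np.any(np.diff(peaks) <= 0) or np.any(peaks <= 0):
        raise ConfigurationError("peak MFIs must be positive and increasing")
    known = 10.0 ** (true_intercept + true_slope * np.log10(peaks))
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + cv_per_peak ** 2))  # natural-log sigma for CV
    all_peaks = ([blank_mfi] if has_blank else []) + list(peaks)
    draws = [m * np.exp(rng.normal(0.0, sigma, n_per_peak)) for m in all_peaks]
    values = np.concatenate(draws) if draws else np.empty(0)
    values = values[rng.permutation(values.size)]
    table = EventTable(values=values.reshape(-1, 1),
                       channels=[Channel(name=channel_name, role="dna_label")],
                       sample_id=f"beads-seed{seed}")
    return BeadSet(events=table, known_mesf=known, has_blank=has_blank)
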