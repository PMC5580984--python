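"""Transfection-efficiency readouts from gated event data.

Two independent efficiency measures are computed per sample on viable
singlets: the fraction of cells that took up the fluorescently labeled
plasmid (DNA channel, quadrants Q1+Q2) and the fraction expressing the
encoded protein (protein channel, Q2+Q3).  Positivity thresholds come from
matched negative controls — cells transfected with the unlabeled plasmid for
the DNA channel, and a zero-timepoint harvest (before any protein is made)
for the protein channel.  Median fluorescence is blank-corrected against the
same controls (ΔMFI) and optionally standardized to MESF via a bead
calibration.  Toxicity is the dye-positive (or scatter-dead) fraction among
intact singlets, compared against the untransfected control.

All statistics are computed on untransformed acquisition-scale values;
quadrant ties (value equal to a threshold) fall on the non-positive side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .event_io import EventTable
from .gating import (Gate, GatingResult, apply_hierarchy, fit_intact_gate,
                     fit_singlet_gate, viability_gate_dye, viability_gate_scatter)
from .mesf import BeadCalibration, mfi_to_mesf

logger = logging.getLogger(__name__)


@dataclass
class ControlSet:
    """The three negative controls that anchor thresholds and blanks.

    ``untransfected``: no plasmid, defines autofluorescence and baseline
    death.  ``unlabeled_plasmid``: transfected with the unlabeled plasmid;
    FITC background of transfected cells.  ``zero_timepoint``: harvested
    before protein expression (may alias the unlabeled-plasmid tube at t=0);
    protein background and, being pre-toxicity, a dye-negative reference.
    """

    untransfected: EventTable
    unlabeled_plasmid: EventTable
    zero_timepoint: EventTable

    def require(self, name: str) -> EventTable:
        table = getattr(self, name, None)
        if table is None:
            raise ConfigurationError(f"missing control: {name}")
        return table


@dataclass
class PipelineParams:
    """Tunable gating/threshold parameters, all serialized into reports."""

    band_width: float = 0.15
    intact_lower_pct: float = 2.0
    intact_upper_pct: float = 99.5
    viability_pct: float = 99.5
    scatter_fsc_pct: float = 10.0
    scatter_ssc_pct: float = 75.0
    positivity_pct: float = 99.9
    mfi_stat: str = "median"  # "mean" available but never default

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class QuadrantStats:
    """Quadrant percentages of viable cells around (x, y) thresholds."""

    x_threshold: float
    y_threshold: float
    q1: float  # x+ y-
    q2: float  # x+ y+
    q3: float  # x- y+
    q4: float  # x- y-

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.q1, self.q2, self.q3, self.q4)


@dataclass
class TransfectionReadout:
    """The four efficiency measures plus bookkeeping for one sample."""

    sample_id: str
    timepoint_h: float | None
    pct_dna_pos: float          # Q1+Q2, % of viable cells
    pct_protein_pos: float      # Q2+Q3, % of viable cells
    dmfi_dna: float             # blank-corrected median FITC
    dmfi_protein: float         # blank-corrected median protein signal
    mesf_dna: float | None = None
    mesf_protein: float | None = None
    mesf_dna_extrapolated: bool = False
    mesf_protein_extrapolated: bool = False
    n_viable: int = 0
    quadrants: QuadrantStats | None = None
    gate_fractions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "quadrants"}
        if self.quadrants is not None:
            d.update({"q1": self.quadrants.q1, "q2": self.quadrants.q2,
                      "q3": self.quadrants.q3, "q4": self.quadrants.q4,
                      "x_threshold": self.quadrants.x_threshold,
                      "y_threshold": self.quadrants.y_threshold})
        return d


@dataclass
class ToxicityReadout:
    """Transfection toxicity relative to the untransfected control."""

    sample_id: str
    pct_dead: float
    pct_dead_control: float
    excess_death: float
    pct_dead_among_dna_pos: float | None = None
    method: str = "dye"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _mfi(x: np.ndarray, stat: str = "median") -> float:
    return float(np.mean(x)) if stat == "mean" else float(np.median(x))


def positivity_threshold(control: EventTable, role: str,
                         pct: float = 99.9) -> float:
    """Percentile threshold on a viable-gated negative control.

    Events strictly above the threshold are positive; ties sit on the
    negative side, so a control run against itself is at most
    ``100 - pct`` percent positive.
    """
    if control.n_events == 0:
        raise InsufficientDataError("empty control for positivity threshold")
    if control.n_events < 200:
        logger.warning("positivity threshold from only %d control events",
                       control.n_events)
    return float(np.percentile(control.column(role), pct))


def quadrant_stats(sample: EventTable, x_threshold: float,
                   y_threshold: float) -> QuadrantStats:
    """Quadrant percentages on (dna_label, protein) for viable-gated events."""
    if not (math.isfinite(x_threshold) and math.isfinite(y_threshold)):
        raise ConfigurationError("quadrant thresholds must be finite")
    n = sample.n_events
    if n == 0:
        nan = float("nan")
        return QuadrantStats(x_threshold, y_threshold, nan, nan, nan, nan)
    x = sample.column("dna_label")
    y = sample.column("protein")
    xp, yp = x > x_threshold, y > y_threshold
    pct = lambda m: 100.0 * int(m.sum()) / n
    return QuadrantStats(
        x_threshold=x_threshold, y_threshold=y_threshold,
        q1=pct(xp & ~yp), q2=pct(xp & yp), q3=pct(~xp & yp), q4=pct(~xp & ~yp))


def blank_corrected_mfi(sample: EventTable, control: EventTable, role: str,
                        stat: str = "median") -> float:
    """Sample MFI minus matched-control MFI on one channel (ΔMFI).

    Negative values are reported as-is (with a warning): clipping would bias
    reproducibility statistics computed across assays.
    """
    if sample.n_events == 0 or control.n_events == 0:
        raise InsufficientDataError("ΔMFI requires non-empty sample and control")
    delta = _mfi(sample.column(role), stat) - _mfi(control.column(role), stat)
    if delta < 0:
        logger.warning("negative ΔMFI (%.3g) on %s for %s",
                       delta, role, sample.sample_id)
    return delta


def gate_sample(table: EventTable, params: PipelineParams,
                untransfected: EventTable | None = None,
                dye_reference: EventTable | None = None) -> GatingResult:
    """Fit and apply the full hierarchy to one table.

    Gates are fitted on the table itself (transfection perturbs scatter, so
    control-fitted scatter gates would not transfer).  The viability stage
    uses the dye when the channel is mapped — thresholded on
    ``dye_reference`` (a dye-negative table; falls back to ``untransfected``,
    then the sample) — and otherwise the scatter dead-region against the
    untransfected reference, the only option in electroporation experiments.
    """
    singlet = fit_singlet_gate(table, band_width=params.band_width)
    intact = fit_intact_gate(table, lower_pct=params.intact_lower_pct,
                             upper_pct=params.intact_upper_pct)
    viability: Gate | None
    if table.has_role("viability"):
        ref = dye_reference if dye_reference is not None else (
            untransfected if untransfected is not None else table)
        viability = viability_gate_dye(table, ref, pct=params.viability_pct)
    elif untransfected is not None:
        viability = viability_gate_scatter(
            table, untransfected,
            fsc_pct=params.scatter_fsc_pct, ssc_pct=params.scatter_ssc_pct)
    else:
        viability = None
    return apply_hierarchy(table, singlet, intact, viability)


def transfection_readouts(sample: EventTable, controls: ControlSet,
                          params: PipelineParams | None = None,
                          calibration: BeadCalibration | None = None,
                          protein_calibration: BeadCalibration | None = None,
                          ) -> TransfectionReadout:
    """Full per-sample readout: quadrants, ΔMFIs and optional MESF.

    The sample and each control are gated with gates fitted on themselves;
    the DNA threshold/blank comes from the unlabeled-plasmid control and the
    protein threshold/blank from the zero-timepoint control.  MESF values
    are emitted only when a calibration is supplied and the corresponding
    ΔMFI is positive (no MESF kits exist for fluorescent proteins such as
    mCherry, so the protein calibration is optional by design).
    """
    params = params or PipelineParams()
    for role in ("dna_label", "protein"):
        if not sample.has_role(role):
            raise ConfigurationError(f"sample lacks required role {role!r}")
    untransfected = controls.require("untransfected")
    unlabeled = controls.require("unlabeled_plasmid")
    zero_tp = controls.require("zero_timepoint")
    dye_ref = zero_tp if sample.has_role("viability") else None

    res = gate_sample(sample, params, untransfected, dye_reference=dye_ref)
    viable = res.viable_events(sample)
    viable_unlabeled = gate_sample(unlabeled, params, untransfected,
                                   dye_reference=dye_ref).viable_events(unlabeled)
    viable_zero = gate_sample(zero_tp, params, untransfected,
                              dye_reference=dye_ref).viable_events(zero_tp)

    x_thr = positivity_threshold(viable_unlabeled, "dna_label", params.positivity_pct)
    y_thr = positivity_threshold(viable_zero, "protein", params.positivity_pct)
    quads = quadrant_stats(viable, x_thr, y_thr)
    dmfi_dna = blank_corrected_mfi(viable, viable_unlabeled, "dna_label",
                                   params.mfi_stat)
    dmfi_protein = blank_corrected_mfi(viable, viable_zero, "protein",
                                       params.mfi_stat)

    out = TransfectionReadout(
        sample_id=sample.sample_id, timepoint_h=sample.timepoint_h,
        pct_dna_pos=quads.q1 + quads.q2, pct_protein_pos=quads.q2 + quads.q3,
        dmfi_dna=dmfi_dna, dmfi_protein=dmfi_protein,
        n_viable=viable.n_events, quadrants=quads,
        gate_fractions=dict(res.fractions))
    if calibration is not None and dmfi_dna > 0:
        est = mfi_to_mesf(calibration, dmfi_dna)
        out.mesf_dna, out.mesf_dna_extrapolated = est.value, est.extrapolated
    if protein_calibration is not None and dmfi_protein > 0:
        est = mfi_to_mesf(protein_calibration, dmfi_protein)
        out.mesf_protein, out.mesf_protein_extrapolated = est.value, est.extrapolated
    return out


def toxicity_readout(sample: EventTable, untransfected: EventTable,
                     params: PipelineParams | None = None,
                     dye_reference: EventTable | None = None) -> ToxicityReadout:
    """Dead-cell fraction among intact singlets, vs the untransfected control.

    ``dye_reference`` supplies the dye-negative table for thresholding (the
    pipeline passes the zero-timepoint control); without a viability channel
    the scatter dead-region is used, referenced to the untransfected control.
    ``pct_dead_among_dna_pos`` — the dye-positive fraction of labeled-DNA-
    positive cells, direct toxicity of the internalized complex — is
    computed only when both channels are present.
    """
    params = params or PipelineParams()
    use_dye = sample.has_role("viability")
    ref = dye_reference if dye_reference is not None else untransfected

    def _dead_pct(table: EventTable) -> tuple[float, np.ndarray, np.ndarray]:
        singlet = fit_singlet_gate(table, band_width=params.band_width)
        intact = fit_intact_gate(table, lower_pct=params.intact_lower_pct,
                                 upper_pct=params.intact_upper_pct)
        if use_dye:
            vg = viability_gate_dye(table, ref, pct=params.viability_pct)
        else:
            vg = viability_gate_scatter(table, untransfected,
                                        fsc_pct=params.scatter_fsc_pct,
                                        ssc_pct=params.scatter_ssc_pct)
        res = apply_hierarchy(table, singlet, intact, vg)
        intact_mask = res.masks["intact"]
        dead_mask = intact_mask & ~res.masks["viable"]
        n_intact = int(intact_mask.sum())
        pct = 100.0 * int(dead_mask.sum()) / n_intact if n_intact else float("nan")
        return pct, intact_mask, dead_mask

    pct_dead, intact_mask, dead_mask = _dead_pct(sample)
    pct_dead_control, _, _ = _dead_pct(untransfected)

    pct_dead_dna_pos = None
    if use_dye and sample.has_role("dna_label") and untransfected.has_role("dna_label"):
        ctrl_gated = gate_sample(untransfected, params, untransfected,
                                 dye_reference=dye_reference)
        x_thr = positivity_threshold(
            ctrl_gated.viable_events(untransfected), "dna_label",
            params.positivity_pct)
        dna_pos = intact_mask & (sample.column("dna_label") > x_thr)
        n_pos = int(dna_pos.sum())
        if n_pos:
            pct_dead_dna_pos = 100.0 * int((dna_pos & dead_mask).sum()) / n_pos

    return ToxicityReadout(
        sample_id=sample.sample_id, pct_dead=pct_dead,
        pct_dead_control=pct_dead_control,
        excess_death=pct_dead - pct_dead_control,
        pct_dead_among_dna_pos=pct_dead_dna_pos,
        method="dye" if use_dye else "scatter")
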