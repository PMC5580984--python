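"""Hierarchical gating: singlets -> intact cells -> viable cells.

The hierarchy mirrors the standard manual workflow on a cell-line
transfection experiment: doublet discrimination on the FSC-H/FSC-A pulse
ratio, a scatter box to remove debris and aggregates, then dead-cell removal
either by a viability dye threshold or, when no dye can be used (e.g. after
electroporation), by a low-FSC/high-SSC scatter region.

All gates are pure, deterministic predicates over single events, fitted from
data by explicit rules (median ratio band, percentile boxes) rather than
drawn by hand, so a run is reproducible from its parameters alone.
Percentiles are computed with linear interpolation between order statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .event_io import EventTable

logger = logging.getLogger(__name__)

GATE_KINDS = ("ratio_band", "percentile_box", "threshold_above", "threshold_below")


@dataclass(frozen=True)
class Gate:
    """A pure per-event predicate.

    ``selects`` states what a True mask value means: ``"keep"`` (event passes
    to the next stage) or ``"dead"`` (event is removed by the viability
    stage).  ``params`` are kind-specific; boxes use ``lo``/``hi`` per role
    with infinities for open sides.
    """

    kind: str
    channels: tuple[str, ...]
    params: dict = field(default_factory=dict)
    selects: str = "keep"

    def __post_init__(self) -> None:
        if self.kind not in GATE_KINDS:
            raise ConfigurationError(f"unknown gate kind {self.kind!r}")
        for v in self.params.values():
            if not math.isfinite(v) and abs(v) != math.inf:
                raise ConfigurationError(f"non-finite gate parameter {v!r}")

    def mask(self, table: EventTable) -> np.ndarray:
        """Boolean vector: which events the gate selects."""
        if self.kind == "ratio_band":
            a = table.column(self.channels[0])
            h = table.column(self.channels[1])
            lo, hi = self.params["ratio_lo"], self.params["ratio_hi"]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(a > 0, h / np.where(a > 0, a, 1.0), np.nan)
            return (a > 0) & (ratio >= lo) & (ratio <= hi)
        if self.kind == "percentile_box":
            out = np.ones(table.n_events, dtype=bool)
            for role in self.channels:
                x = table.column(role)
                out &= (x >= self.params[f"{role}_lo"]) & (x <= self.params[f"{role}_hi"])
            return out
        x = table.column(self.channels[0])
        t = self.params["threshold"]
        if self.kind == "threshold_above":
            return x > t
        return x <= t  # threshold_below

    def to_dict(self) -> dict:
        return {"kind": self.kind, "channels": list(self.channels),
                "params": dict(self.params), "selects": self.selects}

    @classmethod
    def from_dict(cls, d: dict) -> "Gate":
        return cls(kind=d["kind"], channels=tuple(d["channels"]),
                   params=dict(d["params"]), selects=d.get("selects", "keep"))


@dataclass
class GatingResult:
    """Nested stage masks over the original event index.

    ``viable`` implies ``intact`` implies ``singlet`` by construction.
    Fractions are stage-wise survival (relative to the previous stage) and
    NaN when the previous stage is empty.
    """

    masks: dict[str, np.ndarray]
    counts: dict[str, int]
    fractions: dict[str, float]

    def viable_events(self, table: EventTable) -> EventTable:
        return table.subset(self.masks["viable"])


def _percentile(x: np.ndarray, q: float) -> float:
    return float(np.percentile(x, q))


def fit_singlet_gate(table: EventTable, band_width: float = 0.15) -> Gate:
    """Doublet discrimination on the FSC-H/FSC-A ratio.

    Keeps events whose height/area ratio lies within ``median * (1 +/- w)``;
    doublets sum pulse area across the two cells while height tracks the
    larger one, halving the ratio.
    """
    if not 0 < band_width < 1:
        raise ConfigurationError("band_width must be in (0, 1)")
    if table.n_events < 50:
        raise InsufficientDataError(
            f"singlet gate needs >= 50 events, got {table.n_events}")
    a = table.column("fsc_a")
    pos = a > 0
    if pos.mean() < 0.90:
        raise InsufficientDataError("fewer than 90% of events have FSC-A > 0")
    m = float(np.median(table.column("fsc_h")[pos] / a[pos]))
    return Gate(kind="ratio_band", channels=("fsc_a", "fsc_h"),
                params={"ratio_lo": m * (1 - band_width),
                        "ratio_hi": m * (1 + band_width)})


def fit_intact_gate(table: EventTable, lower_pct: float = 2.0,
                    upper_pct: float = 99.5,
                    reference: EventTable | None = None) -> Gate:
    """Scatter box removing debris and aggregates on (FSC-A, SSC-A).

    Box edges are per-axis percentiles of ``reference`` (an untransfected
    table) when given, else of the sample itself.  A degenerate axis (zero
    spread) passes everything on that axis with a warning.
    """
    src = reference if reference is not None else table
    if src.n_events < 50:
        raise InsufficientDataError(
            f"intact gate needs >= 50 events, got {src.n_events}")
    params = {}
    for role in ("fsc_a", "ssc_a"):
        x = src.column(role)
        lo, hi = _percentile(x, lower_pct), _percentile(x, upper_pct)
        if lo == hi:
            logger.warning("degenerate %s axis in intact gate; passing all", role)
            lo, hi = -np.inf, np.inf
        params[f"{role}_lo"], params[f"{role}_hi"] = lo, hi
    return Gate(kind="percentile_box", channels=("fsc_a", "ssc_a"), params=params)


def viability_gate_dye(table: EventTable, dye_control: EventTable,
                       pct: float = 99.5) -> Gate:
    """Dead-cell gate from a viability dye.

    Threshold at the ``pct``-th percentile of the dye channel in a
    dye-negative control; events above it are dead.
    """
    for t in (table, dye_control):
        if not t.has_role("viability"):
            raise ConfigurationError("viability channel not mapped")
    if dye_control.n_events == 0:
        raise InsufficientDataError("empty dye control")
    thr = _percentile(dye_control.column("viability"), pct)
    return Gate(kind="threshold_above", channels=("viability",),
                params={"threshold": thr}, selects="dead")


def viability_gate_scatter(table: EventTable, reference: EventTable,
                           fsc_pct: float = 10.0, ssc_pct: float = 75.0) -> Gate:
    """Dead-cell gate without a dye: shrunken FSC with inflated SSC.

    Events with FSC-A below the reference ``fsc_pct`` percentile AND SSC-A
    above the reference ``ssc_pct`` percentile are dead.  The reference is an
    untransfected sample.
    """
    if reference.n_events < 50:
        raise InsufficientDataError(
            f"scatter viability needs >= 50 reference events, got {reference.n_events}")
    fsc_lo = _percentile(reference.column("fsc_a"), fsc_pct)
    ssc_hi = _percentile(reference.column("ssc_a"), ssc_pct)
    # Dead region as an open percentile box: FSC-A in (-inf, fsc_lo),
    # SSC-A in (ssc_hi, inf); strict edges via nextafter keep the box closed.
    return Gate(kind="percentile_box", channels=("fsc_a", "ssc_a"),
                params={"fsc_a_lo": -np.inf,
                        "fsc_a_hi": float(np.nextafter(fsc_lo, -np.inf)),
                        "ssc_a_lo": float(np.nextafter(ssc_hi, np.inf)),
                        "ssc_a_hi": np.inf},
                selects="dead")


def apply_hierarchy(table: EventTable, singlet: Gate, intact: Gate,
                    viability: Gate | None = None) -> GatingResult:
    """Apply singlet -> intact -> viable in order within prior survivors."""
    n = table.n_events
    singlet_mask = singlet.mask(table) if n else np.zeros(0, dtype=bool)
    intact_mask = singlet_mask & (intact.mask(table) if n else True)
    if viability is None:
        viable_mask = intact_mask.copy()
    else:
        vm = viability.mask(table) if n else np.zeros(0, dtype=bool)
        dead = vm if viability.selects == "dead" else ~vm
        viable_mask = intact_mask & ~dead

    masks = {"singlet": singlet_mask, "intact": intact_mask, "viable": viable_mask}
    counts = {k: int(v.sum()) for k, v in masks.items()}
    nan = float("nan")
    fractions = {
        "singlet": counts["singlet"] / n if n else nan,
        "intact": counts["intact"] / counts["singlet"] if counts["singlet"] else nan,
        "viable": counts["viable"] / counts["intact"] if counts["intact"] else nan,
    }
    return GatingResult(masks=masks, counts=counts, fractions=fractions)
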