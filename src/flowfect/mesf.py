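"""MESF bead calibration and conversion to plasmid copies per cell.

MESF (Molecules of Equivalent Soluble Fluorochrome) beads carry several
populations with known numbers of fluorochrome molecules.  Regressing
log10(MESF) on log10(median intensity) over the detected bead peaks gives a
standard curve that converts any blank-corrected median fluorescence into an
absolute molecule count.  For a plasmid covalently labeled at a known density
(here one fluorophore per ~40 bp), the FITC-MESF of a cell divides by the
labels per plasmid to give plasmid copies, and by Avogadro's number to moles.

Peak medians are used throughout: the robust location for lognormal-like
bead populations, and consistent with the median MFI statistics used on
cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.constants import Avogadro

from .errors import CalibrationQualityError, DataError, InsufficientDataError
from .event_io import EventTable

MIN_R2 = 0.98
MERGE_RTOL = 0.10


@dataclass
class BeadSet:
    """Bead events on one fluorescence channel plus the kit's known values."""

    events: EventTable
    known_mesf: Sequence[float]
    has_blank: bool = False
    channel_role: str = "dna_label"

    def __post_init__(self) -> None:
        known = np.asarray(self.known_mesf, dtype=float)
        if known.size < 3:
            raise DataError("bead kit must list at least 3 MESF populations")
        if np.any(known <= 0) or np.any(np.diff(known) <= 0):
            raise DataError("known MESF values must be positive and strictly increasing")
        self.known_mesf = known

    @property
    def n_populations(self) -> int:
        return len(self.known_mesf)


@dataclass(frozen=True)
class BeadCalibration:
    """Fitted log-log standard curve: log10(MESF) = intercept + slope*log10(MFI)."""

    peak_mfi: tuple[float, ...]
    known_mesf: tuple[float, ...]
    slope: float
    intercept: float
    r2: float

    @property
    def valid_range(self) -> tuple[float, float]:
        return (self.peak_mfi[0], self.peak_mfi[-1])

    def to_dict(self) -> dict:
        return {"peak_mfi": list(self.peak_mfi), "known_mesf": list(self.known_mesf),
                "slope": self.slope, "intercept": self.intercept, "r2": self.r2,
                "valid_range": list(self.valid_range)}

    @classmethod
    def from_dict(cls, d: dict) -> "BeadCalibration":
        return cls(peak_mfi=tuple(d["peak_mfi"]), known_mesf=tuple(d["known_mesf"]),
                   slope=d["slope"], intercept=d["intercept"], r2=d["r2"])


class MesfEstimate(NamedTuple):
    value: float
    extrapolated: bool


def _kmeans_1d(x: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Deterministic 1-D Lloyd clustering with quantile initialization.

    Returns integer labels ordered so that cluster centers ascend.
    """
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    labels = np.zeros(x.size, dtype=int)
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        new_labels = np.argmin(d, axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            sel = labels == j
            if sel.any():
                centers[j] = x[sel].mean()
    order = np.argsort(centers)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels]


def detect_bead_peaks(beads: BeadSet) -> list[float]:
    """Locate the per-population median intensities of a bead acquisition.

    Clusters log10(MFI + 1) into K (+1 when a blank population is present)
    groups, takes per-cluster medians on the linear scale and matches them to
    the kit's known MESF values by rank.  Raises
    :class:`CalibrationQualityError` when two adjacent peaks are closer than
    10% relative — the signature of merged populations that would corrupt
    the standard curve.
    """
    k = beads.n_populations + (1 if beads.has_blank else 0)
    x = beads.events.column(beads.channel_role)
    if x.size < 100 * k:
        raise InsufficientDataError(
            f"bead peak detection needs >= {100 * k} events, got {x.size}")
    labels = _kmeans_1d(np.log10(np.maximum(x, 0) + 1.0), k)
    medians = [float(np.median(x[labels == j])) for j in range(k)]
    for lo, hi in zip(medians, medians[1:]):
        if hi <= 0 or (hi - lo) / hi < MERGE_RTOL:
            raise CalibrationQualityError(
                f"bead populations merged: adjacent peak medians {lo:.3g} and "
                f"{hi:.3g} are within {MERGE_RTOL:.0%} relative")
    if beads.has_blank:
        medians = medians[1:]
    return medians


def fit_mesf_curve(peak_mfi: Sequence[float],
                   known_mesf: Sequence[float]) -> BeadCalibration:
    """Ordinary least squares in log10-log10 space over the bead peaks."""
    mfi = np.asarray(peak_mfi, dtype=float)
    mesf = np.asarray(known_mesf, dtype=float)
    if mfi.size != mesf.size:
        raise DataError("peak and known-MESF lists differ in length")
    if np.any(mfi <= 0) or np.any(mesf <= 0):
        raise DataError("peak MFIs and MESF values must be positive")
    if np.any(np.diff(mfi) <= 0) or np.any(np.diff(mesf) <= 0):
        raise DataError("peak/known pairing must be strictly increasing on both sides")
    lx, ly = np.log10(mfi), np.log10(mesf)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (intercept + slope * lx)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    if r2 < MIN_R2:
        raise CalibrationQualityError(
            f"standard curve r2 = {r2:.4f} below quality bar {MIN_R2}")
    if slope <= 0:
        raise CalibrationQualityError(f"non-positive standard-curve slope {slope:.4f}")
    return BeadCalibration(peak_mfi=tuple(mfi), known_mesf=tuple(mesf),
                           slope=float(slope), intercept=float(intercept), r2=r2)


def calibrate_beads(beads: BeadSet) -> BeadCalibration:
    """Peak detection plus curve fit in one step."""
    return fit_mesf_curve(detect_bead_peaks(beads), beads.known_mesf)


def mfi_to_mesf(cal: BeadCalibration, mfi: float) -> MesfEstimate:
    """Convert an acquisition-scale MFI to MESF along the standard curve.

    Values outside the calibrated peak range are still converted but flagged
    as extrapolated.
    """
    if mfi <= 0:
        raise DataError(f"MESF conversion requires MFI > 0, got {mfi}")
    value = 10.0 ** (cal.intercept + cal.slope * np.log10(mfi))
    lo, hi = cal.valid_range
    return MesfEstimate(value=float(value), extrapolated=not (lo <= mfi <= hi))


@dataclass(frozen=True)
class PlasmidSpec:
    """A plasmid and its covalent labeling density (bp per fluorophore)."""

    name: str
    length_bp: int
    bp_per_label: float = 40.0

    def __post_init__(self) -> None:
        if self.length_bp <= 0 or self.bp_per_label <= 0:
            raise DataError("plasmid length and labeling density must be positive")
        if self.length_bp < self.bp_per_label:
            raise DataError("plasmid shorter than one labeling interval")


def labels_per_plasmid(spec: PlasmidSpec) -> float:
    """Expected fluorophores per plasmid molecule (real-valued, no rounding)."""
    return spec.length_bp / spec.bp_per_label


def plasmids_per_cell(mesf_fitc: float, spec: PlasmidSpec) -> tuple[float, float]:
    """(copies, moles) of plasmid per cell from a cell's FITC MESF."""
    if mesf_fitc < 0:
        raise DataError(f"MESF must be non-negative, got {mesf_fitc}")
    copies = mesf_fitc / labels_per_plasmid(spec)
    return copies, copies / Avogadro
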