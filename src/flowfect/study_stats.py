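"""Study-level analyses over per-sample readouts.

Covers the four recurring questions of a transfection-optimization study:
when uptake and expression peak over a time course, whether conditions
differ after normalizing each experiment to its own control, how
reproducible each readout is across independent assays (inter-assay CV),
and how strongly the different readouts agree (Spearman rank correlation).
Group comparisons use the nonparametric Kruskal-Wallis and Mann-Whitney
tests, matching common practice for small-n bioassay replicates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError, InsufficientDataError
from .readouts import TransfectionReadout


@dataclass
class TimeCourse:
    """Readouts at strictly increasing timepoints for one condition."""

    points: list[tuple[float, TransfectionReadout]]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DataError("timepoints must be strictly increasing")


@dataclass
class AssayMatrix:
    """One readout across independent assays: rows = assays, cols = samples."""

    values: np.ndarray
    readout_name: str = ""
    sample_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 2:
            raise InsufficientDataError("inter-assay CV needs >= 2 assays")


def timecourse_peaks(tc: TimeCourse) -> tuple[float, float]:
    """Timepoints of maximal ΔMFI for DNA uptake and protein expression.

    Argmax over the measured timepoints only (no interpolation — peaks are
    reported at sampled times); ties resolve to the earliest timepoint.
    """
    if len(tc.points) < 2:
        raise InsufficientDataError("peak finding needs >= 2 timepoints")
    times = np.array([t for t, _ in tc.points])
    dna = np.array([r.dmfi_dna for _, r in tc.points])
    protein = np.array([r.dmfi_protein for _, r in tc.points])
    return float(times[int(np.argmax(dna))]), float(times[int(np.argmax(protein))])


def normalize_to_control(values: Sequence[float],
                         control_values: Sequence[float]) -> np.ndarray:
    """Express values as percent of the experiment's own control mean.

    Per-experiment normalization lets readouts from different transfection
    methods (with different absolute scales) be pooled.
    """
    control_mean = float(np.mean(control_values))
    if control_mean == 0:
        raise DataError("control mean is zero; cannot normalize")
    return np.asarray(values, dtype=float) * 100.0 / control_mean


def interassay_cv(m: AssayMatrix | np.ndarray
                  ) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Per-sample inter-assay CV%, their mean, and (min, max) range.

    CV = 100 * sd / mean with the sample standard deviation (n-1).  Samples
    with non-positive mean get an undefined (NaN) CV and are excluded from
    the summary, with a warning.
    """
    values = m.values if isinstance(m, AssayMatrix) else AssayMatrix(m).values
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, 100.0 * sds / means, np.nan)
    if np.isnan(cvs).any():
        warnings.warn("CV undefined for samples with non-positive mean; excluded",
                      stacklevel=2)
    valid = cvs[~np.isnan(cvs)]
    if valid.size == 0:
        return cvs, float("nan"), (float("nan"), float("nan"))
    return cvs, float(valid.mean()), (float(valid.min()), float(valid.max()))


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all pairings (n <= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry0 = ry - ry.mean()
    perms = np.array(list(itertools.permutations(ry0)))
    denom = ry0.std() * len(x)
    rhos = perms @ rx / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlate_readouts(x: Sequence[float], y: Sequence[float]
                       ) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    The two-sided p-value is by exact permutation for n <= 9 and by the
    t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigurationError("x and y must have equal length")
    if x.size < 4:
        raise InsufficientDataError("correlation needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if x.size <= 9:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return rho, p


def compare_groups(groups: Sequence[Sequence[float]], test: str = "kruskal_wallis"
                   ) -> tuple[float, float]:
    """Nonparametric comparison across groups.

    ``kruskal_wallis`` for >= 2 groups; ``mann_whitney`` for exactly 2.
    Both use average-rank tie correction and asymptotic p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 3 for g in groups):
        raise InsufficientDataError("each group needs n >= 3")
    if test == "kruskal_wallis":
        if len(groups) < 2:
            raise ConfigurationError("Kruskal-Wallis needs >= 2 groups")
        stat, p = stats.kruskal(*groups)
    elif test == "mann_whitney":
        if len(groups) != 2:
            raise ConfigurationError("Mann-Whitney compares exactly 2 groups")
        stat, p = stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
    else:
        raise ConfigurationError(f"unknown test {test!r}")
    return float(stat), float(p)


def cv_anova(cv_groups: dict[str, Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA on per-sample CVs grouped by readout.

    Used to ask whether one readout is systematically more reproducible than
    the others; normality of CVs is not checked (see methods note).
    """
    arrays = [np.asarray(v, dtype=float) for v in cv_groups.values()]
    if len(arrays) < 2:
        raise ConfigurationError("ANOVA needs >= 2 readout groups")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
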