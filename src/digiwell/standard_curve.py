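"""Serial-dilution fitting, amplification efficiency, and single-copy Cq anchoring.

A 10-fold dilution series measured on the chip shows two regimes. At high
template every well amplifies and the mean Cq falls linearly with
log10(concentration); ordinary least squares on that range gives the slope and
the amplification efficiency E = 10^(-1/slope) - 1 (E = 1 means perfect
doubling each cycle, slope -3.3219). Below roughly one copy per partition the
mean Cq stops moving — the digital plateau — because almost every positive
well holds exactly one molecule. The pooled Cq of those singleton wells is the
single-copy anchor Cq1, which converts any Cq to a copy number:

    copies(Cq) = (1 + E)^(Cq1 - Cq).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import digital
from .chip import ChipRun
from .errors import FitError, InsufficientDataError, SaturationError

#: Slope of a perfectly doubling assay, -log2(10) reciprocal in cycles/log10.
PERFECT_SLOPE = -1.0 / math.log10(2.0)


@dataclass
class DilutionLevel:
    nominal_concentration: float  # copies/uL
    cq_values: list[float] = field(default_factory=list)
    runs: list[ChipRun] = field(default_factory=list)

    @property
    def mean_cq(self) -> float:
        return float(np.mean(self.cq_values)) if self.cq_values else math.nan

    @property
    def sd_cq(self) -> float:
        return float(np.std(self.cq_values, ddof=1)) if len(self.cq_values) > 1 else math.nan


@dataclass
class DilutionSeries:
    """Serial-dilution levels, kept sorted by ascending concentration."""

    levels: list[DilutionLevel]

    def __post_init__(self) -> None:
        if any(lv.nominal_concentration <= 0 for lv in self.levels):
            raise FitError("concentrations must be strictly positive")
        self.levels.sort(key=lambda lv: lv.nominal_concentration)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([lv.nominal_concentration for lv in self.levels])

    @property
    def mean_cqs(self) -> np.ndarray:
        return np.array([lv.mean_cq for lv in self.levels])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DilutionSeries":
        levels = [
            DilutionLevel(float(conc), [float(v) for v in grp["cq"].dropna()])
            for conc, grp in df.groupby("concentration", sort=True)
        ]
        return cls(levels=levels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DilutionSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class StandardCurveResults:
    """OLS fit of mean Cq on log10(concentration) plus derived efficiency."""

    slope: float  # cycles per log10
    intercept: float  # cycles at 1 copy/uL
    r_squared: float
    efficiency_fraction: float  # E; percent = 100 * E
    linear_range: tuple[int, ...]  # level indices used in the fit
    stderr_slope: float

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency_fraction

    def predict_cq(self, concentration: float) -> float:
        return self.slope * math.log10(concentration) + self.intercept

    def summary(self) -> str:
        return "\n".join(
            [
                "Standard curve (Cq ~ log10 concentration)",
                f"  slope        {self.slope:.4f} cycles/log10 (SE {self.stderr_slope:.4f})",
                f"  intercept    {self.intercept:.4f} cycles",
                f"  R^2          {self.r_squared:.4f}",
                f"  efficiency   {self.efficiency_percent:.2f}%",
                f"  levels used  {list(self.linear_range)}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "efficiency_fraction": self.efficiency_fraction,
            "efficiency_percent": self.efficiency_percent,
            "linear_range": list(self.linear_range),
        }

    def plot(self, series: DilutionSeries, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.log10(series.concentrations)
        ax.scatter(x, series.mean_cqs, color="k", label="levels")
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, self.slope * xs + self.intercept, label="fit")
        ax.set_xlabel("log10 concentration (copies/µL)")
        ax.set_ylabel("mean Cq")
        ax.legend()
        return ax


def efficiency_from_slope(slope: float) -> float:
    """E = 10^(-1/slope) - 1; the fraction of templates copied per cycle."""
    return float(10.0 ** (-1.0 / slope) - 1.0)


class StandardCurveModel:
    """Model object for a dilution series; ``fit`` returns the curve results."""

    def __init__(self, series: DilutionSeries):
        self.series = series

    def fit(self, levels: Sequence[int] | None = None) -> StandardCurveResults:
        idx = tuple(range(len(self.series.levels))) if levels is None else tuple(levels)
        if len(idx) < 2:
            raise FitError("standard curve needs at least two levels")
        conc = self.series.concentrations[list(idx)]
        cq = self.series.mean_cqs[list(idx)]
        if np.unique(conc).size < 2:
            raise FitError("identical concentrations: singular fit")
        res = stats.linregress(np.log10(conc), cq)
        return StandardCurveResults(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            efficiency_fraction=efficiency_from_slope(float(res.slope)),
            linear_range=idx,
            stderr_slope=float(res.stderr),
        )


def fit_standard_curve(
    series: DilutionSeries, levels: Sequence[int] | None = None
) -> StandardCurveResults:
    return StandardCurveModel(series).fit(levels)


def detect_digital_regime(
    series: DilutionSeries, anchor_tolerance: float = 0.5
) -> tuple[list[int], list[int]]:
    """Split the series into (linear_levels, plateau_levels) by mean-Cq flatness.

    The plateau is the maximal low-concentration suffix whose consecutive
    mean-Cq differences stay below ``anchor_tolerance`` cycles despite at
    least a 2-fold concentration change — the signature of the digital regime
    where mean Cq is pinned at the single-copy value. A lone flat level is
    not evidence; a strictly linear series returns an empty plateau.
    """
    if len(series.levels) < 3:
        raise FitError("regime detection needs at least three levels")
    conc = series.concentrations
    cq = series.mean_cqs
    j = 0
    while j + 1 < len(series.levels):
        if conc[j + 1] / conc[j] >= 2.0 and abs(cq[j + 1] - cq[j]) < anchor_tolerance:
            j += 1
        else:
            break
    plateau = list(range(j + 1)) if j >= 1 else []
    linear = [i for i in range(len(series.levels)) if i not in plateau]
    return linear, plateau


@dataclass
class SingleCopyAnchor:
    """Mean and SD of the single-copy Cq, pooled from digital-regime runs."""

    cq1_mean: float
    cq1_sd: float
    n_wells: int
    source_levels: list[float]  # nominal concentrations of the source runs

    def to_dict(self) -> dict:
        return {
            "cq1_mean": self.cq1_mean,
            "cq1_sd": self.cq1_sd,
            "n_wells": self.n_wells,
            "source_levels": self.source_levels,
        }


PER_WELL = "per_well"
PER_LEVEL = "per_level"


def estimate_single_copy_cq(
    runs: Sequence[ChipRun],
    weighting: str = PER_WELL,
    one_copy_threshold: float = 0.95,
) -> SingleCopyAnchor:
    """Anchor Cq1 on runs whose wells are almost surely singletons.

    A run qualifies when its chip-wide P(at most one copy per well), with
    lambda = k/(n - fail), is at least ``one_copy_threshold``. ``per_well``
    pools every positive-well Cq; ``per_level`` averages the per-run means
    (the two differ when the qualifying runs have unequal positive counts).
    """
    qualifying = []
    for run in runs:
        try:
            p = digital.single_copy_probability(run.k_positive, run.n_partitions, run.n_fail)
        except SaturationError:
            continue
        if p / 100.0 >= one_copy_threshold and run.k_positive > 0:
            qualifying.append(run)
    if not qualifying:
        raise InsufficientDataError(
            "no runs in the digital regime (one-copy probability below threshold)"
        )
    levels = [
        run.metadata.nominal_concentration
        for run in qualifying
        if run.metadata.nominal_concentration is not None
    ]
    if weighting == PER_WELL:
        pooled = np.concatenate([run.positive_cqs() for run in qualifying])
        mean = float(np.mean(pooled))
        sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
        n = int(pooled.size)
    elif weighting == PER_LEVEL:
        means = np.array([float(np.mean(run.positive_cqs())) for run in qualifying])
        mean = float(np.mean(means))
        sd = float(np.std(means, ddof=1)) if means.size > 1 else 0.0
        n = sum(run.k_positive for run in qualifying)
    else:
        raise FitError(f"unknown weighting {weighting!r}")
    return SingleCopyAnchor(cq1_mean=mean, cq1_sd=sd, n_wells=n, source_levels=levels)


def copies_from_cq(
    cq: float | np.ndarray,
    anchor: SingleCopyAnchor | float,
    efficiency_fraction: float,
) -> float | np.ndarray:
    """Copies corresponding to a Cq: (1 + E)^(Cq1 - Cq).

    Strictly decreasing in Cq and equal to 1 at the anchor; one cycle earlier
    means (1 + E) times more template.
    """
    if efficiency_fraction <= 0:
        raise FitError("efficiency must be positive")
    cq1 = anchor.cq1_mean if isinstance(anchor, SingleCopyAnchor) else float(anchor)
    return (1.0 + efficiency_fraction) ** (cq1 - np.asarray(cq, dtype=float) * 1.0)


def estimate_run_copies(
    run: ChipRun,
    anchor: SingleCopyAnchor | float,
    efficiency_fraction: float,
    saturation_fraction: float = 0.95,
) -> float:
    """Total copies over the full dynamic range.

    Below saturation the Poisson digital estimate is used; once more than
    ``saturation_fraction`` of effective partitions are positive, counting is
    uninformative and the estimate switches to the Cq-anchored form
    k * copies_from_cq(mean positive Cq).
    """
    n_eff = digital.effective_partitions(run.n_partitions, run.n_fail, run.n_dimer_expected or 0.0)
    k = run.k_positive
    if k < saturation_fraction * n_eff:
        return digital.total_copies_digital(k, n_eff)
    mean_cq = float(np.mean(run.positive_cqs()))
    return float(k * copies_from_cq(mean_cq, anchor, efficiency_fraction))
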