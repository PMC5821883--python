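"""Poisson model of cell loading across the 2,500-well chip.

Cells settling randomly and independently land in wells with Poisson
occupancy: with N input cells over n wells (lambda = N/n),

    P0 = e^(-N/n),   P1 = (N/n) e^(-N/n),   P2+ = 1 - P0 - P1.

The number of occupied (reactive) wells k' inverts to the input count through
the same relation used for molecules, X = log(1 - k'/n)/log(1 - 1/n). The
single-cell fraction — the chance an occupied well holds exactly one cell —
is P1/(1 - P0); at 500 cells over 2,500 wells it is 90.33%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .digital import total_copies_digital
from .errors import FitError, FormatError, InsufficientDataError, UnattainableError

DEFAULT_N_WELLS = 2500


def estimate_input_cells(k_reactive: float, n_wells: int = DEFAULT_N_WELLS) -> float:
    """Total input cells from the count of occupied wells (Poisson inversion)."""
    return total_copies_digital(k_reactive, float(n_wells))


def occupancy_probabilities(
    n_input: float, n_wells: int = DEFAULT_N_WELLS
) -> tuple[float, float, float]:
    """(P0, P1, P2+) for N input cells over n wells; sums to 1 exactly."""
    if n_input < 0:
        raise FormatError("input cell count must be nonnegative")
    lam = n_input / n_wells
    p0 = math.exp(-lam)
    p1 = lam * math.exp(-lam)
    return p0, p1, 1.0 - p0 - p1


def single_cell_fraction(n_input: float, n_wells: int = DEFAULT_N_WELLS) -> float:
    """Percent of occupied wells holding exactly one cell: 100*P1/(1-P0)."""
    if n_input <= 0:
        raise FormatError("single-cell fraction undefined without input cells")
    lam = n_input / n_wells
    return float(100.0 * lam * math.exp(-lam) / -math.expm1(-lam))


def recommend_loading(
    target_single_fraction: float, n_wells: int = DEFAULT_N_WELLS
) -> float:
    """Largest input-cell count whose single-cell fraction meets the target.

    The fraction decreases monotonically with load, so the recommendation is
    the root of single_cell_fraction(N) = target (found by bracketed
    root-finding); any smaller load also meets the target but wastes wells.
    """
    if not (0 < target_single_fraction < 100):
        raise UnattainableError("target single-cell fraction must lie in (0, 100)%")
    f = lambda n: single_cell_fraction(n, n_wells) - target_single_fraction
    lo, hi = 1e-9, float(n_wells)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e9 * n_wells:  # pragma: no cover - unreachable for valid targets
            raise UnattainableError("target not bracketed")
    return float(brentq(f, lo, hi, xtol=1e-9, rtol=1e-12))


@dataclass
class OccupancyObservation:
    """Microscopic well-occupancy histogram for one nominal cell load."""

    n_input_nominal: float
    counts_per_occupancy: dict[int, int]  # occupancy -> number of wells
    n_wells: int = DEFAULT_N_WELLS

    def __post_init__(self) -> None:
        total = sum(self.counts_per_occupancy.values())
        if total != self.n_wells:
            raise FormatError(
                f"occupancy counts sum to {total}, expected {self.n_wells}"
            )

    @property
    def proportions(self) -> tuple[float, float, float]:
        """Observed (p0, p1, p2+)."""
        n = self.n_wells
        p0 = self.counts_per_occupancy.get(0, 0) / n
        p1 = self.counts_per_occupancy.get(1, 0) / n
        return p0, p1, 1.0 - p0 - p1

    @property
    def n_occupied(self) -> int:
        return self.n_wells - self.counts_per_occupancy.get(0, 0)


CATEGORIES = ("0", "1", "2+")


@dataclass
class OccupancyModelFit:
    """Goodness of the Poisson occupancy model against observed proportions."""

    n_wells: int
    loads: np.ndarray
    observed: pd.DataFrame  # columns 0, 1, 2+ indexed by load
    predicted: pd.DataFrame
    r_squared_per_category: dict[str, float]
    estimated_N_per_load: list[float]

    def summary(self) -> str:
        lines = ["Poisson occupancy fit (n = %d wells)" % self.n_wells]
        for cat in CATEGORIES:
            lines.append(f"  R^2 [{cat} cells]  {self.r_squared_per_category[cat]:.4f}")
        for load, est in zip(self.loads, self.estimated_N_per_load):
            lines.append(f"  load {load:>7.0f} -> estimated N = {est:.1f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_wells": self.n_wells,
            "loads": self.loads.tolist(),
            "r_squared_per_category": self.r_squared_per_category,
            "estimated_N_per_load": self.estimated_N_per_load,
        }

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        markers = {"0": "o", "1": "s", "2+": "v"}
        xs = np.linspace(0, self.loads.max() * 1.05, 200)
        for cat in CATEGORIES:
            ax.scatter(self.loads, self.observed[cat], marker=markers[cat], label=f"{cat} cells")
        probs = np.array([occupancy_probabilities(x, self.n_wells) for x in xs])
        for i in range(3):
            ax.plot(xs, probs[:, i], lw=0.8)
        ax.set_xlabel("input cells")
        ax.set_ylabel("proportion of wells")
        ax.legend()
        return ax


class PoissonOccupancyModel:
    """Fits (checks) the Poisson occupancy curves against counted wells.

    The chip size n is fixed, so the theoretical curves have no free
    parameter; ``fit`` reports per-category R-squared of the observed
    proportions against the model at the nominal loads, plus the Poisson
    inversion estimate of the true input count at each load.
    """

    def __init__(self, observations: Sequence[OccupancyObservation]):
        if len(observations) < 3:
            raise InsufficientDataError("occupancy fit needs at least three load levels")
        n_wells = {o.n_wells for o in observations}
        if len(n_wells) != 1:
            raise FormatError("observations mix chip sizes")
        self.observations = sorted(observations, key=lambda o: o.n_input_nominal)
        self.n_wells = n_wells.pop()

    def fit(self) -> OccupancyModelFit:
        loads = np.array([o.n_input_nominal for o in self.observations], dtype=float)
        obs = np.array([o.proportions for o in self.observations])
        pred = np.array([occupancy_probabilities(x, self.n_wells) for x in loads])
        r2 = {}
        for i, cat in enumerate(CATEGORIES):
            ss_res = float(np.sum((obs[:, i] - pred[:, i]) ** 2))
            ss_tot = float(np.sum((obs[:, i] - obs[:, i].mean()) ** 2))
            r2[cat] = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
        if all(math.isnan(v) for v in r2.values()):
            raise FitError("degenerate observations: no variation across loads")
        estimated = [
            estimate_input_cells(o.n_occupied, self.n_wells) for o in self.observations
        ]
        observed_df = pd.DataFrame(obs, columns=CATEGORIES, index=loads)
        predicted_df = pd.DataFrame(pred, columns=CATEGORIES, index=loads)
        return OccupancyModelFit(
            n_wells=self.n_wells,
            loads=loads,
            observed=observed_df,
            predicted=predicted_df,
            r_squared_per_category=r2,
            estimated_N_per_load=estimated,
        )


def fit_poisson_occupancy(
    observations: Sequence[OccupancyObservation],
) -> OccupancyModelFit:
    return PoissonOccupancyModel(observations).fit()


def read_occupancy_table(path) -> list[OccupancyObservation]:
    """Read an occupancy CSV (load_nominal,cells_in_well,count) into observations."""
    df = pd.read_csv(path)
    missing = [c for c in ("load_nominal", "cells_in_well", "count") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for load, grp in df.groupby("load_nominal", sort=True):
        counts = {int(r.cells_in_well): int(r.count) for r in grp.itertuples(index=False)}
        out.append(
            OccupancyObservation(
                n_input_nominal=float(load),
                counts_per_occupancy=counts,
                n_wells=sum(counts.values()),
            )
        )
    return out
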