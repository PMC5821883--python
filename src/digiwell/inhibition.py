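"""Quantifying PCR inhibitor (heparin) effects and fitting IC50.

Inhibition is expressed as percent-of-control against a no-inhibitor control
(NIC). In a bulk reaction the Cq shift carries the signal:

    percent = 100 * (1 + E)^(Cq_NIC - Cq'),

since an inhibited reaction reaching the same fluorescence threshold K with
the same template must have lost (1+E)^(Cq' - Cq_NIC) fold of signal. On the
chip, counting survives inhibition of individual partitions, so the digital
percent-of-control is simply the ratio of Poisson copy estimates. Modelling
the loss as an efficiency decrement E' (amplification proceeds at 1+E+E' per
cycle) and equating the two threshold expressions gives

    E' = (1 + E) * ((N_apparent / N_true)^(1/Cq') - 1)  <= 0 under inhibition.

The dose-response curve of percent-of-control against inhibitor concentration
is summarised by its IC50 via a 4-parameter log-logistic (Hill) fit with top
and bottom fixed at 100 and 0 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .digital import total_copies_digital
from .errors import FitError, FormatError, InsufficientDataError

#: Heparin stocks are added 1 uL into a 20 uL reaction; final = stock / 20.
STOCK_DILUTION_FACTOR = 20.0


def percent_of_control(
    cq_inhibited: float, cq_nic: float, efficiency_fraction: float
) -> float:
    """Bulk percent-of-control from the Cq shift against the NIC."""
    if efficiency_fraction <= 0:
        raise FormatError("efficiency must be positive")
    return float(100.0 * (1.0 + efficiency_fraction) ** (cq_nic - cq_inhibited))


def digital_percent_of_control(k_inhibited: float, k_nic: float, n_eff: float) -> float:
    """Chip percent-of-control: ratio of Poisson copy estimates."""
    if k_nic <= 0:
        raise InsufficientDataError("no positive wells in the no-inhibitor control")
    if k_inhibited == 0:
        return 0.0
    return float(
        100.0 * total_copies_digital(k_inhibited, n_eff) / total_copies_digital(k_nic, n_eff)
    )


def inhibitory_parameter(
    n_true: float, n_apparent: float, efficiency_fraction: float, cq_inhibited: float
) -> float:
    """Efficiency decrement E' explaining an apparent copy loss at a given Cq'."""
    if n_true <= 0 or n_apparent <= 0:
        raise FormatError("copy numbers must be positive")
    if cq_inhibited <= 0:
        raise FormatError("Cq' must be positive")
    return float(
        (1.0 + efficiency_fraction)
        * ((n_apparent / n_true) ** (1.0 / cq_inhibited) - 1.0)
    )


def apparent_copy_ratio(
    eprime: float, efficiency_fraction: float, cq_inhibited: float
) -> float:
    """Inverse of :func:`inhibitory_parameter`: N_apparent/N_true given E'."""
    return float((1.0 + eprime / (1.0 + efficiency_fraction)) ** cq_inhibited)


@dataclass
class InhibitionCurveFit:
    """Fitted log-logistic dose-response curve and its IC50."""

    points: pd.DataFrame  # concentration, percent_of_control[, sd]
    ic50: float  # IU/mL, concentration at 50% of control
    hill_slope: float
    top: float
    bottom: float
    r_squared: float
    residuals: np.ndarray = field(repr=False)

    def predict(self, concentration: float | np.ndarray) -> np.ndarray:
        c = np.asarray(concentration, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (c / self.ic50) ** self.hill_slope
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "Inhibition curve (log-logistic)",
                f"  IC50        {self.ic50:.4g} IU/mL",
                f"  Hill slope  {self.hill_slope:.3f}",
                f"  top/bottom  {self.top:.1f}% / {self.bottom:.1f}%",
                f"  R^2         {self.r_squared:.4f}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "ic50": self.ic50,
            "hill_slope": self.hill_slope,
            "top": self.top,
            "bottom": self.bottom,
            "r_squared": self.r_squared,
            "residuals": self.residuals.tolist(),
        }

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.points["concentration"].to_numpy()
        ax.scatter(c, self.points["percent_of_control"], color="k")
        xs = np.geomspace(c.min() / 3, c.max() * 3, 100)
        ax.plot(xs, self.predict(xs))
        ax.axvline(self.ic50, ls="--", lw=0.8)
        ax.set_xscale("log")
        ax.set_xlabel("inhibitor concentration (IU/mL)")
        ax.set_ylabel("percent of control")
        return ax


class InhibitionCurve:
    """Dose-response model over (concentration, percent-of-control) points.

    Zero-concentration rows are the NIC and are excluded from the fit's
    abscissa (log 0 is undefined); they should already define the 100% level.
    """

    def __init__(self, points: pd.DataFrame | list[dict]):
        df = pd.DataFrame(points)
        if not {"concentration", "percent_of_control"} <= set(df.columns):
            raise FormatError("points need concentration and percent_of_control columns")
        self.points = df[df["concentration"] > 0].reset_index(drop=True)

    def fit(
        self,
        top: float | None = 100.0,
        bottom: float | None = 0.0,
    ) -> InhibitionCurveFit:
        """Nonlinear least squares; pass ``top=None``/``bottom=None`` to free them."""
        c = self.points["concentration"].to_numpy(dtype=float)
        y = self.points["percent_of_control"].to_numpy(dtype=float)
        if np.unique(c).size < 4:
            raise InsufficientDataError("IC50 fit needs at least four concentrations")
        if y.max() - y.min() < 10.0:
            raise FitError("no transition in the inhibition points; IC50 undetermined")

        fixed_top, fixed_bottom = top, bottom

        def model(conc, log_ic50, hill, *rest):
            t = rest[0] if fixed_top is None else fixed_top
            b = rest[-1] if fixed_bottom is None else fixed_bottom
            return b + (t - b) / (1.0 + (conc / 10.0**log_ic50) ** hill)

        # Initial IC50: concentration where the points cross 50% (log interp).
        order = np.argsort(c)
        y50 = np.interp(50.0, y[order][::-1], np.log10(c[order][::-1]))
        p0 = [float(np.clip(y50, np.log10(c.min()) - 1, np.log10(c.max()) + 1)), 1.0]
        lower = [np.log10(c.min()) - 3, 0.05]
        upper = [np.log10(c.max()) + 3, 20.0]
        if fixed_top is None:
            p0.append(float(y.max()))
            lower.append(50.0)
            upper.append(200.0)
        if fixed_bottom is None:
            p0.append(float(y.min()))
            lower.append(-50.0)
            upper.append(50.0)
        try:
            popt, _ = curve_fit(model, c, y, p0=p0, bounds=(lower, upper), maxfev=20000)
        except RuntimeError as exc:  # pragma: no cover - depends on data
            raise FitError(f"IC50 fit did not converge: {exc}") from exc
        pred = model(c, *popt)
        resid = y - pred
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
        rest = list(popt[2:])
        t = rest.pop(0) if fixed_top is None else fixed_top
        b = rest.pop(0) if fixed_bottom is None else fixed_bottom
        return InhibitionCurveFit(
            points=self.points.copy(),
            ic50=float(10.0 ** popt[0]),
            hill_slope=float(popt[1]),
            top=float(t),
            bottom=float(b),
            r_squared=r2,
            residuals=resid,
        )


def fit_ic50(points: pd.DataFrame | list[dict], **kwargs) -> InhibitionCurveFit:
    return InhibitionCurve(points).fit(**kwargs)


def percent_points_from_bulk(
    df: pd.DataFrame, efficiency_fraction: float
) -> pd.DataFrame:
    """Percent-of-control points from a bulk CSV (concentration_iu_ml, cq).

    Rows at concentration 0 are the NIC; their mean Cq defines 100%.
    """
    col = "concentration_iu_ml" if "concentration_iu_ml" in df.columns else "concentration"
    nic = df[df[col] == 0]["cq"]
    if nic.empty:
        raise InsufficientDataError("bulk table has no zero-concentration NIC rows")
    cq_nic = float(nic.mean())
    rows = []
    for conc, grp in df[df[col] > 0].groupby(col, sort=True):
        pcts = [percent_of_control(float(v), cq_nic, efficiency_fraction) for v in grp["cq"]]
        rows.append(
            {
                "concentration": float(conc),
                "percent_of_control": float(np.mean(pcts)),
                "sd": float(np.std(pcts, ddof=1)) if len(pcts) > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows)
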