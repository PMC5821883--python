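"""Poisson digital quantification from positive-partition counts.

When a template solution is split over n partitions, the per-partition copy
number is Poisson with mean lambda. Counting the k positive (amplified)
partitions estimates lambda = -ln(1 - k/n) and hence the total number of
template copies loaded on the chip,

    total = log(1 - k/n') / log(1 - 1/n'),

where n' is the effective partition count after removing failed wells and the
expected number of primer-dimer false positives (estimated from no-template
controls). Replicate means are accepted, so k may be non-integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .chip import ChipRun
from .errors import FormatError, InsufficientDataError, SaturationError

AT_MOST_ONE = "at_most_one"
EXACTLY_ONE_GIVEN_POSITIVE = "exactly_one_given_positive"


def effective_partitions(n: int, n_fail: float = 0.0, n_dimer: float = 0.0) -> float:
    """n' = n - fail wells - expected primer-dimer false positives."""
    n_eff = n - n_fail - n_dimer
    if n_eff <= 0:
        raise FormatError(
            f"effective partitions nonpositive (n={n}, fail={n_fail}, dimer={n_dimer})"
        )
    return float(n_eff)


def lambda_from_positives(k: float, n_eff: float) -> float:
    """Mean copies per partition, lambda = -ln(1 - k/n_eff)."""
    if k < 0:
        raise FormatError("k must be nonnegative")
    if k >= n_eff:
        raise SaturationError(
            f"all {n_eff:g} effective partitions positive (k={k:g}); "
            "concentration not quantifiable, dilute the sample"
        )
    return float(-math.log1p(-k / n_eff))


def total_copies_digital(k: float, n_eff: float) -> float:
    """Estimated total template copies, log(1 - k/n')/log(1 - 1/n').

    Equals lambda * n_eff to first order (within 0.03% for n' = 2500) and
    tends to k as the chip empties.
    """
    lam = lambda_from_positives(k, n_eff)  # validates inputs
    return float(lam / -math.log1p(-1.0 / n_eff))


def poisson_copy_pmf(lambda_mean: float, x: int) -> float:
    """P(X = x) = e^(-lambda) lambda^x / x! for the per-partition copy number."""
    if lambda_mean < 0:
        raise FormatError("lambda must be nonnegative")
    return float(stats.poisson.pmf(x, lambda_mean))


def single_copy_probability(
    k: float,
    n: int,
    n_fail: float = 0.0,
    convention: str = AT_MOST_ONE,
) -> float:
    """Percent probability that a well holds (at most / exactly) one copy.

    With lambda = k/(n - n_fail):

    - ``at_most_one``: 100 * e^(-lambda)(1 + lambda) — the chip-wide
      probability that a partition holds 0 or 1 copies. This convention
      reproduces the published per-level "1 copy (%)" figures.
    - ``exactly_one_given_positive``: 100 * lambda e^(-lambda)/(1 - e^(-lambda))
      — the chance a *positive* well is a true singleton.
    """
    denom = n - n_fail
    if denom <= 0 or k >= denom:
        raise SaturationError("k must be below the usable partition count")
    lam = k / denom
    if convention == AT_MOST_ONE:
        return float(100.0 * math.exp(-lam) * (1.0 + lam))
    if convention == EXACTLY_ONE_GIVEN_POSITIVE:
        if k == 0:
            raise InsufficientDataError(
                "exactly-one-given-positive is undefined with no positive wells"
            )
        return float(100.0 * lam * math.exp(-lam) / -math.expm1(-lam))
    raise FormatError(f"unknown convention {convention!r}")


@dataclass
class DigitalQuantResult:
    """Full digital quantification of one chip run."""

    k_positive: float
    n_partitions: int
    n_fail: float
    n_dimer: float
    n_effective: float
    lambda_mean: float
    total_copies: float
    total_ci_low: float
    total_ci_high: float
    p_exactly_one: float  # percent, of positive wells
    p_at_most_one: float  # percent, chip-wide
    dimers_subtracted: bool

    def summary(self) -> str:
        lines = [
            "Digital quantification",
            f"  positive wells (k)        {self.k_positive:g}",
            f"  fail wells                {self.n_fail:g}",
            f"  expected dimers           {self.n_dimer:g}"
            + ("  (subtracted from k)" if self.dimers_subtracted else ""),
            f"  effective partitions (n') {self.n_effective:.2f}",
            f"  lambda (copies/partition) {self.lambda_mean:.4f}",
            f"  total copies              {self.total_copies:.2f}"
            f"  [95% CI {self.total_ci_low:.2f}, {self.total_ci_high:.2f}]",
            f"  P(<=1 copy | any well)    {self.p_at_most_one:.1f}%",
            f"  P(=1 copy | positive)     {self.p_exactly_one:.1f}%"
            if not math.isnan(self.p_exactly_one)
            else "  P(=1 copy | positive)     undefined (k=0)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k_positive": self.k_positive,
            "n_partitions": self.n_partitions,
            "n_fail": self.n_fail,
            "n_dimer": self.n_dimer,
            "n_effective": self.n_effective,
            "lambda_mean": self.lambda_mean,
            "total_copies": self.total_copies,
            "total_ci_low": self.total_ci_low,
            "total_ci_high": self.total_ci_high,
            "p_exactly_one_percent": self.p_exactly_one,
            "p_at_most_one_percent": self.p_at_most_one,
            "dimers_subtracted": self.dimers_subtracted,
        }


def quantify_counts(
    k: float,
    n: int,
    n_fail: float = 0.0,
    n_dimer: float = 0.0,
    subtract_dimers: bool = False,
) -> DigitalQuantResult:
    """Digital quantification from raw counts (k may be a replicate mean)."""
    n_eff = effective_partitions(n, n_fail, n_dimer)
    k_eff = max(k - n_dimer, 0.0) if subtract_dimers else float(k)
    if k_eff == 0:
        lam, total, lo, hi = 0.0, 0.0, 0.0, 0.0
    else:
        lam = lambda_from_positives(k_eff, n_eff)
        total = total_copies_digital(k_eff, n_eff)
        # Normal approximation on lambda: var(lambda) ~ (e^lambda - 1)/n_eff.
        se = math.sqrt(math.expm1(lam) / n_eff)
        per_lambda = 1.0 / -math.log1p(-1.0 / n_eff)
        lo = max(0.0, (lam - 1.959963984540054 * se) * per_lambda)
        hi = (lam + 1.959963984540054 * se) * per_lambda
    p_le1 = single_copy_probability(k_eff, n, n_fail, AT_MOST_ONE)
    p_eq1 = (
        single_copy_probability(k_eff, n, n_fail, EXACTLY_ONE_GIVEN_POSITIVE)
        if k_eff > 0
        else math.nan
    )
    return DigitalQuantResult(
        k_positive=float(k),
        n_partitions=n,
        n_fail=float(n_fail),
        n_dimer=float(n_dimer),
        n_effective=n_eff,
        lambda_mean=lam,
        total_copies=total,
        total_ci_low=lo,
        total_ci_high=hi,
        p_exactly_one=p_eq1,
        p_at_most_one=p_le1,
        dimers_subtracted=subtract_dimers,
    )


def quantify_run(
    run: ChipRun,
    ntc: ChipRun | Sequence[ChipRun] | None = None,
    subtract_dimers: bool = False,
) -> DigitalQuantResult:
    """End-to-end digital quantification of a called chip run.

    The expected primer-dimer count comes, in order of preference, from the
    supplied NTC run(s) (their mean positive count), from the run's stored
    ``n_dimer_expected``, or from analyst-marked dimer wells. It always
    reduces n' (failed chemistry occupies partitions); it is subtracted from
    k only when ``subtract_dimers`` is set, since dimer signals are
    indistinguishable from true positives on the instrument.
    """
    if ntc is not None:
        ntcs = [ntc] if isinstance(ntc, ChipRun) else list(ntc)
        n_dimer = float(np.mean([r.k_positive + r.n_dimer_wells for r in ntcs]))
    elif run.n_dimer_expected is not None:
        n_dimer = float(run.n_dimer_expected)
    else:
        n_dimer = float(run.n_dimer_wells)
    return quantify_counts(
        k=float(run.k_positive),
        n=run.n_partitions,
        n_fail=float(run.n_fail),
        n_dimer=n_dimer,
        subtract_dimers=subtract_dimers,
    )
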