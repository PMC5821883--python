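"""Single-cell gene-expression profiling from per-well Cq values.

Each reactive well is assumed to hold a single cell, and its transcript count
is anchored to a single-copy reference Cq (a GAPDH-derived Cq1):

    A = 2^(Cq1 - Cq)  copies per cell.

Per-cell copy numbers are heavily right-skewed, so groups are summarised by
their geometric mean (equivalently, the arithmetic mean in Cq space) and
compared with Kolmogorov-Smirnov tests: one-sample KS against normal or
lognormal families to characterise the distribution shape, and two-sample KS
between treatment time points to detect differential expression. The
two-sample statistic is invariant under the log transform; the one-sample
test is run on log copies for the lognormal family. p-values for the pairwise
comparisons are Holm-adjusted across the family of tests per gene (raw values
are kept alongside).

Caveat: the one-sample tests estimate the reference family's moments from the
same data, which inflates the type-I error (the Lilliefors effect); a
parametric-bootstrap p-value is available via ``n_bootstrap``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, InsufficientDataError

ONE_SAMPLE_NORMAL = "one_sample_normal"
ONE_SAMPLE_LOGNORMAL = "one_sample_lognormal"
TWO_SAMPLE = "two_sample"


def copies_per_cell(cq: float | np.ndarray, cq1_ref: float) -> float | np.ndarray:
    """Initial transcript copies in the cell: 2^(Cq1 - Cq)."""
    return 2.0 ** (cq1_ref - np.asarray(cq, dtype=float))


def geometric_mean_copies(values) -> float:
    """exp(mean(ln values)); equals copies_per_cell at the arithmetic-mean Cq."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no reactive wells to average")
    if np.any(arr <= 0):
        raise FormatError("geometric mean requires positive copy numbers")
    return float(np.exp(np.mean(np.log(arr))))


@dataclass
class KSResult:
    statistic_d: float
    p_value: float
    test: str
    groups: tuple[str, ...] = ()
    n: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "statistic_D": self.statistic_d,
            "p_value": self.p_value,
            "test": self.test,
            "groups": list(self.groups),
            "n": list(self.n),
        }


def ks_one_sample(
    values,
    family: str = "normal",
    n_bootstrap: int = 0,
    rng: np.random.Generator | int | None = None,
) -> KSResult:
    """One-sample KS against a normal/lognormal family with estimated moments."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise InsufficientDataError("one-sample KS needs at least 5 values")
    if family == "lognormal":
        if np.any(arr <= 0):
            raise FormatError("lognormal test requires positive values")
        x = np.log(arr)
        test = ONE_SAMPLE_LOGNORMAL
    elif family == "normal":
        x = arr
        test = ONE_SAMPLE_NORMAL
    else:
        raise FormatError(f"unknown family {family!r}")
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0:
        raise InsufficientDataError("degenerate (constant) sample")
    d, p = stats.kstest(x, "norm", args=(mu, sd))
    if n_bootstrap > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        exceed = 0
        for _ in range(n_bootstrap):
            sim = gen.normal(mu, sd, size=x.size)
            d_sim, _ = stats.kstest(sim, "norm", args=(sim.mean(), sim.std(ddof=1)))
            exceed += d_sim >= d
        p = (exceed + 1) / (n_bootstrap + 1)
    return KSResult(float(d), float(p), test, n=(int(arr.size),))


def ks_two_sample(a, b, labels: tuple[str, str] = ("a", "b")) -> KSResult:
    """Two-sample KS on log copies (the statistic is transform-invariant)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise InsufficientDataError("two-sample KS needs at least 5 values per group")
    if np.all(a > 0) and np.all(b > 0):
        a, b = np.log(a), np.log(b)
    d, p = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(d), float(p), TWO_SAMPLE, groups=labels, n=(a.size, b.size))


@dataclass
class CellExpressionRecord:
    well_id: str
    gene: str
    condition: str
    cq: float
    copies: float


def log_histogram(copies, bins: int | str = "fd") -> tuple[np.ndarray, np.ndarray]:
    """Histogram of log10 copies with Freedman-Diaconis bin count by default."""
    logs = np.log10(np.asarray(copies, dtype=float))
    counts, edges = np.histogram(logs, bins=bins)
    return edges, counts


@dataclass
class GeneReport:
    gene: str
    geometric_means: dict[str, float]  # condition -> copies
    n_per_condition: dict[str, int]
    pairwise: pd.DataFrame | None  # columns: group_a, group_b, D, p_raw, p_holm, significant
    histograms: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)

    def significant_pairs(self) -> list[tuple[str, str]]:
        if self.pairwise is None:
            return []
        sig = self.pairwise[self.pairwise["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))


@dataclass
class TimecourseReport:
    genes: dict[str, GeneReport]

    def summary(self) -> str:
        lines = []
        for gene, rep in self.genes.items():
            lines.append(f"{gene}:")
            for cond, gm in rep.geometric_means.items():
                lines.append(
                    f"  {cond:>10}  geometric mean {gm:10.2f} copies"
                    f"  (n={rep.n_per_condition[cond]})"
                )
            if rep.pairwise is not None:
                for r in rep.pairwise.itertuples(index=False):
                    mark = "*" if r.significant else " "
                    lines.append(
                        f"  KS {r.group_a} vs {r.group_b}: D={r.D:.3f},"
                        f" p={r.p_raw:.2e} (Holm {r.p_holm:.2e}){mark}"
                    )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {}
        for gene, rep in self.genes.items():
            out[gene] = {
                "geometric_means": rep.geometric_means,
                "n_per_condition": rep.n_per_condition,
                "pairwise": None
                if rep.pairwise is None
                else rep.pairwise.to_dict(orient="records"),
            }
        return out


class ExpressionProfile:
    """Per-well single-cell expression records for several genes/conditions.

    Built from a table with columns ``well_id, gene, condition, cq``; the
    single-copy reference may be one Cq1 for all genes or a per-gene mapping.
    """

    def __init__(self, records: pd.DataFrame, cq1_ref: float | dict[str, float]):
        required = {"gene", "condition", "cq"}
        if not required <= set(records.columns):
            raise FormatError(f"expression table needs columns {sorted(required)}")
        df = records.dropna(subset=["cq"]).copy()
        if isinstance(cq1_ref, dict):
            refs = df["gene"].map(cq1_ref)
            if refs.isna().any():
                raise FormatError("cq1_ref mapping is missing some genes")
        else:
            refs = float(cq1_ref)
        df["copies"] = 2.0 ** (refs - df["cq"])
        self.frame = df
        self.cq1_ref = cq1_ref

    def copies(self, gene: str, condition: str) -> np.ndarray:
        sel = (self.frame["gene"] == gene) & (self.frame["condition"] == condition)
        return self.frame.loc[sel, "copies"].to_numpy()

    def geometric_means(self) -> pd.DataFrame:
        return (
            self.frame.groupby(["gene", "condition"])["copies"]
            .apply(geometric_mean_copies)
            .unstack()
        )

    def normality(self, gene: str, condition: str, family: str = "lognormal") -> KSResult:
        return ks_one_sample(self.copies(gene, condition), family=family)

    def profile_timecourse(
        self,
        alpha: float = 0.05,
        condition_order: list[str] | None = None,
        bins: int | str = "fd",
    ) -> TimecourseReport:
        """Per gene: geometric means, log-binned histograms, and the pairwise
        two-sample KS matrix. Holm correction is applied across the full
        family of comparisons in the report (all genes jointly), so the
        experiment-wide error rate is controlled; raw p-values are kept."""
        reports = {}
        all_rows: list[dict] = []
        for gene, gdf in self.frame.groupby("gene", sort=True):
            conds = [c for c in (condition_order or sorted(gdf["condition"].unique()))
                     if c in set(gdf["condition"])]
            gms, ns, hists = {}, {}, {}
            for cond in conds:
                vals = self.copies(gene, cond)
                gms[cond] = geometric_mean_copies(vals)
                ns[cond] = int(vals.size)
                hists[cond] = log_histogram(vals, bins=bins)
            if len(conds) >= 2:
                for a, b in itertools.combinations(conds, 2):
                    res = ks_two_sample(self.copies(gene, a), self.copies(gene, b), (a, b))
                    all_rows.append({"gene": gene, "group_a": a, "group_b": b,
                                     "D": res.statistic_d, "p_raw": res.p_value})
            reports[gene] = GeneReport(
                gene=gene,
                geometric_means=gms,
                n_per_condition=ns,
                pairwise=None,
                histograms=hists,
            )
        if all_rows:
            table = pd.DataFrame(all_rows)
            reject, p_holm, _, _ = multipletests(table["p_raw"], alpha=alpha, method="holm")
            table["p_holm"] = p_holm
            table["significant"] = reject
            for gene, rep in reports.items():
                sub = table[table["gene"] == gene]
                if not sub.empty:
                    rep.pairwise = sub.drop(columns=["gene"]).reset_index(drop=True)
        return TimecourseReport(genes=reports)


def profile_timecourse(
    records: pd.DataFrame,
    cq1_ref: float | dict[str, float],
    alpha: float = 0.05,
    condition_order: list[str] | None = None,
) -> TimecourseReport:
    """Convenience wrapper building an :class:`ExpressionProfile` and profiling it."""
    return ExpressionProfile(records, cq1_ref).profile_timecourse(
        alpha=alpha, condition_order=condition_order
    )
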