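"""Core data model and I/O for microwell-chip runs and bulk qPCR replicates.

A chip run is a grid of 2,500 independent 20 nL reaction partitions. Each well
either amplified (a quantification cycle, Cq, was recorded), stayed negative,
failed (reagent not introduced, or a bubble), or was marked by the analyst as a
primer-dimer artifact. The :class:`ChipRun` container is the universal input
object for every downstream analysis.

Well tables are plain CSV with columns ``well_id,row,col,cq,status`` (``cq``
empty for no amplification; ``status`` optional). Bulk qPCR replicate tables
use columns ``gene,concentration,replicate,cq``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, InsufficientDataError

POSITIVE = "positive"
NEGATIVE = "negative"
FAIL = "fail"
DIMER = "dimer"
STATUSES = (POSITIVE, NEGATIVE, FAIL, DIMER)

#: Default chip geometry: 2,500 wells on a 50x50 grid.
DEFAULT_N_PARTITIONS = 2500
DEFAULT_GRID = 50
#: Protocol cycle count; a well with no Cq by this cycle is negative.
MAX_CYCLES = 40.0


@dataclass
class WellRecord:
    """State of one partition after a run.

    ``status`` follows the calling rules: a present Cq implies positive unless
    the well is flagged fail (fail wins) or marked as a primer dimer.
    """

    well_id: str
    row: int
    col: int
    cq: float | None = None
    status: str = NEGATIVE
    endpoint_fluorescence: float | None = None

    def validate(self, grid: int = DEFAULT_GRID) -> None:
        if self.status not in STATUSES:
            raise FormatError(f"unknown well status {self.status!r}")
        if self.status == POSITIVE and self.cq is None:
            raise FormatError(f"well {self.well_id}: positive without a Cq")
        if self.status == NEGATIVE and self.cq is not None:
            raise FormatError(f"well {self.well_id}: negative with a Cq")
        if not (0 <= self.row < grid and 0 <= self.col < grid):
            raise FormatError(f"well {self.well_id}: row/col outside {grid}x{grid} grid")


def default_well_id(row: int, col: int) -> str:
    return f"R{row}C{col}"


@dataclass
class RunMetadata:
    gene: str | None = None
    sample_label: str | None = None
    nominal_concentration: float | None = None  # copies/uL
    inhibitor_concentration: float | None = None  # IU/mL, final in-reaction
    is_ntc: bool = False

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "sample_label": self.sample_label,
            "nominal_concentration": self.nominal_concentration,
            "inhibitor_concentration": self.inhibitor_concentration,
            "is_ntc": self.is_ntc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunMetadata":
        return cls(
            gene=d.get("gene"),
            sample_label=d.get("sample_label"),
            nominal_concentration=d.get("nominal_concentration"),
            inhibitor_concentration=d.get("inhibitor_concentration"),
            is_ntc=bool(d.get("is_ntc", False)),
        )


@dataclass(eq=False)
class ChipRun:
    """One 2,500-partition run: the per-well states plus run metadata.

    ``truth`` is populated only by the simulator (per-well molecule counts,
    dimer/fail indices); it is never serialized and never consulted by the
    analysis path.
    """

    wells: list[WellRecord]
    n_partitions: int = DEFAULT_N_PARTITIONS
    metadata: RunMetadata = field(default_factory=RunMetadata)
    n_dimer_expected: float | None = None  # mean NTC false positives
    truth: dict | None = None

    def __post_init__(self) -> None:
        if len(self.wells) != self.n_partitions:
            raise DimensionError(
                f"chip has {len(self.wells)} wells, expected {self.n_partitions}"
            )

    # -- equality on observable content only -------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChipRun):
            return NotImplemented
        return self.n_partitions == other.n_partitions and self.wells == other.wells

    def validate(self, grid: int | None = None) -> None:
        grid = grid if grid is not None else int(math.isqrt(self.n_partitions))
        for w in self.wells:
            w.validate(grid=grid)
        counts = self.status_counts()
        if sum(counts.values()) != self.n_partitions:
            raise DimensionError("status counts do not sum to n_partitions")

    def status_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(STATUSES, 0)
        for w in self.wells:
            counts[w.status] += 1
        return counts

    @property
    def k_positive(self) -> int:
        return sum(1 for w in self.wells if w.status == POSITIVE)

    @property
    def n_fail(self) -> int:
        return sum(1 for w in self.wells if w.status == FAIL)

    @property
    def n_dimer_wells(self) -> int:
        return sum(1 for w in self.wells if w.status == DIMER)

    @property
    def n_negative(self) -> int:
        return sum(1 for w in self.wells if w.status == NEGATIVE)

    def positive_cqs(self) -> np.ndarray:
        """Cq values of positive wells (primer-dimer wells excluded)."""
        return np.array([w.cq for w in self.wells if w.status == POSITIVE], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_id": [w.well_id for w in self.wells],
                "row": [w.row for w in self.wells],
                "col": [w.col for w in self.wells],
                "cq": [w.cq for w in self.wells],
                "status": [w.status for w in self.wells],
            }
        )


@dataclass
class BulkQpcrReplicates:
    """Replicate Cq values of one bulk (non-partitioned) qPCR reaction."""

    gene: str
    template_concentration: float
    cq_values: list[float]

    def validate(self, max_cycles: float = MAX_CYCLES) -> None:
        if len(self.cq_values) < 1:
            raise InsufficientDataError("bulk qPCR needs at least one replicate")
        for cq in self.cq_values:
            if not (0 < cq <= max_cycles):
                raise FormatError(f"Cq {cq} outside (0, {max_cycles}]")


@dataclass
class RunSummary:
    """Counts and Cq precision statistics of one run (or replicate set).

    ``cv_percent`` is 100*sd/mean with the sample (n-1) standard deviation,
    computed over the positive-well Cq values.
    """

    k_positive: int
    n_negative: int
    n_fail: int
    n_dimer: int
    n_dimer_expected: float | None
    mean_cq: float
    sd_cq: float
    cv_percent: float

    @property
    def n_partitions(self) -> int:
        return self.k_positive + self.n_negative + self.n_fail + self.n_dimer


def _cq_stats(cqs: np.ndarray) -> tuple[float, float, float]:
    if cqs.size == 0:
        return (math.nan, math.nan, math.nan)
    mean = float(np.mean(cqs))
    sd = float(np.std(cqs, ddof=1)) if cqs.size > 1 else math.nan
    cv = 100.0 * sd / mean if cqs.size > 1 and mean != 0 else math.nan
    return mean, sd, cv


def summarize_run(run: ChipRun) -> RunSummary:
    """Counts per status and CV of the positive-well Cq values."""
    mean, sd, cv = _cq_stats(run.positive_cqs())
    return RunSummary(
        k_positive=run.k_positive,
        n_negative=run.n_negative,
        n_fail=run.n_fail,
        n_dimer=run.n_dimer_wells,
        n_dimer_expected=run.n_dimer_expected,
        mean_cq=mean,
        sd_cq=sd,
        cv_percent=cv,
    )


def summarize_replicates(reps: BulkQpcrReplicates) -> RunSummary:
    """The analogous summary over a bulk qPCR replicate set."""
    mean, sd, cv = _cq_stats(np.asarray(reps.cq_values, dtype=float))
    return RunSummary(
        k_positive=len(reps.cq_values),
        n_negative=0,
        n_fail=0,
        n_dimer=0,
        n_dimer_expected=None,
        mean_cq=mean,
        sd_cq=sd,
        cv_percent=cv,
    )


def call_wells(
    run: ChipRun,
    max_cq: float = MAX_CYCLES,
    ntc_reference: ChipRun | Sequence[ChipRun] | None = None,
) -> ChipRun:
    """Re-call well statuses from the recorded Cq values.

    A well with a Cq at or below ``max_cq`` is positive; wells flagged fail
    stay fail regardless of any Cq (unfilled/bubbled wells are excluded from
    k); analyst-marked dimer wells keep their mark. When one or more NTC runs
    are supplied, their mean positive count (including dimer-marked wells) is
    stored on the result as ``n_dimer_expected`` — the expected number of
    primer-dimer false positives per chip.
    """
    if max_cq > MAX_CYCLES:
        raise FormatError(f"max_cq {max_cq} exceeds the protocol's {MAX_CYCLES} cycles")
    called = []
    for w in run.wells:
        if w.status in (FAIL, DIMER):
            called.append(WellRecord(w.well_id, w.row, w.col, w.cq, w.status, w.endpoint_fluorescence))
        elif w.cq is not None and w.cq <= max_cq:
            called.append(WellRecord(w.well_id, w.row, w.col, w.cq, POSITIVE, w.endpoint_fluorescence))
        else:
            called.append(WellRecord(w.well_id, w.row, w.col, None, NEGATIVE, w.endpoint_fluorescence))
    n_dimer_expected = run.n_dimer_expected
    if ntc_reference is not None:
        ntcs = [ntc_reference] if isinstance(ntc_reference, ChipRun) else list(ntc_reference)
        n_dimer_expected = float(
            np.mean([ntc.k_positive + ntc.n_dimer_wells for ntc in ntcs])
        )
    return ChipRun(
        wells=called,
        n_partitions=run.n_partitions,
        metadata=run.metadata,
        n_dimer_expected=n_dimer_expected,
        truth=run.truth,
    )


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------

WELL_TABLE_COLUMNS = ("well_id", "row", "col", "cq")


def read_well_table(
    path: str | Path,
    n_partitions: int = DEFAULT_N_PARTITIONS,
    metadata: RunMetadata | None = None,
) -> ChipRun:
    """Read a per-well CSV into a validated :class:`ChipRun`.

    Wells lacking a Cq and not marked fail/dimer become negative; wells with a
    Cq and no explicit status become positive.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in WELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) != n_partitions:
        raise DimensionError(f"{path}: {len(df)} rows, expected {n_partitions}")
    has_status = "status" in df.columns
    wells = []
    for rec in df.itertuples(index=False):
        cq = None if pd.isna(rec.cq) else float(rec.cq)
        status = None
        if has_status and isinstance(rec.status, str) and rec.status.strip():
            status = rec.status.strip()
        if status in (FAIL, DIMER):
            pass  # explicit flags win
        elif cq is not None:
            status = POSITIVE
        else:
            status = NEGATIVE
        if status == NEGATIVE:
            cq = None
        wells.append(WellRecord(str(rec.well_id), int(rec.row), int(rec.col), cq, status))
    run = ChipRun(wells=wells, n_partitions=n_partitions, metadata=metadata or RunMetadata())
    run.validate()
    return run


def write_well_table(run: ChipRun, path: str | Path) -> None:
    """Write a chip run as CSV; round-trips through :func:`read_well_table`."""
    run.to_frame().to_csv(path, index=False)


def write_metadata(metadata: RunMetadata, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metadata.to_dict(), indent=2))


def read_metadata(path: str | Path) -> RunMetadata:
    return RunMetadata.from_dict(json.loads(Path(path).read_text()))


def read_bulk_table(path: str | Path) -> list[BulkQpcrReplicates]:
    """Read a bulk-qPCR CSV (gene,concentration,replicate,cq) into groups."""
    df = pd.read_csv(path)
    missing = [c for c in ("gene", "concentration", "cq") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for (gene, conc), grp in df.groupby(["gene", "concentration"], sort=True):
        reps = BulkQpcrReplicates(
            gene=str(gene),
            template_concentration=float(conc),
            cq_values=[float(v) for v in grp["cq"].dropna()],
        )
        reps.validate()
        out.append(reps)
    return out


def empty_run(
    n_partitions: int = DEFAULT_N_PARTITIONS,
    metadata: RunMetadata | None = None,
) -> ChipRun:
    """An all-negative chip (useful as a starting grid)."""
    grid = int(math.isqrt(n_partitions))
    wells = [
        WellRecord(default_well_id(r, c), r, c, None, NEGATIVE)
        for r in range(grid)
        for c in range(n_partitions // grid)
    ]
    return ChipRun(wells=wells, n_partitions=n_partitions, metadata=metadata or RunMetadata())
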