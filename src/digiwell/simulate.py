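"""Seedable generator of every input the analysis pipeline consumes.

The generator reproduces the statistical structure the analysis assumes for a
2,500-well, 20 nL/well digital real-time PCR chip:

- template molecules are placed multinomially (uniform over wells), so the
  marginal per-well count is Poisson;
- a well with m molecules amplifies to the detection threshold at
  Cq = Cq1 - ln(m)/ln(1+E) plus Gaussian cycle noise, anchored at the
  single-copy Cq1 (default 26.20) and amplification efficiency E (default
  0.8981, i.e. a -3.593 cycles/log10 standard-curve slope);
- wells can fail (unfilled/bubbled) at a configurable rate, and a Poisson
  number of template-free wells per chip turn into primer-dimer false
  positives with late, high-variance Cq (defaults 1.67 wells at 28.80+-5.08,
  the no-template-control signature);
- heparin inhibition splits into per-well complete inhibition (log-logistic
  probability in concentration) plus an efficiency decrement E'(c) applied to
  surviving wells;
- cells load multinomially like molecules, and each single-cell well's
  transcript count per gene is lognormal with per-condition location shifts
  emulating an EMT time course under TGF-beta1.

All randomness flows from one numpy Generator passed explicitly (or a seed).
Simulated ChipRun objects carry a ``truth`` dict (per-well molecule counts,
dimer/fail indices, true totals) that tests may consult but the analysis path
never reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip import (
    DIMER,
    FAIL,
    NEGATIVE,
    POSITIVE,
    BulkQpcrReplicates,
    ChipRun,
    RunMetadata,
    WellRecord,
    default_well_id,
)
from .errors import FormatError
from .occupancy import OccupancyObservation
from .standard_curve import DilutionLevel, DilutionSeries


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class SimulationConfig:
    """Chip and amplification-model parameters (defaults = study conditions)."""

    n_partitions: int = 2500
    well_volume_nl: float = 20.0
    #: Effective template volume per chip in µL; copies/chip = conc * this.
    sample_volume_ul: float = 1.0
    #: Bulk reactions (20 µL) hold 1000x the volume of one 20 nL well, so
    #: their fluorescence threshold sits ln(1000)/ln(1+E) cycles later.
    bulk_threshold_scale: float = 1000.0
    cq1_true: float = 26.20
    efficiency_true: float = 0.8981
    cq_noise_sd: float = 0.4
    fail_rate: float = 0.0
    dimer_rate_mean: float = 1.67  # per chip
    dimer_cq_mean: float = 28.80
    dimer_cq_sd: float = 5.08
    #: Primer dimers form when template does not outcompete the primers;
    #: chips loaded with more than this many copies show none by default.
    dimer_template_max: int = 0
    max_cycles: float = 40.0

    def validate(self) -> None:
        if not (0 <= self.fail_rate <= 1):
            raise FormatError("fail_rate must lie in [0, 1]")
        for name in ("cq_noise_sd", "dimer_cq_sd", "dimer_rate_mean"):
            if getattr(self, name) < 0:
                raise FormatError(f"{name} must be nonnegative")
        if self.efficiency_true <= 0:
            raise FormatError("efficiency must be positive")

    @property
    def grid(self) -> int:
        return int(math.isqrt(self.n_partitions))


DEFAULT_CONFIG = SimulationConfig()


def partition_molecules(
    total_copies: int, n_partitions: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Place each molecule uniformly at random; per-well counts sum exactly."""
    if total_copies < 0:
        raise FormatError("total copies must be nonnegative")
    gen = as_rng(rng)
    return gen.multinomial(int(total_copies), np.full(n_partitions, 1.0 / n_partitions))


def cq_for_molecules(
    m: np.ndarray | float,
    config: SimulationConfig,
    efficiency: float | None = None,
    threshold_scale: float = 1.0,
) -> np.ndarray:
    """Deterministic Cq of a reaction starting from m molecules.

    With the single-copy anchor defining the per-well threshold
    K = (1+E)^Cq1, a reaction at per-cycle efficiency ``efficiency`` (the
    chip's E when None, lower under inhibition) crosses its threshold at
    Cq = (Cq1 ln(1+E) + ln(threshold_scale) - ln m) / ln(1 + efficiency).
    ``threshold_scale`` is the reaction volume relative to one well: a 20 µL
    bulk reaction needs 1000x the amplicons of a 20 nL well to reach the same
    fluorescence concentration.
    """
    e_chip = config.efficiency_true
    eff = e_chip if efficiency is None else efficiency
    log_k = config.cq1_true * math.log1p(e_chip) + math.log(threshold_scale)
    return (log_k - np.log(np.asarray(m, dtype=float))) / math.log1p(eff)


def _assemble_chip(
    counts: np.ndarray,
    cq: np.ndarray,
    positive_mask: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    metadata: RunMetadata | None,
    extra_truth: dict | None = None,
    allow_dimers: bool = True,
) -> ChipRun:
    """Shared assembly: apply fail wells and primer dimers, build WellRecords."""
    n = config.n_partitions
    grid = config.grid
    fail_mask = rng.random(n) < config.fail_rate
    # Primer dimers: template-free, non-failed wells self-amplify late.
    n_dimer = rng.poisson(config.dimer_rate_mean) if allow_dimers else 0
    empty = np.flatnonzero(~positive_mask & ~fail_mask)
    dimer_idx = (
        rng.choice(empty, size=min(n_dimer, empty.size), replace=False)
        if n_dimer > 0 and empty.size > 0
        else np.array([], dtype=int)
    )
    dimer_cq = np.clip(
        rng.normal(config.dimer_cq_mean, config.dimer_cq_sd, size=dimer_idx.size),
        0.1,
        config.max_cycles,
    )
    wells = []
    dimer_pos = dict(zip(dimer_idx.tolist(), dimer_cq.tolist()))
    for i in range(n):
        r, c = divmod(i, grid)
        wid = default_well_id(r, c)
        if fail_mask[i]:
            wells.append(WellRecord(wid, r, c, None, FAIL))
        elif positive_mask[i] and cq[i] <= config.max_cycles:
            wells.append(WellRecord(wid, r, c, float(cq[i]), POSITIVE))
        elif i in dimer_pos:
            # Dimer wells look positive on the instrument; truth records them.
            wells.append(WellRecord(wid, r, c, float(dimer_pos[i]), POSITIVE))
        else:
            wells.append(WellRecord(wid, r, c, None, NEGATIVE))
    truth = {
        "counts": counts,
        "fail_wells": np.flatnonzero(fail_mask),
        "dimer_wells": dimer_idx,
    }
    if extra_truth:
        truth.update(extra_truth)
    return ChipRun(
        wells=wells,
        n_partitions=n,
        metadata=metadata or RunMetadata(),
        truth=truth,
    )


def simulate_chip(
    total_copies: int,
    config: SimulationConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | int | None = None,
    metadata: RunMetadata | None = None,
) -> ChipRun:
    """One chip run: partition molecules, anchor Cq, add noise/fails/dimers."""
    config.validate()
    gen = as_rng(rng)
    counts = partition_molecules(total_copies, config.n_partitions, gen)
    positive = counts >= 1
    cq = np.full(config.n_partitions, np.nan)
    if positive.any():
        base = cq_for_molecules(counts[positive], config)
        cq[positive] = base + gen.normal(0.0, config.cq_noise_sd, size=int(positive.sum()))
    return _assemble_chip(
        counts,
        cq,
        positive,
        config,
        gen,
        metadata,
        {"total_copies": total_copies},
        allow_dimers=total_copies <= config.dimer_template_max,
    )


def simulate_ntc(
    config: SimulationConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | int | None = None,
) -> ChipRun:
    """A no-template control chip; its only positives are primer dimers."""
    return simulate_chip(
        0, config, rng, metadata=RunMetadata(sample_label="NTC", is_ntc=True)
    )


def simulate_bulk_qpcr(
    total_copies: float,
    replicates: int = 3,
    config: SimulationConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | int | None = None,
    gene: str = "target",
    aliquot_sampling: bool = True,
) -> BulkQpcrReplicates:
    """Bulk qPCR replicates: the solution is split into equal aliquots.

    Each replicate's template count is Poisson(total/replicates) — the
    sampling noise that dominates bulk precision at low copy numbers. With
    ``aliquot_sampling=False`` the exact mean is used (noise-free templates),
    which makes a zero-Cq-noise dilution series land exactly on the line
    Cq = Cq1 - log10(m)/log10(1+E). Aliquots that receive zero templates
    yield no Cq and are omitted from the replicate list.
    """
    if replicates < 1:
        raise FormatError("at least one replicate required")
    config.validate()
    gen = as_rng(rng)
    mean = total_copies / replicates
    cqs = []
    for _ in range(replicates):
        m = gen.poisson(mean) if aliquot_sampling else mean
        if m <= 0:
            continue
        cq = float(
            cq_for_molecules(m, config, threshold_scale=config.bulk_threshold_scale)
        ) + (gen.normal(0.0, config.cq_noise_sd) if config.cq_noise_sd > 0 else 0.0)
        if 0 < cq <= config.max_cycles:
            cqs.append(cq)
    return BulkQpcrReplicates(gene=gene, template_concentration=mean, cq_values=cqs)


def simulate_dilution_series(
    concentrations,
    config: SimulationConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | int | None = None,
    chip_replicates: int = 3,
    bulk_replicates: int = 3,
) -> tuple[DilutionSeries, DilutionSeries]:
    """Matched digital and bulk dilution series.

    Per level the expected chip load is concentration * sample_volume_ul
    (the actual load is Poisson-sampled, as pipetting an aliquot is). The
    digital series' level Cq values are the per-chip means of positive-well
    Cq; the bulk series carries replicate reaction Cqs. Returns
    (digital_series, bulk_series).
    """
    if len(concentrations) == 0:
        raise FormatError("need at least one concentration")
    gen = as_rng(rng)
    digital_levels, bulk_levels = [], []
    for conc in concentrations:
        expected = conc * config.sample_volume_ul
        runs, means = [], []
        for _ in range(chip_replicates):
            run = simulate_chip(
                int(gen.poisson(expected)),
                config,
                gen,
                metadata=RunMetadata(nominal_concentration=float(conc)),
            )
            runs.append(run)
            pos = run.positive_cqs()
            if pos.size:
                means.append(float(np.mean(pos)))
        digital_levels.append(DilutionLevel(float(conc), means, runs))
        bulk = simulate_bulk_qpcr(
            expected * bulk_replicates, bulk_replicates, config, gen
        )
        bulk_levels.append(DilutionLevel(float(conc), list(bulk.cq_values)))
    return DilutionSeries(digital_levels), DilutionSeries(bulk_levels)


# ---------------------------------------------------------------------------
# Inhibition
# ---------------------------------------------------------------------------


@dataclass
class InhibitionSimParams:
    """Heparin model: complete per-well kill plus efficiency loss.

    ``ic50_complete`` is the concentration at which half the otherwise
    positive wells are fully inhibited (log-logistic with ``hill_complete``);
    ``eprime_slope`` scales the efficiency decrement
    E'(c) = eprime_slope * log10(1 + c/conc_ref) applied to surviving wells.
    Final in-reaction concentrations (IU/mL) are stock/20.
    """

    ic50_complete: float = 0.02
    hill_complete: float = 1.0
    eprime_slope: float = -0.05
    conc_ref: float = 0.001
    concentrations: tuple[float, ...] = (0.001, 0.01, 0.025, 0.05, 0.25)

    def p_complete(self, concentration: float) -> float:
        if concentration <= 0:
            return 0.0
        return 1.0 / (1.0 + (self.ic50_complete / concentration) ** self.hill_complete)

    def eprime(self, concentration: float, efficiency: float) -> float:
        if concentration <= 0:
            return 0.0
        ep = self.eprime_slope * math.log10(1.0 + concentration / self.conc_ref)
        # keep 1 + E + E' comfortably positive
        return max(ep, -efficiency + 0.05)


def simulate_inhibited_chip(
    concentration: float,
    params: InhibitionSimParams = InhibitionSimParams(),
    config: SimulationConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | int | None = None,
    total_copies: int = 500,
) -> ChipRun:
    """A chip under heparin: wells die completely w.p. p(c); survivors run slow."""
    if concentration < 0:
        raise FormatError("concentration must be nonnegative")
    config.validate()
    gen = as_rng(rng)
    counts = partition_molecules(total_copies, config.n_partitions, gen)
    occupied = counts >= 1
    p_dead = params.p_complete(concentration)
    if p_dead > 0:  # skip the draw at 0 so the RNG stream matches simulate_chip
        dead = occupied & (gen.random(config.n_partitions) < p_dead)
    else:
        dead = np.zeros(config.n_partitions, dtype=bool)
    positive = occupied & ~dead
    eff = config.efficiency_true + params.eprime(concentration, config.efficiency_true)
    cq = np.full(config.n_partitions, np.nan)
    if positive.any():
        base = cq_for_molecules(counts[positive], config, efficiency=eff)
        cq[positive] = base + gen.normal(0.0, config.cq_noise_sd, size=int(positive.sum()))
    meta = RunMetadata(inhibitor_concentration=float(concentration))
    return _assemble_chip(
        counts,
        cq,
        positive,
        config,
        gen,
        meta,
        {
            "total_copies": total_copies,
            "p_complete": p_dead,
            "efficiency_inhibited": eff,
            "completely_inhibited_wells": np.flatnonzero(dead),
        },
        allow_dimers=total_copies <= config.dimer_template_max,
    )


def simulate_inhibited_bulk(
    concentration: float,
    mean_copies: float,
    replicates: int = 3,
    params: InhibitionSimParams = InhibitionSimParams(),
    config: SimulationConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | int | None = None,
) -> BulkQpcrReplicates:
    """Bulk reactions under heparin: the same kill probability acts on every
    template molecule and the whole reaction runs at the reduced efficiency —
    the un-partitioned counterpart of :func:`simulate_inhibited_chip`."""
    gen = as_rng(rng)
    p_dead = params.p_complete(concentration)
    eff = config.efficiency_true + params.eprime(concentration, config.efficiency_true)
    cqs = []
    for _ in range(replicates):
        m = gen.poisson(mean_copies)
        m_live = gen.binomial(m, 1.0 - p_dead) if m > 0 else 0
        if m_live <= 0:
            continue
        cq = float(
            cq_for_molecules(
                m_live,
                config,
                efficiency=eff,
                threshold_scale=config.bulk_threshold_scale,
            )
        ) + gen.normal(0.0, config.cq_noise_sd)
        if 0 < cq <= config.max_cycles:
            cqs.append(cq)
    return BulkQpcrReplicates(
        gene="target", template_concentration=mean_copies, cq_values=cqs
    )


# ---------------------------------------------------------------------------
# Cell loading and EMT expression
# ---------------------------------------------------------------------------


def simulate_cell_loading(
    n_cells: int,
    n_wells: int = 2500,
    rng: np.random.Generator | int | None = None,
    load_jitter: float = 0.0,
) -> tuple[OccupancyObservation, np.ndarray]:
    """Cells settle uniformly at random; returns the occupancy histogram and
    the per-well counts. ``load_jitter`` optionally perturbs the true load by
    a uniform +-fraction (nominal counts are approximate in practice)."""
    if n_cells < 0:
        raise FormatError("cell count must be nonnegative")
    gen = as_rng(rng)
    true_n = n_cells
    if load_jitter > 0:
        true_n = int(round(n_cells * (1.0 + gen.uniform(-load_jitter, load_jitter))))
    counts = partition_molecules(true_n, n_wells, gen)
    occupancies, freq = np.unique(counts, return_counts=True)
    hist = {int(o): int(f) for o, f in zip(occupancies, freq)}
    obs = OccupancyObservation(
        n_input_nominal=float(n_cells), counts_per_occupancy=hist, n_wells=n_wells
    )
    return obs, counts


def _default_gene_programs() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-gene, per-condition lognormal programs (mean, sd of log10 copies).

    N-cadherin rises monotonically through the TGF-beta1 time course,
    vimentin rises then falls, E-cadherin stays flat (the null gene), and
    GAPDH is the stable high-expression housekeeping reference.
    """
    return {
        "E-cadherin": {c: (1.5, 0.45) for c in ("control", "d1", "d2", "d4")},
        "N-cadherin": {
            "control": (0.8, 0.45),
            "d1": (1.2, 0.45),
            "d2": (1.6, 0.45),
            "d4": (2.0, 0.45),
        },
        "vimentin": {
            "control": (1.2, 0.45),
            "d1": (1.8, 0.45),
            "d2": (2.1, 0.45),
            "d4": (1.6, 0.45),
        },
        "GAPDH": {c: (2.5, 0.35) for c in ("control", "d1", "d2", "d4")},
    }


@dataclass
class EmtScenario:
    """TGF-beta1 EMT time-course generator settings."""

    conditions: tuple[str, ...] = ("control", "d1", "d2", "d4")
    genes: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_gene_programs
    )
    n_cells_loaded: int = 500
    cq1_ref: float = 26.20  # GAPDH-anchored single-copy reference

    def validate(self) -> None:
        for gene, prog in self.genes.items():
            for cond in self.conditions:
                if cond not in prog:
                    raise FormatError(f"{gene} missing condition {cond}")
                if prog[cond][1] <= 0:
                    raise FormatError(f"{gene}/{cond}: sd must be positive")

    def true_geometric_mean(self, gene: str, condition: str) -> float:
        return 10.0 ** self.genes[gene][condition][0]

    @classmethod
    def null(cls, n_cells_loaded: int = 500) -> "EmtScenario":
        """All conditions identical for every gene (type-I error checks)."""
        genes = {
            g: {c: prog["control"] for c in ("control", "d1", "d2", "d4")}
            for g, prog in _default_gene_programs().items()
        }
        return cls(genes=genes, n_cells_loaded=n_cells_loaded)


def simulate_emt_experiment(
    scenario: EmtScenario = EmtScenario(),
    config: SimulationConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Single-cell expression records across the EMT time course.

    For each gene x condition a chip is loaded with ~n_cells_loaded cells;
    every occupied well contributes one record with Cq = Cq1 - log2(copies)
    plus cycle noise, where copies sums one lognormal draw per cell in the
    well (multi-cell wells therefore read high; truth flags them). Returns
    (records DataFrame with well_id/gene/condition/cq, truth dict).
    """
    scenario.validate()
    config.validate()
    gen = as_rng(rng)
    rows = []
    truth: dict = {"multiplets": {}, "geometric_means": {}}
    for gene, program in scenario.genes.items():
        for cond in scenario.conditions:
            mu, sd = program[cond]
            _, counts = simulate_cell_loading(scenario.n_cells_loaded, config.n_partitions, gen)
            occupied = np.flatnonzero(counts)
            multi = []
            for idx in occupied:
                c = int(counts[idx])
                copies = float(np.sum(10.0 ** gen.normal(mu, sd, size=c)))
                cq = scenario.cq1_ref - math.log2(copies) + gen.normal(0.0, config.cq_noise_sd)
                r, ccol = divmod(int(idx), config.grid)
                rows.append(
                    {
                        "well_id": default_well_id(r, ccol),
                        "gene": gene,
                        "condition": cond,
                        "cq": cq,
                        "n_cells": c,
                    }
                )
                if c > 1:
                    multi.append(default_well_id(r, ccol))
            truth["multiplets"][(gene, cond)] = multi
            truth["geometric_means"][(gene, cond)] = scenario.true_geometric_mean(gene, cond)
    return pd.DataFrame(rows), truth
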