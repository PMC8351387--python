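"""The in-silico invasion experiment over the mixing x secretion-fold grid.

Runs replicated 25-transfer serial-dilution simulations seeded with a
single over-secreting mutant, scores invasion (the mutant still present
after the final transfer's dilution) and the final mutant fraction, and
summarizes each (mixing, fold) grid cell the way the study's figure does:
invasion percentage, plus mean/SD/min/max of the mutant fraction over
successful invasions only, with the SD suppressed when fewer than three
invasions support it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .abm import (
    PopulationRecord,
    SimConfig,
    WorldState,
    apply_transfer,
    init_world,
    run_transfer_cycle,
)

__all__ = [
    "ReplicateOutcome",
    "SummaryCell",
    "run_replicate",
    "run_replicates",
    "summarize",
    "fisher_invasion_test",
    "sweep",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = ["mixing", "fold", "n", "invasion_percent", "frac_mean",
                   "frac_sd", "frac_min", "frac_max", "n_collapsed"]


@dataclass(frozen=True)
class ReplicateOutcome:
    """One replicate of the serial-transfer experiment."""

    mixing: float
    fold: float
    seed: int
    invaded: bool
    final_mutant_fraction: float  # NaN unless invaded
    collapsed: bool               # extinction or timeout before the last transfer
    records: tuple[PopulationRecord, ...] = ()


@dataclass(frozen=True)
class SummaryCell:
    """Summary statistics of one (mixing, fold) grid cell."""

    mixing: float
    fold: float
    n_replicates: int
    invasion_percent: float
    fraction_mean: float
    fraction_sd: float   # NaN when fewer than 3 invasions
    fraction_min: float  # NaN when no invasions
    fraction_max: float
    n_collapsed: int


def run_replicate(config: SimConfig, seed: int,
                  collect_records: bool = False) -> ReplicateOutcome:
    """One full n_transfers serial-transfer run from a single seed.

    Invasion is evaluated on the population immediately after the final
    transfer's dilution. A run that goes extinct or times out earlier is
    recorded as collapsed and counts as not invaded.
    """
    rng = np.random.default_rng(seed)
    world = init_world(config, rng)
    records: list[PopulationRecord] = []
    for transfer in range(config.n_transfers):
        world, recs, outcome = run_transfer_cycle(
            world, config, rng, transfer_index=transfer,
            collect_records=collect_records)
        if collect_records:
            records.extend(recs)
        if outcome != "reached_threshold":
            return ReplicateOutcome(
                config.mixing, config.mutant_secretion_fold, seed,
                invaded=False, final_mutant_fraction=float("nan"),
                collapsed=True, records=tuple(records))
        world = apply_transfer(world, config, rng)
    _, n_wt, n_mut = world.counts()
    invaded = n_mut > 0
    frac = n_mut / (n_mut + n_wt) if invaded and (n_mut + n_wt) else float("nan")
    return ReplicateOutcome(
        config.mixing, config.mutant_secretion_fold, seed,
        invaded=invaded, final_mutant_fraction=frac,
        collapsed=False, records=tuple(records))


def run_replicates(config: SimConfig, n_replicates: int, base_seed: int,
                   collect_records: bool = False) -> list[ReplicateOutcome]:
    """Replicate i runs with seed ``base_seed + i``; order-stable."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [run_replicate(dc_replace(config, rng_seed=base_seed + i),
                          base_seed + i, collect_records)
            for i in range(n_replicates)]


def summarize(outcomes) -> SummaryCell:
    """Figure-convention summary of one grid cell's outcomes.

    Fraction statistics are computed over invaded replicates only; a mean
    of zero denotes no successful invasion; the SD is reported only when
    more than two invasions support it.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("summarize needs at least one outcome")
    keys = {(o.mixing, o.fold) for o in outcomes}
    if len(keys) > 1:
        raise ValueError(f"outcomes mix grid cells: {sorted(keys)}")
    mixing, fold = keys.pop()
    n = len(outcomes)
    fracs = np.array([o.final_mutant_fraction for o in outcomes if o.invaded])
    k = fracs.size
    nan = float("nan")
    return SummaryCell(
        mixing=mixing, fold=fold, n_replicates=n,
        invasion_percent=100.0 * k / n,
        fraction_mean=float(fracs.mean()) if k else 0.0,
        fraction_sd=float(fracs.std(ddof=1)) if k >= 3 else nan,
        fraction_min=float(fracs.min()) if k else nan,
        fraction_max=float(fracs.max()) if k else nan,
        n_collapsed=sum(o.collapsed for o in outcomes),
    )


def fisher_invasion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for a difference in invasion frequency.

    Sums hypergeometric probabilities no larger than that of the observed
    2x2 table at fixed margins.
    """
    for v in (k1, n1, k2, n2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if k1 > n1 or k2 > n2:
        raise ValueError("successes cannot exceed trials")
    _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]],
                              alternative="two-sided")
    return float(p)


def _cell_seed_block(base_seed: int, mixing: float, fold: float) -> int:
    """Disjoint, grid-composition-independent seed block per cell."""
    return int(base_seed + (round(mixing * 10) * 41 + round(fold * 10)) * 100_000)


def sweep(
    base_config: SimConfig,
    mixing_values=None,
    folds=(1.0, 1.5, 2.0, 3.0),
    n_replicates: int = 200,
    base_seed: int = 0,
    outdir=None,
) -> pd.DataFrame:
    """The full invasion sweep: one summary row per (mixing, fold) cell.

    Seed blocks are disjoint per cell and independent of which other cells
    are in the grid, so enlarging the sweep never perturbs existing cells.
    If ``outdir`` is given, writes ``summary.csv`` there.
    """
    if mixing_values is None:
        mixing_values = np.round(np.arange(0.0, 1.01, 0.1), 1)
    rows = []
    for mixing in mixing_values:
        for fold in folds:
            cfg = dc_replace(base_config, mixing=float(mixing),
                             mutant_secretion_fold=float(fold))
            outs = run_replicates(
                cfg, n_replicates, _cell_seed_block(base_seed, mixing, fold))
            c = summarize(outs)
            rows.append((c.mixing, c.fold, c.n_replicates, c.invasion_percent,
                         c.fraction_mean, c.fraction_sd, c.fraction_min,
                         c.fraction_max, c.n_collapsed))
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "summary.csv", index=False)
    return df
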