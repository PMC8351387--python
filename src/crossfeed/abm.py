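"""Agent-based model of an obligate cross-feeding community under serial transfer.

A 32 x 32 toroidal patch grid holds two diffusible metabolite pools:
amino acids (secreted by yeast, consumed by bacteria) and a vitamin
(secreted by bacteria, consumed by yeast). Agents carry an energy store;
secretion costs energy, consumption replenishes it, reaching a threshold
triggers division, and hitting zero kills. A mutant bacterial strain
secretes ``mutant_secretion_fold`` times more vitamin per tick, paying
proportionally more — the fitness-costly over-secretion phenotype whose
invasion is the object of study.

Each tick applies, in fixed order: mixing movement, secretion, diffusion,
consumption (agents drain their own patch in a freshly shuffled order),
death, division. A transfer cycle ticks until the census reaches the
inoculum size times 2**doublings, then dilutes back to the inoculum size
into an empty world.

The per-tick update is compiled with numba; all randomness flows from a
caller-supplied numpy Generator (the kernel is re-seeded from it each
tick), so runs are reproducible from a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "SpeciesParams",
    "SimConfig",
    "WorldState",
    "Agent",
    "PopulationRecord",
    "ConfigError",
    "init_world",
    "diffuse",
    "tick",
    "run_transfer_cycle",
    "apply_transfer",
    "records_to_dataframe",
    "RECORD_COLUMNS",
]

YEAST, BACTERIUM = 0, 1
WILD, MUTANT = 0, 1

RECORD_COLUMNS = ["transfer", "tick", "n_yeast", "n_wt", "n_mutant",
                  "total_aa", "total_vit"]


class ConfigError(ValueError):
    """A SimConfig invariant is violated; the message names it."""


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species metabolic exchange parameters.

    uptake_max: cap on metabolite units consumable per tick from the own
        patch; infinite by default — consumption is limited by what the
        patch holds, the way patch-grid agents typically harvest, so a
        metabolite surplus is stored in the patch rather than discarded.
    secretion_rate: metabolite units deposited on the own patch per tick.
    secretion_cost: energy paid per secreted unit.
    conversion_efficiency: energy gained per consumed unit.
    """

    uptake_max: float = float("inf")
    secretion_rate: float = 1.0
    secretion_cost: float = 0.1
    conversion_efficiency: float = 1.1

    def net_gain(self, intake: float) -> float:
        """Energy balance per tick at a given metabolite intake."""
        return (self.conversion_efficiency * min(intake, self.uptake_max)
                - self.secretion_cost * self.secretion_rate)


def _default_yeast() -> SpeciesParams:
    return SpeciesParams(secretion_rate=4.0, secretion_cost=0.025,
                         conversion_efficiency=0.3)


def _default_bacteria() -> SpeciesParams:
    return SpeciesParams(secretion_rate=0.5, secretion_cost=0.2,
                         conversion_efficiency=2.2)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the serial-transfer simulation.

    Defaults follow the calibration constraints of the study design: a net
    gain of one energy unit per agent per tick at optimal conditions for
    both wild types, yeast secretion sized so one yeast supports about
    eight bacteria, and equal division thresholds for the two species.
    Deviations from those constraints are warned about, not rejected.
    """

    grid_width: int = 32
    grid_height: int = 32
    mixing: float = 0.0
    diffusion_rate: float = 0.6
    init_yeast: int = 10
    init_wt_bacteria: int = 79
    init_mutant_bacteria: int = 1
    doublings_per_transfer: int = 5
    n_transfers: int = 25
    energy_init: float = 10.0
    division_threshold: float = 40.0
    yeast: SpeciesParams = field(default_factory=_default_yeast)
    bacteria: SpeciesParams = field(default_factory=_default_bacteria)
    mutant_secretion_fold: float = 2.0
    max_ticks_per_transfer: int = 2000
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    @property
    def init_total(self) -> int:
        return self.init_yeast + self.init_wt_bacteria + self.init_mutant_bacteria

    @property
    def transfer_threshold(self) -> int:
        """Census that triggers a transfer: inoculum x 2**doublings."""
        return self.init_total * 2 ** self.doublings_per_transfer

    @property
    def n_patches(self) -> int:
        return self.grid_width * self.grid_height

    def validate(self) -> None:
        def err(msg):
            raise ConfigError(msg)

        if not 0.0 <= self.mixing <= 1.0:
            err(f"mixing must lie in [0, 1], got {self.mixing}")
        if not 0.0 <= self.diffusion_rate <= 1.0:
            err(f"diffusion_rate must lie in [0, 1], got {self.diffusion_rate}")
        if self.grid_width < 1 or self.grid_height < 1:
            err("grid dimensions must be >= 1")
        for name in ("init_yeast", "init_wt_bacteria", "init_mutant_bacteria",
                     "doublings_per_transfer", "n_transfers",
                     "max_ticks_per_transfer"):
            if getattr(self, name) < 0:
                err(f"{name} must be non-negative")
        if self.init_total < 1:
            err("at least one initial agent is required")
        for sp_name, sp in (("yeast", self.yeast), ("bacteria", self.bacteria)):
            for f in ("uptake_max", "secretion_rate", "secretion_cost",
                      "conversion_efficiency"):
                if getattr(sp, f) < 0:
                    err(f"{sp_name}.{f} must be non-negative")
        if self.mutant_secretion_fold < 0:
            err("mutant_secretion_fold must be non-negative")
        if not self.division_threshold > self.energy_init > 0:
            err("division_threshold > energy_init > 0 is required")
        # calibration checks from the study design: warn, not reject.
        # "Optimal growth conditions" means the community steady state of
        # one yeast cross-feeding with its cohort of about eight
        # bacteria. On the amino-acid side this pins yeast secretion to
        # exactly eight bacterial shares; on the vitamin side the
        # bacterial cohort whose combined secretion gives a yeast a net
        # gain of +1 must be about eight cells.
        bact_share = self.yeast.secretion_rate / 8.0
        gain = self.bacteria.net_gain(bact_share)
        if abs(gain - 1.0) > 1e-9:
            warnings.warn(
                f"bacterial net optimal energy gain is {gain:g}, not 1 "
                "(calibration convention)", stacklevel=3)
        cohort = self.yeast_supporting_cohort()
        if not 6.0 <= cohort <= 10.0:
            warnings.warn(
                f"a yeast needs {cohort:.2f} wild-type bacteria for a net "
                "energy gain of 1; calibration convention is around 8",
                stacklevel=3)
        if abs(self.yeast.secretion_rate
               - 8.0 * self.bacteria.secretion_rate) > 1e-9:
            warnings.warn(
                "yeast secretion_rate != 8 x bacterial secretion_rate "
                "(one yeast supports ~8 bacteria)", stacklevel=3)

    def yeast_supporting_cohort(self) -> float:
        """Number of wild-type bacteria whose combined secretion gives one
        yeast a net energy gain of exactly +1 per tick."""
        y = self.yeast
        burn = y.secretion_cost * y.secretion_rate
        marginal = y.conversion_efficiency * self.bacteria.secretion_rate
        return (1.0 + burn) / marginal if marginal > 0 else float("inf")


@dataclass(frozen=True)
class Agent:
    """One cell: species, strain (meaningful for bacteria), energy, patch."""

    species: int
    strain: int
    energy: float
    position: tuple[int, int]


@dataclass
class WorldState:
    """Patch pools plus flat agent arrays; topology is always toroidal."""

    amino_acid: np.ndarray          # (H, W) non-negative
    vitamin: np.ndarray             # (H, W) non-negative
    species: np.ndarray             # (n,) int8, YEAST or BACTERIUM
    strain: np.ndarray              # (n,) int8, WILD or MUTANT
    energy: np.ndarray              # (n,) float
    position: np.ndarray            # (n,) flat patch index
    tick: int = 0
    torus: bool = True

    @property
    def n_agents(self) -> int:
        return int(self.species.size)

    def counts(self) -> tuple[int, int, int]:
        """(n_yeast, n_wild_bacteria, n_mutant_bacteria)."""
        yeast = int(np.sum(self.species == YEAST))
        mut = int(np.sum((self.species == BACTERIUM) & (self.strain == MUTANT)))
        wt = int(np.sum(self.species == BACTERIUM)) - mut
        return yeast, wt, mut

    def agents(self) -> list[Agent]:
        w = self.amino_acid.shape[1]
        return [
            Agent(int(s), int(st), float(e), (int(p) // w, int(p) % w))
            for s, st, e, p in zip(self.species, self.strain, self.energy,
                                   self.position)
        ]

    def copy(self) -> "WorldState":
        return WorldState(
            self.amino_acid.copy(), self.vitamin.copy(), self.species.copy(),
            self.strain.copy(), self.energy.copy(), self.position.copy(),
            self.tick, self.torus,
        )


@dataclass(frozen=True)
class PopulationRecord:
    transfer_index: int
    tick: int
    n_yeast: int
    n_wt: int
    n_mutant: int
    total_amino_acid: float
    total_vitamin: float


def records_to_dataframe(records):
    """Tidy per-tick population dynamics with the canonical CSV header."""
    import pandas as pd

    return pd.DataFrame(
        [(r.transfer_index, r.tick, r.n_yeast, r.n_wt, r.n_mutant,
          r.total_amino_acid, r.total_vitamin) for r in records],
        columns=RECORD_COLUMNS,
    )


# ---------------------------------------------------------------------------
# compiled kernels

@njit(cache=True)
def _diffuse_kernel(grid, out, rate, H, W):
    sh = rate / 8.0
    for r in range(H):
        rm = (r - 1) % H
        rp = (r + 1) % H
        for c in range(W):
            cm = (c - 1) % W
            cp = (c + 1) % W
            out[r, c] = (1.0 - rate) * grid[r, c] + sh * (
                grid[rm, cm] + grid[rm, c] + grid[rm, cp]
                + grid[r, cm] + grid[r, cp]
                + grid[rp, cm] + grid[rp, c] + grid[rp, cp])


@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _tick_kernel(species, strain, energy, pos, n,
                 aa, vit, aa2, vit2, H, W,
                 mixing, diffusion_rate, fold,
                 u_y, s_y, e_y, c_y, u_b, s_b, e_b, c_b,
                 thresh):
    """One world tick in place on capacity arrays, consuming the shared
    compiled-side RNG stream (seed via :func:`_seed_kernel`).

    Returns (new count, secreted aa, secreted vitamin, consumed aa,
    consumed vitamin) for metabolite/energy bookkeeping.
    """
    npatch = H * W
    # 1. mixing: independent teleport to a uniform patch
    if mixing > 0.0:
        for i in range(n):
            if np.random.random() < mixing:
                pos[i] = np.random.randint(0, npatch)
    # 2. secretion (unconditional; the cost is paid even into death)
    sec_aa = 0.0
    sec_vit = 0.0
    for i in range(n):
        p = pos[i]
        if species[i] == 0:
            aa[p // W, p % W] += s_y
            energy[i] -= c_y * s_y
            sec_aa += s_y
        else:
            amt = s_b * fold if strain[i] == 1 else s_b
            vit[p // W, p % W] += amt
            energy[i] -= c_b * amt
            sec_vit += amt
    # 3. diffusion of both pools
    _diffuse_kernel(aa, aa2, diffusion_rate, H, W)
    _diffuse_kernel(vit, vit2, diffusion_rate, H, W)
    aa[:, :] = aa2
    vit[:, :] = vit2
    # 4. consumption in a freshly shuffled order, each agent draining its
    #    own patch up to its species cap
    cons_aa = 0.0
    cons_vit = 0.0
    perm = np.random.permutation(n)
    for j in range(n):
        i = perm[j]
        p = pos[i]
        r = p // W
        c = p % W
        if species[i] == 0:
            take = min(u_y, vit[r, c])
            vit[r, c] -= take
            energy[i] += e_y * take
            cons_vit += take
        else:
            take = min(u_b, aa[r, c])
            aa[r, c] -= take
            energy[i] += e_b * take
            cons_aa += take
    # 5. death strictly at energy <= 0 (before division: a cell cannot
    #    both die and divide in one tick)
    m = 0
    for i in range(n):
        if energy[i] > 0.0:
            species[m] = species[i]
            strain[m] = strain[i]
            energy[m] = energy[i]
            pos[m] = pos[i]
            m += 1
    n = m
    # 6. division: daughters share the parent's energy, same patch
    n0 = n
    for i in range(n0):
        if energy[i] >= thresh:
            energy[i] *= 0.5
            species[n] = species[i]
            strain[n] = strain[i]
            energy[n] = energy[i]
            pos[n] = pos[i]
            n += 1
    return n, sec_aa, sec_vit, cons_aa, cons_vit


@njit(cache=True)
def _transfer_kernel(species, strain, energy, pos, n,
                     aa, vit, aa2, vit2, H, W,
                     mixing, diffusion_rate, fold,
                     u_y, s_y, e_y, c_y, u_b, s_b, e_b, c_b,
                     thresh, threshold_count, max_ticks):
    """A whole stationary-growth phase in one compiled loop; identical
    tick semantics and RNG stream as repeated :func:`_tick_kernel` calls.

    Returns (count, ticks executed, outcome code 0/1/2 for
    reached/extinct/timed out).
    """
    ticks = 0
    while True:
        if n == 0:
            return n, ticks, 1
        if n >= threshold_count:
            return n, ticks, 0
        if ticks >= max_ticks:
            return n, ticks, 2
        n, _, _, _, _ = _tick_kernel(
            species, strain, energy, pos, n, aa, vit, aa2, vit2, H, W,
            mixing, diffusion_rate, fold,
            u_y, s_y, e_y, c_y, u_b, s_b, e_b, c_b, thresh)
        ticks += 1


def _draw_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# public operations

def init_world(config: SimConfig, rng: np.random.Generator) -> WorldState:
    """A fresh, metabolite-free world with the configured inoculum.

    Agents are placed uniformly at random, all at ``energy_init``; yeast
    first, then wild bacteria, then mutants.
    """
    config.validate()
    H, W = config.grid_height, config.grid_width
    n = config.init_total
    species = np.concatenate([
        np.full(config.init_yeast, YEAST, np.int8),
        np.full(config.init_wt_bacteria + config.init_mutant_bacteria,
                BACTERIUM, np.int8),
    ])
    strain = np.concatenate([
        np.full(config.init_yeast + config.init_wt_bacteria, WILD, np.int8),
        np.full(config.init_mutant_bacteria, MUTANT, np.int8),
    ])
    return WorldState(
        amino_acid=np.zeros((H, W)),
        vitamin=np.zeros((H, W)),
        species=species,
        strain=strain,
        energy=np.full(n, float(config.energy_init)),
        position=rng.integers(0, H * W, n),
        tick=0,
    )


def diffuse(grid: np.ndarray, rate: float) -> np.ndarray:
    """One step of 8-neighbour toroidal diffusion.

    Each patch keeps ``1 - rate`` of its content and sends ``rate/8`` to
    each Moore neighbour; the total amount is conserved exactly (up to
    floating-point roundoff).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    g = np.asarray(grid, dtype=float)
    if g.ndim != 2:
        raise ValueError("grid must be 2-D")
    if np.any(g < 0):
        raise ValueError("grid must be non-negative")
    out = np.empty_like(g)
    _diffuse_kernel(g, out, float(rate), g.shape[0], g.shape[1])
    return out


def _capacity_arrays(world: WorldState, capacity: int):
    n = world.n_agents
    sp = np.empty(capacity, np.int8)
    st = np.empty(capacity, np.int8)
    en = np.empty(capacity, np.float64)
    po = np.empty(capacity, np.int64)
    sp[:n] = world.species
    st[:n] = world.strain
    en[:n] = world.energy
    po[:n] = world.position
    return sp, st, en, po


def _kernel_args(config: SimConfig):
    y, b = config.yeast, config.bacteria
    return (config.mixing, config.diffusion_rate,
            config.mutant_secretion_fold,
            y.uptake_max, y.secretion_rate, y.conversion_efficiency,
            y.secretion_cost, b.uptake_max, b.secretion_rate,
            b.conversion_efficiency, b.secretion_cost,
            config.division_threshold)


def tick(world: WorldState, config: SimConfig,
         rng: np.random.Generator) -> WorldState:
    """Apply one full update (move, secrete, diffuse, consume, die,
    divide) and return the successor world.

    Consumes one sub-seed from ``rng``, so repeated calls advance the
    stream deterministically.
    """
    new_world, _ = tick_with_stats(world, config, rng)
    return new_world


def tick_with_stats(world: WorldState, config: SimConfig,
                    rng: np.random.Generator):
    """Like :func:`tick`, additionally returning the tick's metabolite
    bookkeeping: a dict with secreted/consumed totals for both pools."""
    H, W = world.amino_acid.shape
    cap = 2 * world.n_agents + 16
    sp, st, en, po = _capacity_arrays(world, cap)
    aa = world.amino_acid.copy()
    vit = world.vitamin.copy()
    aa2 = np.empty_like(aa)
    vit2 = np.empty_like(vit)
    _seed_kernel(_draw_seed(rng))
    n, sec_aa, sec_vit, cons_aa, cons_vit = _tick_kernel(
        sp, st, en, po, world.n_agents,
        aa, vit, aa2, vit2, H, W, *_kernel_args(config))
    stats = {"secreted_aa": sec_aa, "secreted_vit": sec_vit,
             "consumed_aa": cons_aa, "consumed_vit": cons_vit}
    return WorldState(aa, vit, sp[:n].copy(), st[:n].copy(), en[:n].copy(),
                      po[:n].copy(), world.tick + 1, world.torus), stats


def run_transfer_cycle(world: WorldState, config: SimConfig,
                       rng: np.random.Generator,
                       transfer_index: int = 0,
                       collect_records: bool = True):
    """Tick the world until the transfer-triggering census is reached.

    Returns ``(world, records, outcome)`` with outcome one of
    ``"reached_threshold"``, ``"extinct"`` or ``"timed_out"``. One
    PopulationRecord is appended per executed tick (skipped entirely when
    ``collect_records`` is false, for bulk experiment runs).
    """
    H, W = world.amino_acid.shape
    cap = 2 * config.transfer_threshold + 16
    sp, st, en, po = _capacity_arrays(world, cap)
    n = world.n_agents
    aa = world.amino_acid.copy()
    vit = world.vitamin.copy()
    aa2 = np.empty_like(aa)
    vit2 = np.empty_like(vit)
    args = _kernel_args(config)
    records: list[PopulationRecord] = []
    t = world.tick
    _seed_kernel(_draw_seed(rng))
    if not collect_records:
        n, ticks, code = _transfer_kernel(
            sp, st, en, po, n, aa, vit, aa2, vit2, H, W, *args,
            config.transfer_threshold, config.max_ticks_per_transfer)
        t += ticks
        outcome = ("reached_threshold", "extinct", "timed_out")[code]
    else:
        ticks_done = 0
        outcome = None
        while True:
            if n == 0:
                outcome = "extinct"
                break
            if n >= config.transfer_threshold:
                outcome = "reached_threshold"
                break
            if ticks_done >= config.max_ticks_per_transfer:
                outcome = "timed_out"
                break
            n, *_ = _tick_kernel(sp, st, en, po, n,
                                 aa, vit, aa2, vit2, H, W, *args)
            t += 1
            ticks_done += 1
            ny = int(np.sum(sp[:n] == YEAST))
            nm = int(np.sum((sp[:n] == BACTERIUM) & (st[:n] == MUTANT)))
            records.append(PopulationRecord(
                transfer_index, t, ny, n - ny - nm, nm,
                float(aa.sum()), float(vit.sum())))
    out = WorldState(aa, vit, sp[:n].copy(), st[:n].copy(), en[:n].copy(),
                     po[:n].copy(), t, world.torus)
    return out, records, outcome


def apply_transfer(world: WorldState, config: SimConfig,
                   rng: np.random.Generator) -> WorldState:
    """Dilute into a fresh world: sample ``init_total`` agents uniformly
    without replacement (all are kept if fewer exist), reset both patch
    pools to zero, re-randomize positions, keep energies."""
    n = world.n_agents
    if n == 0:
        raise ValueError("cannot transfer from an empty world")
    k = min(config.init_total, n)
    sel = rng.choice(n, size=k, replace=False)
    H, W = world.amino_acid.shape
    return WorldState(
        amino_acid=np.zeros((H, W)),
        vitamin=np.zeros((H, W)),
        species=world.species[sel].copy(),
        strain=world.strain[sel].copy(),
        energy=world.energy[sel].copy(),
        position=rng.integers(0, H * W, k),
        tick=world.tick,
        torus=world.torus,
    )
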