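"""Mechanics of the agent-based world: construction, diffusion stencil,
tick economics, death/division rules, transfers, and the conservation
invariants that make the model auditable."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from crossfeed.abm import (
    BACTERIUM,
    MUTANT,
    WILD,
    YEAST,
    ConfigError,
    SimConfig,
    SpeciesParams,
    WorldState,
    apply_transfer,
    diffuse,
    init_world,
    run_transfer_cycle,
    tick,
    tick_with_stats,
)


def world_with(config, agents, aa=None, vit=None):
    """Hand-built world: agents = list of (species, strain, energy, flatpos)."""
    H, W = config.grid_height, config.grid_width
    sp = np.array([a[0] for a in agents], np.int8)
    st_ = np.array([a[1] for a in agents], np.int8)
    en = np.array([a[2] for a in agents], float)
    po = np.array([a[3] for a in agents], np.int64)
    return WorldState(
        amino_acid=np.full((H, W), 0.0) if aa is None else aa,
        vitamin=np.full((H, W), 0.0) if vit is None else vit,
        species=sp, strain=st_, energy=en, position=po)


class TestConfig:
    def test_defaults_satisfy_calibration(self, recwarn):
        cfg = SimConfig()
        # a bacterium eating its one-eighth share of a yeast's secretion
        # nets exactly +1 energy per tick
        assert cfg.bacteria.net_gain(cfg.yeast.secretion_rate / 8) == \
            pytest.approx(1.0)
        # a yeast reaches its +1 net gain with a cohort of around eight
        # wild-type bacteria
        cohort = cfg.yeast_supporting_cohort()
        assert 6.0 <= cohort <= 10.0
        assert cfg.yeast.net_gain(cohort * cfg.bacteria.secretion_rate) == \
            pytest.approx(1.0)
        assert cfg.yeast.secretion_rate == 8 * cfg.bacteria.secretion_rate
        assert not recwarn.list  # no calibration warnings on the defaults

    @pytest.mark.parametrize("kwargs, fragment", [
        (dict(mixing=1.5), "mixing"),
        (dict(diffusion_rate=-0.1), "diffusion_rate"),
        (dict(init_yeast=-1), "init_yeast"),
        (dict(energy_init=30.0, division_threshold=20.0), "division_threshold"),
        (dict(energy_init=0.0), "division_threshold"),
    ])
    def test_invariant_violations_named(self, kwargs, fragment):
        with pytest.raises(ConfigError, match=fragment):
            SimConfig(**kwargs)

    def test_off_calibration_warns_but_builds(self):
        with pytest.warns(UserWarning, match="net optimal"):
            SimConfig(bacteria=SpeciesParams(
                secretion_rate=1.0, secretion_cost=0.5,
                conversion_efficiency=1.25))

    def test_transfer_threshold_arithmetic(self):
        # 90 initial agents and five doublings: dilution at 2,880 agents
        cfg = SimConfig()
        assert cfg.init_total == 90
        assert cfg.transfer_threshold == 2880


class TestInitWorld:
    def test_counts_energies_and_empty_pools(self, rng):
        cfg = SimConfig(init_yeast=10, init_wt_bacteria=79,
                        init_mutant_bacteria=1)
        w = init_world(cfg, rng)
        assert w.n_agents == 90
        assert w.counts() == (10, 79, 1)
        assert np.all(w.energy == cfg.energy_init)
        assert w.amino_acid.sum() == 0.0 and w.vitamin.sum() == 0.0
        assert w.tick == 0

    def test_no_mutants_case(self, rng):
        cfg = SimConfig(init_mutant_bacteria=0)
        w = init_world(cfg, rng)
        assert w.counts()[2] == 0

    def test_same_seed_same_positions(self):
        cfg = SimConfig()
        w1 = init_world(cfg, np.random.default_rng(7))
        w2 = init_world(cfg, np.random.default_rng(7))
        assert np.array_equal(w1.position, w2.position)


class TestDiffuse:
    def test_rate_zero_identity(self, rng):
        g = rng.random((5, 7))
        assert np.array_equal(diffuse(g, 0.0), g)

    def test_single_source_stencil(self):
        # one patch holding 8.0 at rate 0.5: keeps 4.0, each Moore
        # neighbour receives 0.5
        g = np.zeros((3, 3))
        g[1, 1] = 8.0
        out = diffuse(g, 0.5)
        assert out[1, 1] == pytest.approx(4.0)
        off = [(r, c) for r in range(3) for c in range(3) if (r, c) != (1, 1)]
        for r, c in off:
            assert out[r, c] == pytest.approx(0.5)

    def test_wraps_around_torus(self):
        g = np.zeros((4, 4))
        g[0, 0] = 1.0
        out = diffuse(g, 1.0)
        assert out[3, 3] == pytest.approx(1.0 / 8)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffuse(np.ones((3, 3)), 1.2)

    @settings(max_examples=40, deadline=None)
    @given(
        hnp.arrays(float, (6, 6), elements=st.floats(0, 1e6)),
        st.floats(0.0, 1.0),
    )
    def test_mass_conserved(self, g, rate):
        out = diffuse(g, rate)
        assert out.sum() == pytest.approx(g.sum(), rel=1e-9, abs=1e-9)
        assert np.all(out >= -1e-12)


class TestTickEconomics:
    def test_wild_bacterium_at_share_intake_nets_exactly_one(self, rng):
        """The calibration contract: +1 energy per tick under optimal
        conditions, i.e. eating the one-eighth share of a yeast's output.
        A uniform amino-acid field at the share value survives diffusion
        unchanged, so the intake is exactly the share."""
        cfg = SimConfig()
        share = cfg.yeast.secretion_rate / 8
        w = world_with(cfg, [(BACTERIUM, WILD, 10.0, 5)],
                       aa=np.full((32, 32), share))
        w2 = tick(w, cfg, rng)
        assert w2.energy[0] == pytest.approx(11.0)

    def test_yeast_at_cohort_intake_nets_exactly_one(self, rng):
        cfg = SimConfig()
        intake = cfg.yeast_supporting_cohort() * cfg.bacteria.secretion_rate
        w = world_with(cfg, [(YEAST, WILD, 10.0, 5)],
                       vit=np.full((32, 32), intake))
        w2 = tick(w, cfg, rng)
        assert w2.energy[0] == pytest.approx(11.0)

    def test_mutant_pays_fold_scaled_cost(self, rng):
        cfg = SimConfig(mutant_secretion_fold=3.0)
        b = cfg.bacteria
        share = cfg.yeast.secretion_rate / 8
        w = world_with(cfg, [(BACTERIUM, MUTANT, 10.0, 5)],
                       aa=np.full((32, 32), share))
        w2 = tick(w, cfg, rng)
        expected = 10.0 + b.conversion_efficiency * share \
            - b.secretion_cost * b.secretion_rate * 3.0
        assert w2.energy[0] == pytest.approx(expected)

    def test_uptake_cap_bounds_consumption(self, rng):
        """With a finite uptake_max the agent harvests at most the cap
        even from a loaded patch."""
        bact = SpeciesParams(uptake_max=1.0, secretion_rate=1.0,
                             secretion_cost=0.1, conversion_efficiency=1.1)
        cfg = SimConfig(bacteria=bact)
        w = world_with(cfg, [(BACTERIUM, WILD, 10.0, 5)],
                       aa=np.full((32, 32), 50.0))
        w2 = tick(w, cfg, rng)
        assert w2.energy[0] == pytest.approx(11.0)

    def test_starved_agent_dies(self, rng):
        cfg = SimConfig()
        cost = cfg.bacteria.secretion_cost * cfg.bacteria.secretion_rate
        w = world_with(cfg, [(BACTERIUM, WILD, cost * 0.99, 5)])
        w2 = tick(w, cfg, rng)
        assert w2.n_agents == 0

    def test_division_at_threshold_halves_energy(self, rng):
        cfg = SimConfig()
        share = cfg.yeast.secretion_rate / 8
        # share-valued field so the agent crosses the threshold this tick
        w = world_with(cfg, [(BACTERIUM, WILD, cfg.division_threshold - 1.0, 5)],
                       aa=np.full((32, 32), share))
        w2 = tick(w, cfg, rng)
        assert w2.n_agents == 2
        assert np.allclose(w2.energy, cfg.division_threshold / 2)
        assert w2.position[0] == w2.position[1]

    def test_division_time_closed_form(self, rng):
        """A lone wild bacterium on a saturating patch (uptake capped so
        intake is its share) divides after exactly
        ceil((threshold - energy_init)/net_gain) ticks."""
        bact = SpeciesParams(uptake_max=1.0, secretion_rate=1.0,
                             secretion_cost=0.1, conversion_efficiency=1.1)
        cfg = SimConfig(bacteria=bact)
        net = bact.net_gain(1.0)
        expected = math.ceil((cfg.division_threshold - cfg.energy_init) / net)
        w = world_with(cfg, [(BACTERIUM, WILD, cfg.energy_init, 5)],
                       aa=np.full((32, 32), 1000.0))
        ticks = 0
        while w.n_agents == 1:
            w = tick(w, cfg, rng)
            ticks += 1
            assert ticks < 10 * expected
        assert ticks == expected

    def test_metabolite_bookkeeping_identity(self, rng):
        """Per tick, each pool changes by exactly secreted - consumed."""
        cfg = SimConfig(mixing=0.3)
        w = init_world(cfg, rng)
        for _ in range(30):
            w2, s = tick_with_stats(w, cfg, rng)
            d_aa = w2.amino_acid.sum() - w.amino_acid.sum()
            d_vit = w2.vitamin.sum() - w.vitamin.sum()
            assert d_aa == pytest.approx(
                s["secreted_aa"] - s["consumed_aa"], rel=1e-9, abs=1e-9)
            assert d_vit == pytest.approx(
                s["secreted_vit"] - s["consumed_vit"], rel=1e-9, abs=1e-9)
            assert np.all(w2.amino_acid >= 0) and np.all(w2.vitamin >= 0)
            w = w2

    def test_energy_bookkeeping_identity(self, rng):
        """Population energy change equals efficiency x consumed minus
        cost x secreted, minus the energy removed by deaths."""
        cfg = SimConfig()
        w = init_world(cfg, rng)
        for _ in range(15):
            before = w.energy.sum()
            w2, s = tick_with_stats(w, cfg, rng)
            y, b = cfg.yeast, cfg.bacteria
            gain = (y.conversion_efficiency * s["consumed_vit"]
                    + b.conversion_efficiency * s["consumed_aa"])
            cost = (y.secretion_cost * s["secreted_aa"]
                    + b.secretion_cost * s["secreted_vit"])
            if w2.n_agents >= w.n_agents:  # no deaths removed energy
                assert w2.energy.sum() - before == pytest.approx(
                    gain - cost, rel=1e-9, abs=1e-9)
            else:
                assert w2.energy.sum() >= before + gain - cost - 1e-9
            w = w2

    def test_obligate_dependence_without_partner(self, rng):
        """Bacteria alone (no amino-acid source) all starve within the
        energy_init / secretion-burn horizon; same for yeast alone."""
        cfg = SimConfig(init_yeast=0, init_wt_bacteria=40,
                        init_mutant_bacteria=0)
        w = init_world(cfg, rng)
        burn = cfg.bacteria.secretion_cost * cfg.bacteria.secretion_rate
        horizon = math.ceil(cfg.energy_init / burn) + 1
        for _ in range(horizon):
            w = tick(w, cfg, rng)
        assert w.n_agents == 0

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = SimConfig(init_yeast=40, init_wt_bacteria=0,
                            init_mutant_bacteria=0)
        w = init_world(cfg, rng)
        burn = cfg.yeast.secretion_cost * cfg.yeast.secretion_rate
        for _ in range(math.ceil(cfg.energy_init / burn) + 1):
            w = tick(w, cfg, rng)
        assert w.n_agents == 0

    def test_mixing_one_relocates_agents(self):
        cfg = SimConfig(mixing=1.0)
        rng = np.random.default_rng(3)
        w = init_world(cfg, rng)
        pos0 = w.position.copy()
        w2 = tick(w, cfg, rng)
        moved = np.sum(w2.position[: len(pos0)] != pos0[: w2.n_agents])
        assert moved > 0.8 * min(len(pos0), w2.n_agents)


class TestTransferCycle:
    def test_empty_world_extinct_immediately(self, small_config, rng):
        w = world_with(small_config, [])
        w2, records, outcome = run_transfer_cycle(w, small_config, rng)
        assert outcome == "extinct"
        assert records == []

    def test_reaches_threshold_and_records(self, small_config):
        rng = np.random.default_rng(11)
        w = init_world(small_config, rng)
        w2, records, outcome = run_transfer_cycle(w, small_config, rng)
        assert outcome == "reached_threshold"
        assert w2.n_agents >= small_config.transfer_threshold
        assert len(records) == w2.tick
        ticks = [r.tick for r in records]
        assert ticks == sorted(ticks)

    def test_deterministic_under_fixed_seed(self, small_config):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            w = init_world(small_config, rng)
            w2, records, outcome = run_transfer_cycle(w, small_config, rng)
            runs.append((outcome, [ (r.n_yeast, r.n_wt, r.n_mutant)
                                    for r in records]))
        assert runs[0] == runs[1]


class TestApplyTransfer:
    def _grown_world(self, cfg, seed=11):
        rng = np.random.default_rng(seed)
        w = init_world(cfg, rng)
        w2, _, outcome = run_transfer_cycle(w, cfg, rng, collect_records=False)
        assert outcome == "reached_threshold"
        return w2, rng

    def test_exact_count_and_clean_pools(self, small_config):
        w2, rng = self._grown_world(small_config)
        w3 = apply_transfer(w2, small_config, rng)
        assert w3.n_agents == small_config.init_total
        assert w3.amino_acid.sum() == 0.0 and w3.vitamin.sum() == 0.0

    def test_energies_preserved_in_sample(self, small_config):
        w2, rng = self._grown_world(small_config)
        w3 = apply_transfer(w2, small_config, rng)
        # every transferred energy value existed in the pre-transfer pool
        pre = np.sort(w2.energy)
        for e in w3.energy:
            i = np.searchsorted(pre, e)
            assert (i < pre.size and pre[i] == pytest.approx(e)) or \
                   (i > 0 and pre[i - 1] == pytest.approx(e))

    def test_fewer_agents_than_inoculum_all_kept(self, small_config, rng):
        agents = [(BACTERIUM, WILD, 5.0, i) for i in range(7)]
        w = world_with(small_config, agents)
        w2 = apply_transfer(w, small_config, rng)
        assert w2.n_agents == 7

    def test_empty_world_rejected(self, small_config, rng):
        with pytest.raises(ValueError):
            apply_transfer(world_with(small_config, []), small_config, rng)

    def test_sampling_is_label_blind(self, small_config):
        """Expected mutant fraction is preserved by the dilution: the
        sample count is hypergeometric, so the mean over many seeds
        matches the pre-transfer fraction within a few SEs."""
        cfg = small_config
        n_b, n_mut = 200, 50
        agents = [(BACTERIUM, MUTANT if i < n_mut else WILD, 5.0, i % 64)
                  for i in range(n_b)]
        w = world_with(cfg, agents)
        k = cfg.init_total
        fracs = []
        for seed in range(400):
            w2 = apply_transfer(w, cfg, np.random.default_rng(seed))
            fracs.append(np.mean(w2.strain == MUTANT))
        p = n_mut / n_b
        se = math.sqrt(p * (1 - p) / k / 400) * \
            math.sqrt((n_b - k) / (n_b - 1))
        assert np.mean(fracs) == pytest.approx(p, abs=4 * se)
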