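"""Tests for the cellular-Potts crypt-base simulator."""

import numpy as np
import pandas as pd
import pytest

from notchcrypt._potts import (
    FIRST_CELL_ID,
    MEDIUM,
    SUPPORT,
    T_PANETH,
    T_STEM,
    contact_counts,
    potts_mcs,
    total_energy,
)
from notchcrypt.crypt import (
    CryptConfig,
    _suppressed_circuit,
    anoikis_and_exit,
    divide_cell,
    fate_update,
    init_crypt,
    niche_contact_graph,
    potts_step,
    run_crypt,
    signaling_step,
)
from notchcrypt.fixtures import crypt_circuits
from notchcrypt.integrate import integrate


@pytest.fixture(scope="module")
def pf_crypt_params():
    return crypt_circuits()["pfli"]


@pytest.fixture()
def small_config():
    return CryptConfig(width=60, height=30, seed=11, n_mcs=50)


class TestInit:
    def test_every_cell_touches_support(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        C = contact_counts(world.lattice, world.next_id)
        for cid in world.live_cells():
            assert C[cid, SUPPORT] > 0

    def test_identical_seeds_identical_worlds(self, small_config, pf_crypt_params):
        a = init_crypt(small_config, pf_crypt_params)
        b = init_crypt(small_config, pf_crypt_params)
        assert np.array_equal(a.lattice, b.lattice)
        assert np.array_equal(a.signaling, b.signaling)

    def test_initial_nicd_spread_bounded_by_noise(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        live = world.live_cells()
        R = world.signaling[live, 2]
        mid = np.median(R)
        assert np.max(np.abs(R - mid)) <= 2 * small_config.init_noise * mid

    def test_volume_bookkeeping_matches_lattice(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        for cid in world.live_cells():
            assert world.volumes[cid] == np.sum(world.lattice == cid)


class TestPottsKernel:
    def test_zero_temperature_only_downhill_moves(self, small_config, pf_crypt_params):
        """At T = 0 every accepted flip lowers (or keeps) the energy."""
        world = init_crypt(small_config, pf_crypt_params)
        J = small_config.J_table()
        e0 = total_energy(world.lattice, world.cell_type, world.volumes,
                          world.target_vol, J, small_config.lambda_volume)
        for seed in range(5):
            potts_mcs(world.lattice, world.cell_type, world.volumes,
                      world.target_vol, J, small_config.lambda_volume, 0.0, seed)
        e1 = total_energy(world.lattice, world.cell_type, world.volumes,
                          world.target_vol, J, small_config.lambda_volume)
        assert e1 <= e0 + 1e-9

    def test_support_pixels_never_change(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        support_mask = world.lattice == SUPPORT
        for _ in range(20):
            potts_step(world)
            world.mcs += 1
        assert np.array_equal(world.lattice == SUPPORT, support_mask)

    def test_single_cell_relaxes_to_target_volume(self, pf_crypt_params):
        """An isolated cell under the volume constraint approaches its
        target volume within 5% over 500 MCS (3 seeded replicates)."""
        for seed in range(3):
            cfg = CryptConfig(width=30, height=30, support_rows=2, cell_size=5,
                              niche_top=28, seed=seed, n_mcs=1)
            world = init_crypt(cfg, pf_crypt_params)
            keep = world.live_cells()[2]
            for cid in world.live_cells():
                if cid != keep:
                    world.lattice[world.lattice == cid] = MEDIUM
                    world.alive[cid] = False
                    world.volumes[cid] = 0
            world.target_vol[keep] = 40.0
            J = cfg.J_table()
            for s in range(500):
                potts_mcs(world.lattice, world.cell_type, world.volumes,
                          world.target_vol, J, cfg.lambda_volume,
                          cfg.potts_temperature, 1000 * seed + s)
            assert abs(world.volumes[keep] - 40.0) <= 2.0

    def test_incremental_energy_matches_scratch_recompute(self, small_config, pf_crypt_params):
        """The kernel's accumulated dE agrees with a from-scratch energy
        difference over a long window of full dynamics."""
        world = init_crypt(small_config, pf_crypt_params)
        for _ in range(200):
            world.mcs += 1
            potts_step(world)
            signaling_step(world)
            fate_update(world)
            for cid in list(world.live_cells()):
                if world.cell_type[cid] == T_STEM and world.volumes[cid] >= world.config.division_volume:
                    divide_cell(world, cid)
            anoikis_and_exit(world)
        assert world.energy == pytest.approx(world.recompute_energy(), abs=1e-9)

    def test_pixel_conservation(self, small_config, pf_crypt_params):
        """Every lattice site is medium, support, or a live cell."""
        world = init_crypt(small_config, pf_crypt_params)
        for _ in range(50):
            world.mcs += 1
            potts_step(world)
            anoikis_and_exit(world)
        ids = np.unique(world.lattice)
        for i in ids:
            assert i in (MEDIUM, SUPPORT) or world.alive[i]


class TestSignaling:
    def test_isolated_cell_receives_no_trans_activation(self, pf_crypt_params):
        cfg = CryptConfig(width=60, height=30, seed=0, n_mcs=1)
        world = init_crypt(cfg, pf_crypt_params)
        live = world.live_cells()
        keep = live[0]
        for cid in live[1:]:
            world.lattice[world.lattice == cid] = MEDIUM
            world.alive[cid] = False
        world.signaling[keep] = [1.0, 1.0, 0.0]
        signaling_step(world)
        # with <D> = 0 no NICD is produced
        assert world.signaling[keep, 2] == pytest.approx(0.0, abs=1e-12)

    def test_contact_weights_are_row_normalized(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        _ids, graph, _sup = niche_contact_graph(world)
        rows = graph.W.sum(axis=1)
        assert np.all((np.isclose(rows, 1.0)) | (np.isclose(rows, 0.0)))

    def test_frozen_mechanics_reduces_to_lattice_ode(self, pf_crypt_params):
        """With mechanics frozen the crypt's niche dynamics equal a direct
        integration of the circuit on the induced contact graph."""
        cfg = CryptConfig(width=60, height=30, seed=4, n_mcs=400, ode_dt=0.01)
        run = run_crypt(cfg, pf_crypt_params, freeze_mechanics=True)
        world0 = init_crypt(cfg, pf_crypt_params)
        ids, graph, _ = niche_contact_graph(world0)
        y0 = world0.signaling[ids]
        t_end = cfg.n_mcs * cfg.ode_dt
        tr = integrate(pf_crypt_params, y0, graph, t_end, t_eval=np.array([0.0, t_end]))
        final_crypt = run.world.signaling[ids]
        assert np.max(np.abs(final_crypt - tr.final)) < 1e-4


class TestFateAndGrowth:
    def test_threshold_boundary_is_stem_inclusive(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        cid = world.live_cells()[0]
        world.signaling[cid, 2] = world.nicd_threshold
        fate_update(world)
        assert world.cell_type[cid] == T_STEM

    def test_no_nicd_no_growth(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        world.signaling[world.live_cells(), 2] = 0.0
        before = world.target_vol.copy()
        fate_update(world)
        assert np.all(world.cell_type[world.live_cells()] == T_PANETH)
        assert np.array_equal(world.target_vol, before)

    def test_growth_ledger_sums_per_mcs(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        world.signaling[world.live_cells(), 2] = world.nicd_threshold + 1.0
        g = small_config.growth_rate * small_config.turnover_multiplier
        before = world.target_vol[world.live_cells()].sum()
        for _ in range(100):
            fate_update(world)
        after = world.target_vol[world.live_cells()].sum()
        assert after - before == pytest.approx(100 * g * len(world.live_cells()))


class TestDivision:
    def test_division_conserves_pixels_and_increments_count(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        cid = world.live_cells()[3]
        vol = world.volumes[cid]
        n0 = world.cell_count()
        new_id = divide_cell(world, cid)
        assert new_id is not None
        assert world.cell_count() == n0 + 1
        assert world.volumes[cid] + world.volumes[new_id] == vol
        assert np.array_equal(world.signaling[new_id], world.signaling[cid])

    def test_division_events_logged_with_daughter(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        cid = world.live_cells()[0]
        divide_cell(world, cid)
        ev = world.events[-1]
        assert ev["event"] == "division" and ev["cell_id"] == cid


class TestRemoval:
    def test_detached_cell_dies_by_anoikis(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        cid = world.live_cells()[2]
        px = np.argwhere(world.lattice == cid)
        # teleport the cell into the medium, fully detached, below the exit row
        world.lattice[px[:, 0], px[:, 1]] = MEDIUM
        world.lattice[world.config.support_rows + 1, 2] = cid
        world.volumes[cid] = 1
        others = {
            int(c): world.volumes[c] for c in world.live_cells() if c != cid
        }
        anoikis_and_exit(world)
        assert not world.alive[cid]
        assert world.events[-1]["event"] == "anoikis"
        for c, v in others.items():
            assert world.alive[c] and world.volumes[c] == v

    def test_displaced_cell_exits(self, small_config, pf_crypt_params):
        world = init_crypt(small_config, pf_crypt_params)
        cid = world.live_cells()[2]
        px = np.argwhere(world.lattice == cid)
        world.lattice[px[:, 0], px[:, 1]] = MEDIUM
        world.lattice[world.config.niche_top + 2, 2] = cid
        world.volumes[cid] = 1
        anoikis_and_exit(world)
        assert not world.alive[cid]
        assert world.events[-1]["event"] == "exit"


class TestRunCrypt:
    def test_same_seed_identical_sample_stream(self, pf_crypt_params):
        cfg = CryptConfig(width=60, height=30, seed=9, n_mcs=120)
        a = run_crypt(cfg, pf_crypt_params)
        b = run_crypt(cfg, pf_crypt_params)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_cell_count_ledger_closes(self, pf_crypt_params):
        cfg = CryptConfig(width=60, height=30, seed=2, n_mcs=300,
                          turnover_multiplier=4.0)
        run = run_crypt(cfg, pf_crypt_params)
        counts = run.event_counts()
        n0 = (cfg.width // cfg.cell_size) * cfg.epithelial_rows
        expected = n0 + counts["division"] - counts["anoikis"] - counts["exit"]
        assert run.world.cell_count() == expected

    def test_event_rates_increase_with_turnover(self, pf_crypt_params):
        totals = []
        for tm in (0.5, 4.0):
            per_seed = []
            for seed in range(2):
                cfg = CryptConfig(width=60, height=30, seed=seed, n_mcs=400,
                                  turnover_multiplier=tm)
                run = run_crypt(cfg, pf_crypt_params)
                per_seed.append(sum(run.event_counts().values()))
            totals.append(np.median(per_seed))
        assert totals[1] > totals[0]


class TestSuppressedCircuit:
    def test_rescale_zero_is_pure_li(self, pf_crypt_params):
        li = _suppressed_circuit(pf_crypt_params, 0.0, "rescale")
        assert li.S_PF == 0.0
        assert li.beta_N == pf_crypt_params.beta_N

    def test_knockdown_keeps_basal_and_lowers_production(self, pf_crypt_params):
        p = pf_crypt_params
        kd = _suppressed_circuit(p, 0.5, "knockdown")
        basal = p.beta_N * (1 - p.S_PF)
        assert kd.beta_N == pytest.approx(basal + 0.5 * p.beta_N * p.S_PF)
        assert kd.beta_N < p.beta_N
        full = _suppressed_circuit(p, 1.0, "knockdown")
        assert full.beta_N == pytest.approx(p.beta_N)
        assert full.S_PF == pytest.approx(p.S_PF)

    def test_out_of_range_rejected(self, pf_crypt_params):
        with pytest.raises(ValueError):
            _suppressed_circuit(pf_crypt_params, 1.5, "rescale")
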