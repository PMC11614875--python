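import numpy as np
import pytest

from oracles import attrition_free_kill_time

from micromet.agents import Cell, CellType, DcState, MacState, start_death, volume_from_radius
from micromet.errors import ConfigurationError
from micromet.immune_interactions import (
    InteractionRates,
    RecruitmentParams,
    cd8_update,
    dc_update,
    macrophage_update,
    place_recruited,
    rate_event,
    recruited_count,
)
from micromet.microenvironment import DiffusionField, VoxelGrid, assign_vascular_voxels


def cell(ctype, cid, pos=(0.0, 0.0), **kw):
    c = Cell(id=cid, type=ctype, position=np.array(pos, float))
    for k, v in kw.items():
        setattr(c, k, v)
    return c


class _NeverFires:
    """Stub generator whose uniform draws always miss sub-unity probabilities."""

    def random(self, *a, **k):
        return 0.999999

    def permutation(self, n):
        return np.arange(n)


class TestRateEvents:
    def test_zero_rate_never_fires(self, rng):
        assert not any(rate_event(0.0, 1.0, rng) for _ in range(100))

    def test_certain_event_always_fires(self, rng):
        assert all(rate_event(2.0, 1.0, rng) for _ in range(100))

    @pytest.mark.parametrize("rate", [1e-4, 1e-3, 1e-2, 1e-1])
    def test_calibration_across_four_orders(self, rate):
        rng = np.random.default_rng(int(rate * 1e6))
        n = 100_000
        p = rate * 1.0
        freq = sum(rate_event(rate, 1.0, rng) for _ in range(n)) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) < 5 * se

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            rate_event(-0.1, 1.0, rng)


class TestRecruitment:
    def make_field(self, level, n=6):
        grid = VoxelGrid(n, n, 20.0)
        f = DiffusionField("TNF", grid, 0.0, 0.0)
        f.conc[:] = level
        return f, grid

    params = RecruitmentParams(r_recruit=2e-5, rho_min=1e-5, rho_sat=1e-4)

    def test_below_minimum_signal_recruits_nothing(self, rng):
        f, grid = self.make_field(1e-5)
        assert all(recruited_count(f, grid, self.params, 6.0, rng) == 0 for _ in range(50))

    def test_saturated_signal_expectation(self, rng):
        f, grid = self.make_field(1e-3)
        expect = self.params.r_recruit * grid.n_voxels * grid.voxel_volume * 6.0
        draws = [recruited_count(f, grid, self.params, 6.0, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(expect, rel=0.01)

    def test_midpoint_ramp_expectation(self, rng):
        f, grid = self.make_field(0.5 * (1e-5 + 1e-4))
        expect = 0.5 * self.params.r_recruit * grid.n_voxels * grid.voxel_volume * 6.0
        draws = [recruited_count(f, grid, self.params, 6.0, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(expect, rel=0.02)

    def test_expected_recruits_bounded(self, rng):
        f, grid = self.make_field(10.0)  # far beyond saturation
        cap = self.params.r_recruit * grid.n_voxels * grid.voxel_volume * 6.0
        assert all(
            recruited_count(f, grid, self.params, 6.0, rng) <= np.ceil(cap) for _ in range(200)
        )


class TestPlacement:
    def test_zero_returns_empty(self, rng):
        grid = assign_vascular_voxels(VoxelGrid(6, 6, 20.0), 0.2, rng)
        assert place_recruited(grid, 0, CellType.MACROPHAGE, rng) == []

    def test_all_placements_inside_vascular_voxels(self, rng):
        grid = assign_vascular_voxels(VoxelGrid(10, 10, 20.0), 0.15, rng)
        cells = place_recruited(grid, 1000, CellType.DC, rng)
        h = grid.voxel_size
        for c in cells:
            i, j = int(c.position[0] / h), int(c.position[1] / h)
            assert grid.vascular_mask[i, j]

    def test_single_vascular_voxel_containment(self, rng):
        grid = VoxelGrid(5, 5, 20.0)
        grid.vascular_mask[2, 3] = True
        cells = place_recruited(grid, 50, CellType.MACROPHAGE, rng)
        for c in cells:
            assert np.abs(c.position - np.array([50.0, 70.0])).max() <= 5.0 + 1e-12

    def test_no_vasculature_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            place_recruited(VoxelGrid(5, 5, 20.0), 3, CellType.MACROPHAGE, rng)


class TestMacrophageStateMachine:
    rates = InteractionRates(
        r_phag=1e9, exhaustion_threshold=volume_from_radius(8.4) * 1.5, tau_digest=0.0
    )

    def test_resting_state_unchanged_without_targets(self, rng):
        mac = cell(CellType.MACROPHAGE, 1)
        live_par = cell(CellType.PARENCHYMAL, 2, (10.0, 0.0))
        macrophage_update(mac, [live_par], self.rates, 6.0, rng)
        assert mac.mac_state is MacState.M0

    def test_engulfment_activates_m0(self, rng):
        mac = cell(CellType.MACROPHAGE, 1)
        corpse = start_death(cell(CellType.PARENCHYMAL, 2, (10.0, 0.0)))
        macrophage_update(mac, [corpse], self.rates, 6.0, rng)
        assert mac.mac_state is MacState.M1
        assert corpse.removed

    def test_cd4_contact_hyperactivates_then_eats_live_cancer(self, rng):
        mac = cell(CellType.MACROPHAGE, 1, mac_state=MacState.M1)
        cd4 = cell(CellType.CD4, 2, (10.0, 0.0))
        macrophage_update(mac, [cd4], self.rates, 6.0, rng)
        assert mac.mac_state is MacState.HYPERACTIVATED
        prey = cell(CellType.CANCER, 3, (10.0, 0.0))
        macrophage_update(mac, [prey], self.rates, 6.0, rng)
        assert prey.removed  # live cancer is an eligible target once hyperactivated

    def test_m1_never_eats_live_cancer(self, rng):
        mac = cell(CellType.MACROPHAGE, 1, mac_state=MacState.M1)
        prey = cell(CellType.CANCER, 3, (10.0, 0.0))
        macrophage_update(mac, [prey], self.rates, 6.0, rng)
        assert not prey.removed

    def test_cd8_contact_converts_to_m2_permanently(self, rng):
        mac = cell(CellType.MACROPHAGE, 1, mac_state=MacState.M1, secretes_tnf=True)
        cd8 = cell(CellType.CD8, 2, (10.0, 0.0))
        macrophage_update(mac, [cd8], self.rates, 6.0, rng)
        assert mac.mac_state is MacState.M2
        assert not mac.secretes_tnf
        # absorbing: CD4 contact afterwards cannot rescue it
        cd4 = cell(CellType.CD4, 3, (10.0, 0.0))
        for _ in range(20):
            macrophage_update(mac, [cd4, start_death(cell(CellType.CANCER, 9, (10.0, 0.0)))],
                              self.rates, 6.0, rng)
            assert mac.mac_state is MacState.M2
            assert mac.ingested_volume == 0.0

    def test_exhaustion_is_absorbing(self, rng):
        mac = cell(CellType.MACROPHAGE, 1, mac_state=MacState.M1)
        mac.ingested_volume = self.rates.exhaustion_threshold
        macrophage_update(mac, [], self.rates, 6.0, rng)
        assert mac.mac_state is MacState.EXHAUSTED
        for k in range(20):
            corpse = start_death(cell(CellType.CANCER, 10 + k, (10.0, 0.0)))
            macrophage_update(mac, [corpse], InteractionRates(
                r_phag=1e9, exhaustion_threshold=self.rates.exhaustion_threshold,
                exhausted_death_rate=0.0), 6.0, rng)
            assert not corpse.removed  # never engulfs again
            assert mac.mac_state is MacState.EXHAUSTED

    def test_transition_dag_by_exhaustive_toy_enumeration(self, rng):
        """Every reachable transition on a 3-cell toy world respects the DAG.

        One update may traverse several forward edges (e.g. an engulfment can
        polarize M0 → M1 and immediately exhaust), so states are checked
        against the transitive closure of M0 → M1 → {M2, hyper, exhausted};
        M2 and exhausted are absorbing and nothing ever moves backwards.
        """
        allowed = {
            MacState.M0: set(MacState),
            MacState.M1: {MacState.M1, MacState.M2, MacState.HYPERACTIVATED, MacState.EXHAUSTED},
            MacState.M2: {MacState.M2},
            MacState.HYPERACTIVATED: {MacState.HYPERACTIVATED, MacState.EXHAUSTED},
            MacState.EXHAUSTED: {MacState.EXHAUSTED},
        }
        partners = {
            "corpse": lambda: start_death(cell(CellType.CANCER, 7, (10.0, 0.0))),
            "cd4": lambda: cell(CellType.CD4, 8, (10.0, 0.0)),
            "cd8": lambda: cell(CellType.CD8, 9, (10.0, 0.0)),
        }
        import itertools

        for start_state, ingested in itertools.product(MacState, (0.0, 1e9)):
            for pair in itertools.product(partners, repeat=2):
                mac = cell(CellType.MACROPHAGE, 1, mac_state=start_state,
                           ingested_volume=ingested)
                state = mac.mac_state
                for name in pair:
                    macrophage_update(mac, [partners[name]()], self.rates, 6.0, rng)
                    assert mac.mac_state in allowed[state], (start_state, pair)
                    state = mac.mac_state


class TestDendriticCells:
    rates = InteractionRates(r_attach_dc=1e9, r_leave=0.2)

    def test_healthy_parenchyma_cannot_activate(self, rng):
        dc = cell(CellType.DC, 1)
        healthy = cell(CellType.PARENCHYMAL, 2, (10.0, 0.0))
        for _ in range(50):
            dc_update(dc, [healthy], self.rates, 6.0, rng)
        assert dc.dc_state is DcState.INACTIVE

    def test_cancer_contact_activates(self, rng):
        dc = cell(CellType.DC, 1)
        dc_update(dc, [cell(CellType.CANCER, 2, (10.0, 0.0))], self.rates, 6.0, rng)
        assert dc.dc_state is DcState.ACTIVE

    def test_dying_parenchyma_activates(self, rng):
        dc = cell(CellType.DC, 1)
        corpse = start_death(cell(CellType.PARENCHYMAL, 2, (10.0, 0.0)))
        dc_update(dc, [corpse], self.rates, 6.0, rng)
        assert dc.dc_state is DcState.ACTIVE

    def test_certain_departure(self, rng):
        dc = cell(CellType.DC, 1, dc_state=DcState.ACTIVE)
        rates = InteractionRates(r_leave=1.0)
        _, departed = dc_update(dc, [], rates, 6.0, rng)
        assert departed and dc.removed

    def test_departure_rate_calibration(self):
        rng = np.random.default_rng(11)
        rates = InteractionRates(r_leave=0.05 / 6.0)
        n = 10_000
        hits = 0
        for _ in range(n):
            dc = cell(CellType.DC, 1, dc_state=DcState.ACTIVE)
            _, departed = dc_update(dc, [], rates, 6.0, rng)
            hits += departed
        assert hits / n == pytest.approx(0.05, abs=0.007)


class TestCd8Killing:
    def test_no_cancer_neighbors_is_a_noop(self, rng):
        t = cell(CellType.CD8, 1)
        before = (t.attach_target, t.attach_clock)
        cd8_update(t, [cell(CellType.PARENCHYMAL, 2, (10.0, 0.0))],
                   InteractionRates(r_attach_cd8=1e9), 6.0, rng)
        assert (t.attach_target, t.attach_clock) == before

    def test_single_step_kill_when_t_attach_equals_dt(self, rng):
        rates = InteractionRates(r_attach_cd8=1e9, T_attach=6.0)
        t = cell(CellType.CD8, 1)
        target = cell(CellType.CANCER, 2, (10.0, 0.0))
        cd8_update(t, [target], rates, 6.0, rng)  # attaches
        cd8_update(t, [target], rates, 6.0, rng)  # accrues 6 min = T_attach
        assert target.dead

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_additive_credit_matches_event_oracle(self, k):
        """k pinned attackers with detachment disabled kill in T_attach/k."""
        rates = InteractionRates(r_attach_cd8=1e9, T_attach=60.0)
        rng = _NeverFires()  # detachment draw never fires
        target = cell(CellType.CANCER, 0, (0.0, 0.0))
        attackers = [cell(CellType.CD8, i + 1, (10.0, 0.0)) for i in range(k)]
        dt, t = 1.0, 0.0
        for a in attackers:  # pin the attackers before the clock starts
            cd8_update(a, [target], rates, dt, rng)
            assert a.attach_target is target
        for _ in range(1000):
            for a in attackers:
                cd8_update(a, [target], rates, dt, rng)
            t += dt
            if target.dead:
                break
        assert t == attrition_free_kill_time(60.0, k, dt)
        assert t == pytest.approx(60.0 / k)

    def test_detach_withdraws_own_credit(self):
        rates = InteractionRates(r_attach_cd8=1e9, T_attach=1e6)

        class FiresOnce(_NeverFires):
            def __init__(self):
                self.fired = False

            def random(self, *a, **k):
                if not self.fired:
                    self.fired = True
                    return 0.0
                return 0.999999

        rng = _NeverFires()
        target = cell(CellType.CANCER, 0, (0.0, 0.0))
        a, b = (cell(CellType.CD8, i, (10.0, 0.0)) for i in (1, 2))
        for cd8 in (a, b):
            cd8_update(cd8, [target], rates, 1.0, rng)
        for _ in range(5):
            cd8_update(a, [target], rates, 1.0, rng)
            cd8_update(b, [target], rates, 1.0, rng)
        assert target.kill_credit == pytest.approx(10.0)
        # a accrues one more minute, then detaches: all of a's credit leaves
        cd8_update(a, [target], rates, 1.0, FiresOnce())
        assert a.attach_target is None
        assert target.kill_credit == pytest.approx(5.0)
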