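"""Circuit currents, event-resolved stepping and velocity measurement."""

import dataclasses

import numpy as np
import pytest

from demyelin.bundle_simulator import (
    PropagationResult,
    StimulusProtocol,
    build_bundle,
    conduction_velocity,
    ephaptic_current,
    ionic_current,
    linear_step,
    nodal_currents,
    simulate,
    single_axon_config,
)
from demyelin.exceptions import (
    DegenerateMeasurementError,
    DomainError,
    PropagationFailureError,
)


class TestIonicCurrent:
    def test_all_branches_closed_gives_zero(self, config):
        assert ionic_current(-10.0, config.channels, 0.3,
                             (False,) * 4) == 0.0

    def test_single_leak_branch_ohmic(self, config):
        p = dataclasses.replace(config.channels, g_leak=0.1, e_leak=-70.0)
        i = ionic_current(-60.0, p, 0.0, (False, False, False, True))
        assert i == pytest.approx(0.1 * 10.0)  # 1.0 uA

    def test_matches_per_branch_brute_force(self, config, rng):
        """Vectorizable form equals an explicit per-branch summation."""
        p = config.channels
        for _ in range(200):
            v = float(rng.uniform(-90, 60))
            gamma = float(rng.uniform(0, 0.99))
            sw = tuple(bool(b) for b in rng.integers(0, 2, 4))
            expected = 0.0
            for g, e, s in zip(p.conductances(), p.nernst(), sw):
                if s:
                    expected += g * (1.0 + gamma) * (v - e)
            assert ionic_current(v, p, gamma, sw) == \
                pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_gamma_domain(self, config):
        with pytest.raises(DomainError):
            ionic_current(0.0, config.channels, 1.2, (True,) * 4)


class TestEphapticCurrent:
    def test_decoupled_limit(self):
        assert ephaptic_current(-70.0, [0.0, 10.0], 0.0, 1.0) == 0.0

    def test_symmetry_zero_at_equal_voltages(self):
        assert ephaptic_current(-55.0, [-55.0] * 6, 0.1, 5.0) == 0.0

    def test_cancellation(self):
        assert ephaptic_current(0.0, [10.0, -10.0], 0.1, 1.0) == \
            pytest.approx(0.0)

    def test_neighbor_count_mismatch(self):
        with pytest.raises(DomainError):
            ephaptic_current(0.0, [], 0.1, 1.0, n_neighbors=6)


class TestBuildBundle:
    def test_layout(self, config):
        model = build_bundle(config)
        assert model.n_axons == 1 + config.layout.n_neighbors
        assert np.all(np.diff(model.positions, axis=1) > 0)
        # A = 1: neighbours exactly registered with the centre
        np.testing.assert_allclose(
            model.positions[1:],
            np.broadcast_to(model.positions[0],
                            model.positions[1:].shape))

    def test_staggered_neighbors(self, config):
        lay = dataclasses.replace(config.layout, alignment=0.75)
        model = build_bundle(config.replace(layout=lay))
        shift = model.positions[1, 0] - model.positions[0, 0]
        assert shift == pytest.approx(
            0.25 * config.geometry.internodal_length)

    def test_per_axon_state_count_checked(self, config):
        from demyelin.model_core import AxonState
        with pytest.raises(DomainError):
            build_bundle(config, per_axon_states=[AxonState()])


class TestKirchhoffBalance:
    def test_implicit_step_balances_currents(self, config, rng):
        """C dV/dt of the solver equals the independent current sum."""
        model = build_bundle(config.with_state(gamma=0.25))
        shape = (model.n_axons, model.n_nodes)
        v = config.resting_potential + 60 * rng.random(shape)
        open_mask = rng.random(shape + (4,)) < 0.5
        open_mask[:, :, 3] = True
        stim = np.zeros(shape)
        stim[0, 0] = 0.05
        h = 0.002
        v_new = linear_step(model, v, open_mask, h, stim)
        c = np.repeat(model.c_eff, model.n_nodes).reshape(shape)
        lhs = c * (v_new - v) / h
        # brute-force oracle: loop every node and branch explicitly
        rhs = np.zeros(shape)
        flat = v_new.reshape(-1)
        for a in range(model.n_axons):
            for i in range(model.n_nodes):
                n = model.flat(a, i)
                axial = model.passive[n] @ flat
                ionic = 0.0
                for x in range(4):
                    if open_mask[a, i, x]:
                        ionic += model.g_eff[a, x] * \
                            (v_new[a, i] - model.e_rev[x])
                rhs[a, i] = axial - ionic + stim[a, i]
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9,
                                   atol=1e-9 * np.abs(rhs).max())

    def test_nodal_currents_matches_linear_step(self, config, rng):
        model = build_bundle(config)
        shape = (model.n_axons, model.n_nodes)
        v = config.resting_potential + 30 * rng.random(shape)
        open_mask = np.zeros(shape + (4,), dtype=bool)
        open_mask[:, :, 3] = True
        stim = np.zeros(shape)
        h = 1e-3
        v_new = linear_step(model, v, open_mask, h, stim)
        c = np.repeat(model.c_eff, model.n_nodes).reshape(shape)
        np.testing.assert_allclose(
            c * (v_new - v) / h,
            nodal_currents(model, v_new, open_mask, stim),
            rtol=1e-9, atol=1e-12)


@pytest.fixture(scope="module")
def default_result(config):
    return simulate(build_bundle(config))


class TestSimulate:
    def test_crossing_times_increase_with_distance(self, default_result):
        ct = default_result.crossing_times[0]
        assert np.all(np.isfinite(ct))
        assert np.all(np.diff(ct) > 0)

    def test_symmetry_identical_axons(self, default_result):
        """A = 1 and identical stimulation: all axons' traces coincide."""
        spread = np.abs(default_result.traces
                        - default_result.traces[:, :1, :]).max()
        assert spread < 1e-9

    def test_decoupling_alpha_zero_equals_single_axon(self, config):
        lay = dataclasses.replace(config.layout, ephaptic_coupling=0.0)
        v_bundle = simulate(
            build_bundle(config.replace(layout=lay))).velocities
        v_single = simulate(
            build_bundle(single_axon_config(config))).velocities[0]
        assert v_bundle == pytest.approx(v_single, rel=0.01)

    def test_step_size_robustness(self, config, default_result):
        """Halving dt moves the velocity by < 1 %."""
        v1 = default_result.velocities[0]
        v2 = simulate(build_bundle(config), dt=0.0025).velocities[0]
        assert abs(v2 - v1) / v1 < 0.01

    def test_determinism(self, config, default_result):
        again = simulate(build_bundle(config))
        np.testing.assert_array_equal(again.crossing_times,
                                      default_result.crossing_times)

    def test_propagation_failure_at_near_total_block(self, config):
        cfg = config.with_state(block_fraction=0.99)
        with pytest.raises(PropagationFailureError):
            simulate(build_bundle(cfg), t_end=3.0)
        result = simulate(build_bundle(cfg), t_end=3.0,
                          raise_on_failure=False)
        assert np.isnan(result.velocities[0])

    def test_invalid_stimulus(self):
        with pytest.raises(DomainError):
            StimulusProtocol(amplitude=0.0)
        with pytest.raises(DomainError):
            StimulusProtocol(duration=-1.0)


class TestConductionVelocity:
    @staticmethod
    def _linear_result(n_nodes=11, spacing_mm=2.0, step_ms=0.1):
        ct = np.arange(n_nodes, dtype=float) * step_ms
        pos = np.arange(n_nodes, dtype=float) * spacing_mm
        return PropagationResult(
            times=np.array([0.0]), traces=np.zeros((1, 1, n_nodes)),
            crossing_times=ct[None, :], velocities=np.array([np.nan]),
            positions=pos[None, :], stimulated_node=0, dt=0.01)

    def test_distance_over_time(self):
        res = self._linear_result()
        # 2 mm per 0.1 ms -> 20 m/s
        assert conduction_velocity(res, 2, 9) == pytest.approx(20.0)

    def test_regression_equals_two_point_on_linear_crossings(self):
        res = self._linear_result()
        assert conduction_velocity(res, 2, 9, method="regression") == \
            pytest.approx(conduction_velocity(res, 2, 9), rel=1e-12)

    def test_degenerate_equal_crossing_times(self):
        res = self._linear_result(step_ms=0.0)
        res.crossing_times[:] = 1.0
        with pytest.raises(DegenerateMeasurementError):
            conduction_velocity(res, 2, 9)

    def test_missing_crossing_raises_propagation_failure(self):
        res = self._linear_result()
        res.crossing_times[0, 9] = np.nan
        with pytest.raises(PropagationFailureError):
            conduction_velocity(res, 2, 9)

    def test_window_validation(self):
        res = self._linear_result()
        with pytest.raises(DomainError):
            conduction_velocity(res, 5, 5)
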