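"""Pooled-network invariants: exact conservation, mean-field collapse,
uniqueness, pool calibration, and indirect competition coupling."""

import numpy as np
import pytest

from rfmnet import (
    Network,
    NetworkState,
    PoolSpec,
    RFMIOSpec,
    calibrate_pool,
    network_rhs,
    solve_network_steady,
    total_ribosomes,
)


def _random_specs(rng, m=3, n_max=5):
    return [
        RFMIOSpec(rates=rng.uniform(0.3, 2.0, size=rng.integers(1, n_max) + 1),
                  copy_weight=float(rng.uniform(0.5, 3.0)), gene_id=f"g{j}")
        for j in range(m)
    ]


class TestConservation:
    def test_weighted_derivative_sum_is_identically_zero(self, rng):
        specs = _random_specs(rng, m=4)
        pool = PoolSpec(H0=10.0, c=2.0)
        state = NetworkState(
            chains=[rng.uniform(0, 1, size=s.n) for s in specs], z=3.0)
        dy = network_rhs(state, specs, pool)
        dH = dy[-1] + sum(
            s.copy_weight * dy[off: off + s.n].sum()
            for s, off in zip(specs, np.concatenate([[0], np.cumsum([s.n for s in specs])]))
        )
        assert abs(dH) < 1e-12

    def test_total_ribosomes_bookkeeping(self):
        specs = [RFMIOSpec(rates=[1.0, 1.0], copy_weight=2.0)]
        empty = NetworkState(chains=[np.zeros(1)], z=200_000.0)
        assert total_ribosomes(empty, specs) == 200_000.0
        # moving delta ribosomes from pool onto the chain leaves H unchanged
        moved = NetworkState(chains=[np.array([0.25])], z=200_000.0 - 2.0 * 0.25)
        assert total_ribosomes(moved, specs) == pytest.approx(200_000.0)

    def test_H_drift_negligible_along_trajectory(self, rng):
        specs = _random_specs(rng, m=5)
        pool = PoolSpec(H0=8.0, c=1.5)
        net = Network(specs, pool)
        y0 = np.concatenate([np.concatenate([rng.uniform(0, 0.5, s.n) for s in specs]), [2.0]])
        H0 = net.total_ribosomes(y0)
        sol = net.integrate(y0, (0.0, 1000.0), t_eval=np.linspace(0, 1000, 21))
        drifts = [abs(net.total_ribosomes(sol.y[:, k]) - H0) / H0 for k in range(sol.y.shape[1])]
        assert max(drifts) < 1e-6

    def test_empty_pool_only_receives(self):
        # G(0) = 0: nothing leaves the pool, chain outflow feeds it
        specs = [RFMIOSpec(rates=[1.0, 1.0], copy_weight=1.0)]
        state = NetworkState(chains=[np.array([0.4])], z=0.0)
        dy = network_rhs(state, specs, PoolSpec(H0=5.0, c=1.0))
        assert dy[-1] == pytest.approx(0.4)  # lambda_1 * x_1
        assert dy[0] == pytest.approx(-0.4)


class TestMeanFieldCollapse:
    def test_two_unit_copies_equal_one_double_weight_chain(self, rng):
        rates = rng.uniform(0.4, 1.5, size=4)
        pool = PoolSpec(H0=4.0, c=1.0)
        two = Network([RFMIOSpec(rates=rates, copy_weight=1.0),
                       RFMIOSpec(rates=rates, copy_weight=1.0)], pool)
        one = Network([RFMIOSpec(rates=rates, copy_weight=2.0)], pool)
        x0 = rng.uniform(0, 0.6, size=3)
        y_two = np.concatenate([x0, x0, [1.5]])
        y_one = np.concatenate([x0, [1.5]])
        t_eval = np.linspace(0, 50, 11)
        sol2 = two.integrate(y_two, (0, 50.0), t_eval=t_eval)
        sol1 = one.integrate(y_one, (0, 50.0), t_eval=t_eval)
        assert np.max(np.abs(sol2.y[-1] - sol1.y[-1])) < 1e-8
        assert np.max(np.abs(sol2.y[:3] - sol1.y[:3])) < 1e-8


class TestNetworkSteady:
    def test_single_site_linear_pool_matches_hand_solution(self):
        # chain n=1, lambda=(1,1), G(z)=z: z(1-e)=e and z+e=H0
        H0 = 0.5
        specs = [RFMIOSpec(rates=[1.0, 1.0], copy_weight=1.0)]
        pool = PoolSpec(H0=H0, c=1.0, G_family="linear")
        st = solve_network_steady(specs, pool)
        e_hand = ((H0 + 2) - np.sqrt((H0 + 2) ** 2 - 4 * H0)) / 2
        assert st.chains[0][0] == pytest.approx(e_hand, abs=1e-8)
        assert st.z == pytest.approx(H0 - e_hand, abs=1e-8)

    def test_integration_from_random_splits_reaches_same_steady_state(self, rng):
        specs = _random_specs(rng, m=3)
        pool = PoolSpec(H0=6.0, c=1.0)
        st = solve_network_steady(specs, pool)
        target = st.pack()
        net = Network(specs, pool)
        for _ in range(3):
            # random split of H0 between pool and chains
            x0 = np.concatenate([rng.uniform(0, 0.3, s.n) for s in specs])
            bound = sum(s.copy_weight * x0[a:b].sum() for s, a, b in
                        zip(specs, net.first, net.last + 1))
            y0 = np.concatenate([x0, [pool.H0 - bound]])
            sol = net.integrate(y0, (0, 4000.0))
            assert np.max(np.abs(sol.y[:, -1] - target)) < 1e-6

    def test_copy_weight_and_pool_rescaling(self, rng):
        # doubling every copy weight and H0 with G(z)=z/c, c doubled, leaves
        # per-chain steady densities unchanged
        specs = _random_specs(rng, m=3)
        pool = PoolSpec(H0=5.0, c=2.0, G_family="linear")
        st1 = solve_network_steady(specs, pool)
        doubled = [RFMIOSpec(rates=s.rates, copy_weight=2 * s.copy_weight) for s in specs]
        st2 = solve_network_steady(doubled, PoolSpec(H0=10.0, c=4.0, G_family="linear"))
        for a, b in zip(st1.chains, st2.chains):
            assert np.max(np.abs(a - b)) < 1e-7
        assert st2.z == pytest.approx(2 * st1.z, rel=1e-7)

    def test_raising_one_copy_weight_drains_pool_and_others(self, rng):
        specs = _random_specs(rng, m=5)
        pool = PoolSpec(H0=6.0, c=1.0)
        st1 = solve_network_steady(specs, pool)
        R1 = [s.rates[-1] * e[-1] for s, e in zip(specs, st1.chains)]
        bumped = [RFMIOSpec(rates=s.rates,
                            copy_weight=s.copy_weight * (3.0 if j == 0 else 1.0))
                  for j, s in enumerate(specs)]
        st2 = solve_network_steady(bumped, pool)
        R2 = [s.rates[-1] * e[-1] for s, e in zip(bumped, st2.chains)]
        assert st2.z < st1.z
        for j in range(1, 5):
            assert R2[j] <= R1[j] + 1e-12


class TestCalibration:
    def test_calibrated_pool_hits_target(self, small_world):
        _, genome, _, specs = small_world
        pool = calibrate_pool(specs, genome.total_ribosomes, 30.0)
        st = solve_network_steady(specs, pool)
        assert 100 * st.z / genome.total_ribosomes == pytest.approx(30.0, abs=0.1)

    def test_zbar_monotone_in_c(self, small_world):
        _, genome, _, specs = small_world
        H0 = genome.total_ribosomes
        zbars = []
        for c in [H0 / 100, H0 / 10, H0, 10 * H0]:
            st = solve_network_steady(specs, PoolSpec(H0=H0, c=c))
            zbars.append(st.z)
        assert all(a < b for a, b in zip(zbars, zbars[1:]))

    def test_infeasible_target_reports_bracket(self, small_world):
        _, genome, _, specs = small_world
        with pytest.raises(ValueError, match="achievable range"):
            calibrate_pool(specs, genome.total_ribosomes, 99.999)


def test_pool_spec_validation():
    with pytest.raises(ValueError):
        PoolSpec(H0=-1.0)
    with pytest.raises(ValueError):
        PoolSpec(H0=1.0, c=0.0)
    with pytest.raises(ValueError):
        PoolSpec(H0=1.0, G_family="sigmoid")
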