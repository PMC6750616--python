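"""Stoichiometric core: S assembly, splitting, null space, FVA, flux LPs."""

import numpy as np
import pytest

import p13cmfa as p
from p13cmfa.network import _split_bounds


class TestBuildNetwork:
    def test_chain_conservation(self, chain_network):
        net = chain_network
        assert net.S.shape == (2, 3)
        # unit throughput is balanced
        assert np.allclose(net.S @ np.ones(3), 0)

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ValueError, match="unknown metabolite"):
            p.build_network(
                [p.Metabolite("A", n_carbons=1)],
                [p.Reaction("r", {"A": -1, "ghost": 1}, 0, 1)],
            )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            p.build_network(
                [p.Metabolite("A"), p.Metabolite("A")],
                [],
            )

    def test_empty_reaction_list(self):
        net = p.build_network([p.Metabolite("A")], [])
        assert net.S.shape == (1, 0)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="lb"):
            p.Reaction("r", {}, 2.0, 1.0)


class TestSplitReversible:
    @pytest.mark.parametrize(
        "v,t,vf,vr",
        [(5.0, 2.0, 7.0, 2.0), (-3.0, 1.0, 1.0, 4.0), (0.0, 0.0, 0.0, 0.0)],
    )
    def test_forward_reverse_assignment(self, chain_network, v, t, vf, vr):
        flux = p.FluxVector(["r1", "r2", "r3"], [v, 0, 0], [t, 0, 0])
        got_vf, got_vr = p.split_reversible(chain_network, flux)
        assert got_vf[0] == pytest.approx(vf)
        assert got_vr[0] == pytest.approx(vr)

    def test_negative_turnover_rejected(self):
        with pytest.raises(ValueError, match="turnover"):
            p.FluxVector(["r"], [1.0], [-0.5])

    def test_roundtrip_recovers_net_and_turnover(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=10)
        t = rng.uniform(0, 2, size=10)
        flux = p.FluxVector([f"r{i}" for i in range(10)], v, t)
        vf, vr = flux.vf, flux.vr
        assert np.allclose(vf - vr, v)
        assert np.allclose(np.minimum(vf, vr), t)
        assert (vf >= 0).all() and (vr >= 0).all()


class TestNullSpace:
    def test_chain_kernel_is_throughput(self, chain_network):
        ns = p.null_space(chain_network)
        assert ns.dim == 1
        col = ns.basis[:, 0]
        assert np.allclose(col, col[0])  # (1,1,1) up to scale

    def test_parallel_routes_kernel_dimension(self, parallel_network):
        assert p.null_space(parallel_network).dim == 2

    def test_random_networks_kernel_property(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            m, n = rng.integers(2, 6), rng.integers(3, 9)
            S = rng.integers(-2, 3, size=(m, n)).astype(float)
            mets = [p.Metabolite(f"M{i}") for i in range(m)]
            rxns = [
                p.Reaction(f"r{j}", {f"M{i}": S[i, j] for i in range(m) if S[i, j]},
                           -10, 10)
                for j in range(n)
            ]
            net = p.build_network(mets, rxns)
            ns = p.null_space(net)
            if ns.dim:
                f = rng.normal(size=ns.dim)
                v = ns.basis @ f
                assert np.max(np.abs(net.S @ v)) <= 1e-9 * max(1, np.abs(v).max())

    def test_free_rows_are_identity(self, parallel_network):
        ns = p.null_space(parallel_network)
        idx = [parallel_network.rxn_index[r] for r in ns.free_flux_ids]
        assert np.allclose(ns.basis[idx, :], np.eye(ns.dim))


class TestFluxFromFree:
    def test_zero_free_gives_zero_flux(self, chain_network):
        ns = p.null_space(chain_network)
        assert np.allclose(p.flux_from_free(ns, np.zeros(ns.dim)).v, 0)

    def test_chain_scaling(self, chain_network):
        ns = p.null_space(chain_network)
        v = p.flux_from_free(ns, [2.0]).v
        assert np.allclose(v, 2.0)

    def test_dimension_mismatch(self, chain_network):
        ns = p.null_space(chain_network)
        with pytest.raises(ValueError):
            p.flux_from_free(ns, [1.0, 2.0])


class TestFluxVariability:
    def test_determined_chain(self, chain_network):
        for fr in p.flux_variability(chain_network):
            assert fr.vmin == pytest.approx(1.0, abs=1e-7)
            assert fr.vmax == pytest.approx(1.0, abs=1e-7)

    def test_parallel_branches_span_uptake(self, parallel_network):
        ranges = {fr.reaction_id: fr for fr in p.flux_variability(parallel_network)}
        for b in ("b1", "b2"):
            assert ranges[b].vmin == pytest.approx(0.0, abs=1e-7)
            assert ranges[b].vmax == pytest.approx(1.0, abs=1e-7)

    def test_closed_network_all_zero(self):
        net = p.build_network(
            [p.Metabolite("A"), p.Metabolite("B")],
            [p.Reaction("r", {"A": -1, "B": 1}, 0, 0)],
        )
        fr = p.flux_variability(net)[0]
        assert fr.vmin == fr.vmax == 0.0

    def test_ranges_contain_sampled_feasible_fluxes(self, parallel_network):
        ranges = {fr.reaction_id: fr for fr in p.flux_variability(parallel_network)}
        rids = [r.id for r in parallel_network.reactions]
        route1 = np.array([1.0, 1.0, 0.0, 1.0])  # upt, b1, b2, exp
        route2 = np.array([1.0, 0.0, 1.0, 1.0])
        rng = np.random.default_rng(3)
        for a in rng.uniform(0, 1, 50):
            v = a * route1 + (1 - a) * route2  # feasible by convexity
            assert np.allclose(parallel_network.S @ v, 0)
            for rid, x in zip(rids, v):
                assert ranges[rid].vmin - 1e-6 <= x <= ranges[rid].vmax + 1e-6


class TestWeightedFluxMinimization:
    def test_parallel_uniform_weights(self, parallel_network):
        flux, obj = p.minimize_weighted_flux_lp(parallel_network)
        # uptake + one branch + export
        assert obj == pytest.approx(3.0, abs=1e-6)
        assert flux["b1"] + flux["b2"] == pytest.approx(1.0, abs=1e-6)

    def test_weight_steers_branch_choice(self, parallel_network):
        w = np.array([1.0, 1.0, 3.0, 1.0])  # upt, b1, b2, exp
        flux, obj = p.minimize_weighted_flux_lp(parallel_network, w)
        assert flux["b1"] == pytest.approx(1.0, abs=1e-6)
        assert flux["b2"] == pytest.approx(0.0, abs=1e-6)
        assert obj == pytest.approx(3.0, abs=1e-6)

    def test_unforced_cycle_is_silent(self):
        net = p.build_network(
            [p.Metabolite("A"), p.Metabolite("B")],
            [
                p.Reaction("f", {"A": -1, "B": 1}, 0, 10),
                p.Reaction("b", {"B": -1, "A": 1}, 0, 10),
            ],
        )
        flux, obj = p.minimize_weighted_flux_lp(net)
        assert obj == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(flux.v, 0, atol=1e-9)

    def test_solver_solution_feasibility_invariant(self, parallel_network):
        flux, _ = p.minimize_weighted_flux_lp(parallel_network)
        net = parallel_network
        assert np.max(np.abs(net.S @ flux.v)) <= 1e-6 * max(1, np.abs(flux.v).max())
        assert np.all(flux.v >= net.lb - 1e-6) and np.all(flux.v <= net.ub + 1e-6)

    def test_optimum_bounds_random_feasible_points(self, parallel_network):
        """pFBA optimum is <= the flux sum of any feasible point, including
        points carrying futile branch recycling."""
        _, obj = p.minimize_weighted_flux_lp(parallel_network)
        route1 = np.array([1.0, 1.0, 0.0, 1.0])  # upt, b1, b2, exp
        route2 = np.array([1.0, 0.0, 1.0, 1.0])
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = rng.uniform(0, 1)
            v = a * route1 + (1 - a) * route2
            assert obj <= np.abs(v).sum() + 1e-9

    def test_infeasible_network_reported(self):
        net = p.build_network(
            [p.Metabolite("A")],
            [p.Reaction("in_", {"A": 1}, 1, 1), p.Reaction("out", {"A": -1}, 0, 0.5)],
        )
        with pytest.raises(p.InfeasibleNetworkError):
            p.minimize_weighted_flux_lp(net)

    def test_split_bounds_nonnegative(self, parallel_network):
        ub_f, ub_r = _split_bounds(parallel_network)
        assert (ub_f >= 0).all() and (ub_r >= 0).all()
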