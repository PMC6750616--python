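"""EMU decomposition, label simulation, pool dilution and the isotopomer oracle."""

import numpy as np
import pytest

import p13cmfa as p
from p13cmfa.atommap import parse_transition_equation
from p13cmfa.isotopomer import fragment_mass_distribution


def oracle_fragments(fx: p.Fixture, flux=None):
    """Brute-force mass distributions of the fixture's target fragments."""
    flux = flux if flux is not None else fx.truth_flux
    iso = p.brute_force_isotopomer(
        fx.net, fx.transitions, flux, fx.tracers,
        extra_inputs={t.metabolite for t in fx.tracers},
    )
    out = {}
    for frag in fx.fragments:
        mid, atoms = p.parse_fragment(fx.net, frag)
        out[frag] = fragment_mass_distribution(
            iso[mid], fx.net.metabolite(mid).n_carbons, atoms
        ).fractions
    return out


def emu_fragments(fx: p.Fixture, flux=None, dilutions=None, net=None):
    net = net or fx.net
    flux = flux if flux is not None else fx.truth_flux
    targets = {f: p.parse_fragment(net, f) for f in fx.fragments}
    system = p.decompose_to_emu(
        net, fx.transitions, targets,
        extra_inputs={t.metabolite for t in fx.tracers},
    )
    lab = p.simulate_labeling(system, flux, fx.tracers, dilutions)
    return {f: lab[f].fractions for f in fx.fragments}


class TestAtomTransitions:
    def test_letter_mapped_cleavage(self):
        tr = parse_transition_equation("ald", "fbp[abcdef] -> dhap[cba] + gap[def]")
        assert tr.source_of(0, 1) == (0, 3)  # dhap C1 <- fbp C3
        assert tr.source_of(1, 1) == (0, 4)  # gap C1 <- fbp C4

    def test_unbalanced_letters_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            parse_transition_equation("r", "a6[abcdef] -> p5[abcde]")

    def test_repeated_letter_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            parse_transition_equation("r", "a2[aa] -> b2[aa]")

    def test_carbon_count_validation(self, chain_network):
        tr = parse_transition_equation("r2", "A[ab] -> B[ab]")  # A has 1 carbon
        with pytest.raises(ValueError, match="carbons"):
            p.validate_transitions(chain_network, [tr])


class TestDecomposition:
    def test_condensation_toy_minimal_emus(self, fixtures):
        fx = fixtures["s1fig_condensation"]
        targets = {"Cab": ("Cab", (1, 2))}
        system = p.decompose_to_emu(
            fx.net, fx.transitions, targets,
            extra_inputs={t.metabolite for t in fx.tracers},
        )
        internal = {str(e) for e in system.all_emus()}
        assert "Cab{1,2}" in internal
        assert any(tr.condensation for tr in system.transitions)
        # mono-carbon precursors appear as size-1 EMUs
        assert {str(e) for e in system.emus_by_size[1]} == {"Ca{1}", "Cb{1}"}

    def test_identity_chain_one_emu_per_metabolite(self, fixtures):
        fx = fixtures["futile_cycle"]
        system = p.decompose_to_emu(
            fx.net, fx.transitions, {"B": ("B", (1, 2))},
            extra_inputs={t.metabolite for t in fx.tracers},
        )
        assert not any(tr.condensation for tr in system.transitions)
        assert all(e.size == 2 for e in system.all_emus())

    def test_cleavage_tracks_only_needed_subset(self):
        """A 2-carbon product of a 3-carbon cleavage needs only the matching
        2-carbon EMU of the precursor (checked against subset reachability)."""
        net = p.build_network(
            [
                p.Metabolite("Sext", compartment="e", n_carbons=3, is_boundary=True),
                p.Metabolite("S", n_carbons=3),
                p.Metabolite("P1", n_carbons=1),
                p.Metabolite("P2", n_carbons=2),
                p.Metabolite("P2ext", compartment="e", n_carbons=2, is_boundary=True),
            ],
            [
                p.Reaction("upt", {"Sext": -1, "S": 1}, 1, 1),
                p.Reaction("clv", {"S": -1, "P1": 1, "P2": 1}, 0, 10),
                p.Reaction("exp", {"P2": -1, "P2ext": 1}, 0, 10),
            ],
        )
        trs = [
            parse_transition_equation("upt", "Sext[abc] -> S[abc]"),
            parse_transition_equation("clv", "S[abc] -> P1[a] + P2[bc]"),
            parse_transition_equation("exp", "P2[ab] -> P2ext[ab]"),
        ]
        system = p.decompose_to_emu(net, trs, {"P2": ("P2", (1, 2))})
        sizes = {str(e): e.size for e in system.all_emus()}
        assert sizes == {"P2{1,2}": 2, "S{2,3}": 2}

    def test_orphan_metabolite_is_an_error(self):
        net = p.build_network(
            [p.Metabolite("X", n_carbons=1)],
            [p.Reaction("out", {"X": -1}, 0, 1)],
        )
        with pytest.raises(ValueError, match="no producing"):
            p.decompose_to_emu(net, [], {"X": ("X", (1,))})


class TestSimulateLabeling:
    def test_pure_m1_condensation(self, fixtures):
        fx = fixtures["s1fig_condensation"]
        tracers = [
            p.TracerSpec("Ca_e", [("1", 1.0)]),
            p.TracerSpec("Cb_e", [("0", 1.0)]),
        ]
        targets = {"Cab": ("Cab", (1, 2))}
        system = p.decompose_to_emu(
            fx.net, fx.transitions, targets, extra_inputs={"Ca_e", "Cb_e"}
        )
        lab = p.simulate_labeling(system, fx.truth_flux, tracers)
        assert np.allclose(lab["Cab"].fractions, [0.0, 1.0, 0.0])

    def test_half_labeled_condensation_binomial(self, fixtures):
        fx = fixtures["s1fig_condensation"]
        got = emu_fragments(fx)["Cab"]
        assert np.allclose(got, [0.25, 0.50, 0.25], atol=1e-12)

    def test_two_route_linear_mixing(self):
        """70:30 mix of a labeled and an unlabeled route into one pool."""
        net = p.build_network(
            [
                p.Metabolite("L_e", compartment="e", n_carbons=1, is_boundary=True),
                p.Metabolite("U_e", compartment="e", n_carbons=1, is_boundary=True),
                p.Metabolite("P", n_carbons=1),
                p.Metabolite("P_e", compartment="e", n_carbons=1, is_boundary=True),
            ],
            [
                p.Reaction("rl", {"L_e": -1, "P": 1}, 0.7, 0.7),
                p.Reaction("ru", {"U_e": -1, "P": 1}, 0.3, 0.3),
                p.Reaction("out", {"P": -1, "P_e": 1}, 0, 10),
            ],
        )
        trs = [
            parse_transition_equation("rl", "L_e[a] -> P[a]"),
            parse_transition_equation("ru", "U_e[a] -> P[a]"),
            parse_transition_equation("out", "P[a] -> P_e[a]"),
        ]
        tracers = [p.TracerSpec("L_e", [("1", 1.0)])]
        system = p.decompose_to_emu(net, trs, {"P": ("P", (1,))}, {"L_e"})
        flux = p.FluxVector(["rl", "ru", "out"], [0.7, 0.3, 1.0])
        lab = p.simulate_labeling(system, flux, tracers)
        assert np.allclose(lab["P"].fractions, [0.3, 0.7], atol=1e-12)

    def test_zero_inflow_reported_with_emu(self, fixtures):
        fx = fixtures["s1fig_condensation"]
        targets = {"Cab": ("Cab", (1, 2))}
        system = p.decompose_to_emu(
            fx.net, fx.transitions, targets,
            extra_inputs={t.metabolite for t in fx.tracers},
        )
        dead = p.FluxVector(fx.truth_flux.reaction_ids, np.zeros(4))
        with pytest.raises(p.SingularLabelingError):
            p.simulate_labeling(system, dead, fx.tracers)

    def test_flux_scaling_invariance(self, fixtures):
        for name in ("reversible_exchange", "mini_ppp"):
            fx = fixtures[name]
            base = emu_fragments(fx)
            scaled_flux = p.FluxVector(
                fx.truth_flux.reaction_ids, 3.7 * fx.truth_flux.v, 3.7 * fx.truth_flux.t
            )
            scaled = emu_fragments(fx, scaled_flux)
            for f in fx.fragments:
                assert np.allclose(base[f], scaled[f], atol=1e-12)

    def test_unlabeled_tracer_gives_pure_m0(self, fixtures):
        fx = fixtures["mini_ppp"]
        tracers = [p.TracerSpec("Hex_e", [("000000", 1.0)])]
        targets = {f: p.parse_fragment(fx.net, f) for f in fx.fragments}
        system = p.decompose_to_emu(
            fx.net, fx.transitions, targets, extra_inputs={"Hex_e"}
        )
        lab = p.simulate_labeling(system, fx.truth_flux, tracers)
        vec = lab["Rib"].fractions
        assert vec[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(vec[1:] <= 1e-12)

    def test_distributions_normalized(self, fixtures, specs):
        for name, fx in fixtures.items():
            for seed in (2, 3):
                x = p.sample_initial_population(specs[name], 1, seed)[0]
                flux = specs[name].decode(x)
                lab = emu_fragments(fx, flux)
                for vec in lab.values():
                    assert vec.sum() == pytest.approx(1.0, abs=1e-9)
                    assert np.all(vec >= -1e-12) and np.all(vec <= 1 + 1e-12)


class TestOracleEquivalence:
    def test_truth_fluxes_match_oracle(self, fixtures):
        for name, fx in fixtures.items():
            got = emu_fragments(fx)
            want = oracle_fragments(fx)
            for f in fx.fragments:
                assert np.max(np.abs(got[f] - want[f])) <= 1e-8, (name, f)

    def test_random_fluxes_match_oracle(self, fixtures, specs):
        """EMU result equals the isotopomer oracle at sampled feasible fluxes
        including nonzero turnover on reversible reactions."""
        for name, fx in fixtures.items():
            spec = specs[name]
            for i, x in enumerate(p.sample_initial_population(spec, 5, seed=17)):
                flux = spec.decode(x)
                got = emu_fragments(fx, flux)
                want = oracle_fragments(fx, flux)
                for f in fx.fragments:
                    assert np.max(np.abs(got[f] - want[f])) <= 1e-8, (name, f, i)

    def test_marginalization_consistency(self, fixtures):
        """Size-1 EMU distributions equal marginals of the full-molecule
        oracle distributions."""
        fx = fixtures["mini_ppp"]
        iso = p.brute_force_isotopomer(
            fx.net, fx.transitions, fx.truth_flux, fx.tracers,
            extra_inputs={t.metabolite for t in fx.tracers},
        )
        for atom in range(1, 6):
            targets = {f"Rib@{atom}": ("Rib", (atom,))}
            system = p.decompose_to_emu(
                fx.net, fx.transitions, targets,
                extra_inputs={t.metabolite for t in fx.tracers},
            )
            lab = p.simulate_labeling(system, fx.truth_flux, fx.tracers)
            want = fragment_mass_distribution(iso["Rib"], 5, (atom,)).fractions
            assert np.max(np.abs(lab[f"Rib@{atom}"].fractions - want)) <= 1e-8

    def test_transport_invariance(self, fixtures):
        """Identity mappings transport the tracer distribution unchanged."""
        fx = fixtures["futile_cycle"]
        got = emu_fragments(fx)["B"]
        assert np.allclose(got, [0.5, 0.0, 0.5], atol=1e-10)


class TestPoolDilution:
    @pytest.fixture()
    def diluted(self, fixtures):
        fx = fixtures["s1fig_condensation"]
        net2, dil = p.add_pool_dilution(fx.net, "Cab", ub=1000.0)
        return fx, net2, dil

    def _labeling(self, fx, net2, dil, d):
        flux = p.FluxVector(
            [r.id for r in net2.reactions], np.concatenate([fx.truth_flux.v, [d]])
        )
        return emu_fragments(fx, flux, dilutions=[dil], net=net2)["Cab"]

    def test_zero_dilution_is_identity(self, diluted):
        fx, net2, dil = diluted
        assert np.allclose(self._labeling(fx, net2, dil, 0.0), [0.25, 0.5, 0.25])

    def test_large_dilution_approaches_unlabeled(self, diluted):
        fx, net2, dil = diluted
        vec = self._labeling(fx, net2, dil, 1000.0)
        assert vec[0] > 0.999

    def test_equal_mix_is_arithmetic_mean(self, diluted):
        """d equal to the production flux gives a 50:50 mix with m0."""
        fx, net2, dil = diluted
        vec = self._labeling(fx, net2, dil, 1.0)
        expect = 0.5 * np.array([0.25, 0.5, 0.25]) + 0.5 * np.array([1.0, 0, 0])
        assert np.allclose(vec, expect, atol=1e-12)

    def test_duplicate_dilution_rejected(self, diluted):
        _fx, net2, _dil = diluted
        with pytest.raises(ValueError, match="already"):
            p.add_pool_dilution(net2, "Cab")

    def test_oracle_agrees_with_dilution(self, diluted):
        fx, net2, dil = diluted
        flux = p.FluxVector(
            [r.id for r in net2.reactions], np.concatenate([fx.truth_flux.v, [0.6]])
        )
        got = emu_fragments(fx, flux, dilutions=[dil], net=net2)["Cab"]
        iso = p.brute_force_isotopomer(
            net2, fx.transitions, flux, fx.tracers,
            dilutions=[dil], extra_inputs={t.metabolite for t in fx.tracers},
        )
        want = fragment_mass_distribution(iso["Cab"], 2).fractions
        assert np.max(np.abs(got - want)) <= 1e-8
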