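"""Core bond-graph compilation: potentials, fluxes, moieties, dissipation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import genebond as gb
from genebond.errors import (
    ConfigurationError,
    StateError,
    UnsupportedLawError,
)


class TestChemicalPotential:
    @pytest.mark.parametrize(
        "K, x, expected",
        [(2.0, 3.0, math.log(6.0)), (1.0, 1.0, 0.0), (0.5, 8.0, math.log(4.0))],
    )
    def test_values(self, K, x, expected):
        assert gb.chemical_potential(K, x) == pytest.approx(expected, abs=1e-14)

    def test_equal_products_give_equal_potentials(self):
        assert gb.chemical_potential(2.0, 3.0) == gb.chemical_potential(3.0, 2.0)

    @pytest.mark.parametrize("K, x", [(1.0, 0.0), (1.0, -1.0), (0.0, 1.0), (-2.0, 1.0)])
    def test_domain_errors(self, K, x):
        with pytest.raises(gb.GenebondError):
            gb.chemical_potential(K, x)


class TestReactionFlux:
    def test_direct_evaluation(self):
        assert gb.reaction_flux(2.0, math.log(3.0), math.log(2.0)) == pytest.approx(2.0)

    def test_equilibrium_is_zero(self):
        assert gb.reaction_flux(5.0, 1.234, 1.234) == 0.0

    def test_sign_follows_potential_drop(self):
        assert gb.reaction_flux(1.0, 1.0, 0.0) > 0
        assert gb.reaction_flux(1.0, 0.0, 1.0) < 0

    def test_mass_action_expansion(self):
        # r (e^(muA+muB) - e^muC) == kf xA xB - kr xC with kf = KA KB, kr = KC
        KA, KB, KC = 2.0, 3.0, 5.0
        xA, xB, xC = 0.7, 1.3, 0.2
        mu_f = math.log(KA * xA) + math.log(KB * xB)
        mu_r = math.log(KC * xC)
        v = gb.reaction_flux(1.0, mu_f, mu_r)
        assert v == pytest.approx(KA * KB * xA * xB - KC * xC, rel=1e-12)

    def test_overflow_reported(self):
        with pytest.raises(StateError):
            gb.reaction_flux(1.0, 1e4, 0.0)


class TestRateField:
    def test_worked_example_derivatives(self, fig_example_net):
        # dxA = -v1, dxB = -v1, dxC = v1 - v2, dxD = 2 v2 with the
        # Marcelin-de Donder fluxes written out by hand
        net = fig_example_net
        x = np.array([0.9, 1.1, 0.5, 0.2])
        KA, KB, KC, KD = 1.0, 2.0, 3.0, 4.0
        v1 = 1.5 * (KA * x[0] * KB * x[1] - KC * x[2])
        v2 = 0.7 * (KC * x[2] - (KD * x[3]) ** 2)
        expected = np.array([-v1, -v1, v1 - v2, 2 * v2])
        rhs = net.rate_field()
        np.testing.assert_allclose(rhs(0.0, x), expected, rtol=1e-12)

    def test_equilibrium_state_is_fixed_point(self, fig_example_net):
        # all potentials equal across each reaction: x_i = 1/K_i balances
        # K_A x_A K_B x_B = K_C x_C = (K_D x_D)^2 when every activity is 1
        x = 1.0 / np.array([1.0, 2.0, 3.0, 4.0])
        rhs = fig_example_net.rate_field()
        np.testing.assert_allclose(rhs(0.0, x), 0.0, atol=1e-13)

    def test_detailed_balance_independent_of_rates(self):
        # Wegscheider consistency: the balanced state stays fixed for any r_j
        for r1, r2 in [(0.3, 9.0), (5.0, 0.01), (1.0, 1.0)]:
            net = gb.NetworkSpec(
                [
                    gb.SpeciesSpec("A", K=1.5, x0=1.0),
                    gb.SpeciesSpec("B", K=2.5, x0=1.0),
                    gb.SpeciesSpec("C", K=3.5, x0=1.0),
                    gb.SpeciesSpec("D", K=4.5, x0=1.0),
                ],
                [
                    gb.ReactionSpec("r1", r1, {"A": 1, "B": 1}, {"C": 1}),
                    gb.ReactionSpec("r2", r2, {"C": 1}, {"D": 2}),
                ],
            )
            x = 1.0 / np.array([1.5, 2.5, 3.5, 4.5])
            np.testing.assert_allclose(net.rate_field()(0.0, x), 0.0, atol=1e-13)

    def test_chemostat_row_zeroed_but_contributes_flux(self):
        net = gb.NetworkSpec(
            [
                gb.SpeciesSpec("A", K=1.0, x0=5.0, kind="chemostat_amount"),
                gb.SpeciesSpec("B", K=1.0, x0=0.1),
            ],
            [gb.ReactionSpec("r", 1.0, {"A": 1}, {"B": 1})],
        )
        f = net.rate_field()(0.0, net.initial_state())
        assert f[0] == 0.0
        assert f[1] == pytest.approx(5.0 - 0.1)

    def test_potential_clamp_contributes_clamped_activity(self):
        net = gb.NetworkSpec(
            [
                gb.SpeciesSpec("S", K=2.0, x0=1.0),
                gb.SpeciesSpec("Z", K=1.0, kind="chemostat_potential", mu_clamp=-3.0),
            ],
            [gb.ReactionSpec("r", 1.0, {"S": 1}, {"Z": 1})],
        )
        v = net.fluxes(net.initial_state())
        assert v[0] == pytest.approx(2.0 - math.exp(-3.0), rel=1e-12)

    def test_zero_amount_kills_forward_term(self):
        net = gb.NetworkSpec(
            [gb.SpeciesSpec("A", K=1.0, x0=0.0), gb.SpeciesSpec("B", K=1.0, x0=2.0)],
            [gb.ReactionSpec("r", 1.0, {"A": 1}, {"B": 1})],
        )
        assert net.fluxes(net.initial_state())[0] == pytest.approx(-2.0)

    def test_unknown_law_rejected(self):
        with pytest.raises(ConfigurationError):
            gb.ReactionSpec("r", 1.0, {"A": 1}, {"B": 1}, law="michaelis")


class TestToMassAction:
    def test_printed_relation(self):
        net = gb.NetworkSpec(
            [
                gb.SpeciesSpec("A", K=3.0, x0=1.0),
                gb.SpeciesSpec("B", K=5.0, x0=1.0),
                gb.SpeciesSpec("C", K=7.0, x0=1.0),
            ],
            [gb.ReactionSpec("r", 2.0, {"A": 1, "B": 1}, {"C": 1})],
        )
        (kf, kr), = net.to_mass_action()
        assert kf == pytest.approx(30.0)
        assert kr == pytest.approx(14.0)

    def test_squared_stoichiometry(self, fig_example_net):
        kf, kr = fig_example_net.to_mass_action()[1]
        assert kf == pytest.approx(0.7 * 3.0)
        assert kr == pytest.approx(0.7 * 4.0**2)

    def test_unit_constants_identity(self):
        net = gb.NetworkSpec(
            [gb.SpeciesSpec("A", K=1.0, x0=1.0), gb.SpeciesSpec("B", K=1.0, x0=1.0)],
            [gb.ReactionSpec("r", 2.5, {"A": 1}, {"B": 1})],
        )
        assert net.to_mass_action() == [(2.5, 2.5)]

    def test_non_mass_action_rejected(self):
        net = gb.NetworkSpec(
            [
                gb.SpeciesSpec("C1", K=1.0, x0=1.0),
                gb.SpeciesSpec("Cn", K=1.0, x0=1.0),
                gb.SpeciesSpec("A", K=1.0, x0=1.0),
            ],
            [
                gb.ReactionSpec(
                    "el",
                    1.0,
                    {"C1": 1, "A": 2},
                    {"Cn": 1},
                    law="elongation",
                    law_params={"kf": 1.0, "kr": 1.0, "m": 2, "energy": "A"},
                )
            ],
        )
        with pytest.raises(UnsupportedLawError):
            net.to_mass_action()


@st.composite
def random_mass_action_network(draw):
    n_species = draw(st.integers(2, 6))
    n_reactions = draw(st.integers(1, 5))
    names = [f"S{i}" for i in range(n_species)]
    pos = st.floats(0.1, 10.0, allow_nan=False)
    species = [gb.SpeciesSpec(n, K=draw(pos), x0=draw(pos)) for n in names]
    reactions = []
    for j in range(n_reactions):
        fwd_names = draw(st.lists(st.sampled_from(names), min_size=1, max_size=2, unique=True))
        rev_pool = [n for n in names if n not in fwd_names]
        if not rev_pool:
            continue
        rev_names = draw(
            st.lists(st.sampled_from(rev_pool), min_size=1, max_size=2, unique=True)
        )
        fwd = {n: draw(st.integers(1, 2)) for n in fwd_names}
        rev = {n: draw(st.integers(1, 2)) for n in rev_names}
        reactions.append(gb.ReactionSpec(f"r{j}", draw(pos), fwd, rev))
    if not reactions:
        reactions.append(gb.ReactionSpec("r0", 1.0, {names[0]: 1}, {names[1]: 1}))
    return gb.NetworkSpec(species, reactions)


class TestMassActionEquivalence:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(net=random_mass_action_network(), seed=st.integers(0, 2**31 - 1))
    def test_bond_graph_flux_equals_standard_mass_action(self, net, seed):
        rng = np.random.default_rng(seed)
        constants = net.to_mass_action()
        for _ in range(10):
            x = rng.uniform(0.1, 10.0, net.n_species)
            v = net.fluxes(x)
            for j, (kf, kr) in enumerate(constants):
                expected = kf * np.prod(x ** net.Sf[:, j]) - kr * np.prod(x ** net.Sr[:, j])
                assert v[j] == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(net=random_mass_action_network(), seed=st.integers(0, 2**31 - 1))
    def test_second_law_at_random_states(self, net, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            x = rng.uniform(0.1, 10.0, net.n_species)
            assert np.all(net.power_dissipation(x) >= -1e-12)


class TestConservedMoieties:
    def test_worked_example_basis_span(self, fig_example_net):
        # conservation laws 2A + 2C + D and 2B + 2C + D
        basis = fig_example_net.conserved_moieties()
        assert len(basis) == 2
        target = np.array([[2.0, 0.0, 2.0, 1.0], [0.0, 2.0, 2.0, 1.0]])
        # each target vector must lie in the span of the returned basis
        B = np.array(basis).T
        for t in target:
            coef, res, *_ = np.linalg.lstsq(B, t, rcond=None)
            assert np.allclose(B @ coef, t, atol=1e-10)
        for g in basis:
            assert np.allclose(g @ fig_example_net.N, 0.0, atol=1e-12)

    def test_two_species_exchange(self):
        net = gb.NetworkSpec(
            [gb.SpeciesSpec("A", K=1.0, x0=1.0), gb.SpeciesSpec("B", K=2.0, x0=0.0)],
            [gb.ReactionSpec("r", 1.0, {"A": 1}, {"B": 1})],
        )
        (g,) = net.conserved_moieties()
        np.testing.assert_allclose(g, [1.0, 1.0])

    def test_chemostat_breaks_conservation(self):
        net = gb.NetworkSpec(
            [
                gb.SpeciesSpec("A", K=1.0, x0=1.0, kind="chemostat_amount"),
                gb.SpeciesSpec("B", K=2.0, x0=0.0),
            ],
            [gb.ReactionSpec("r", 1.0, {"A": 1}, {"B": 1})],
        )
        assert net.conserved_moieties() == []

    def test_moieties_constant_along_trajectory(self, fig_example_net):
        x0 = np.array([1.0, 1.0, 0.0, 0.0])
        tc = gb.integrate(fig_example_net, x0, t_span=(0.0, 50.0))
        for g in fig_example_net.conserved_moieties():
            totals = tc.states @ g
            assert np.max(np.abs(totals - totals[0])) <= 1e-6 * abs(totals[0])


class TestPowerDissipation:
    def test_single_reaction_value(self):
        # r=1, mu_f=1, mu_r=0 -> (1-0)*(e-1)
        net = gb.NetworkSpec(
            [
                gb.SpeciesSpec("A", K=1.0, x0=math.e),
                gb.SpeciesSpec("B", K=1.0, x0=1.0),
            ],
            [gb.ReactionSpec("r", 1.0, {"A": 1}, {"B": 1})],
        )
        d = net.power_dissipation(net.initial_state())
        assert d[0] == pytest.approx(math.e - 1.0, rel=1e-12)

    def test_reversed_potentials_still_positive(self):
        net = gb.NetworkSpec(
            [
                gb.SpeciesSpec("A", K=1.0, x0=1.0),
                gb.SpeciesSpec("B", K=1.0, x0=math.e),
            ],
            [gb.ReactionSpec("r", 1.0, {"A": 1}, {"B": 1})],
        )
        d = net.power_dissipation(net.initial_state())
        assert d[0] == pytest.approx(math.e - 1.0, rel=1e-12)

    def test_equilibrium_dissipation_zero(self, fig_example_net):
        x = 1.0 / np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(fig_example_net.power_dissipation(x), 0.0, atol=1e-12)


class TestValidation:
    def test_unknown_species_in_reaction(self):
        with pytest.raises(ConfigurationError):
            gb.NetworkSpec(
                [gb.SpeciesSpec("A", K=1.0, x0=1.0)],
                [gb.ReactionSpec("r", 1.0, {"A": 1}, {"Z": 1})],
            )

    def test_non_integer_stoichiometry_rejected(self):
        with pytest.raises(ConfigurationError):
            gb.ReactionSpec("r", 1.0, {"A": 1.5}, {"B": 1})

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            gb.ReactionSpec("r", -1.0, {"A": 1}, {"B": 1})

    def test_clamp_requires_mu(self):
        with pytest.raises(ConfigurationError):
            gb.SpeciesSpec("A", K=1.0, kind="chemostat_potential")
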