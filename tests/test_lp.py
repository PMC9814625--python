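import numpy as np
import pytest

from contextflux.lp import (
    AbsFluxCap,
    InfeasibleModelError,
    LinearConstraint,
    LPSettings,
    UnboundedModelError,
    fba,
    fva,
    weighted_pfba,
)
from contextflux.network import MetabolicNetwork
from contextflux.transcripts import ReactionWeights
from oracles import (
    brute_force_fba,
    brute_force_weighted_l1_min,
    random_network,
    to_cobra,
)


def _mass_balance_residual(network, dist):
    S = network.stoichiometric_matrix()
    v = dist.as_array(network.reaction_ids)
    return float(np.max(np.abs(S @ v))) if S.size else 0.0


class TestFBA:
    def test_uptake_bound_forces_optimum(self, parallel_network):
        dist = fba(parallel_network)
        assert dist.objective_value == pytest.approx(10.0, abs=1e-8)
        assert _mass_balance_residual(parallel_network, dist) < 1e-6
        lb, ub = parallel_network.bounds_arrays()
        v = dist.as_array(parallel_network.reaction_ids)
        assert np.all(v >= lb - 1e-8) and np.all(v <= ub + 1e-8)

    def test_infeasible_model_raises(self, parallel_network):
        net = parallel_network.copy()
        # force flux into a metabolite nothing can consume
        net.lower_bound["uptake"] = 5.0
        net.upper_bound["R1"] = 0.0
        net.upper_bound["R2"] = 0.0
        net.upper_bound["bio"] = 0.0
        with pytest.raises(InfeasibleModelError):
            fba(net)

    def test_unbounded_objective_raises(self, parallel_network):
        net = parallel_network.copy()
        net.upper_bound["uptake"] = float("inf")
        net.upper_bound["R1"] = float("inf")
        net.upper_bound["bio"] = float("inf")
        with pytest.raises(UnboundedModelError):
            fba(net)

    def test_matches_vertex_enumeration_on_random_networks(self):
        """FBA optimum equals the brute-force vertex-enumeration oracle
        on 100 random bounded networks."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            net = random_network(rng, freedom=int(rng.integers(1, 4)))
            assert fba(net).objective_value == pytest.approx(
                brute_force_fba(net), abs=1e-6
            )

    def test_matches_cobra_on_toy(self, parallel_network):
        model = to_cobra(parallel_network)
        assert fba(parallel_network).objective_value == pytest.approx(
            model.slim_optimize(), abs=1e-6
        )


class TestFVA:
    def test_parallel_routes_full_range_at_fixed_objective(self, parallel_network):
        ranges = fva(
            parallel_network,
            [LinearConstraint({"bio": 1.0}, "==", 10.0)],
        )
        assert ranges["R1"] == pytest.approx((0.0, 10.0), abs=1e-7)
        assert ranges["R2"] == pytest.approx((0.0, 10.0), abs=1e-7)
        assert ranges["uptake"] == pytest.approx((10.0, 10.0), abs=1e-7)

    def test_bound_fixed_reaction(self, parallel_network):
        net = parallel_network.copy()
        net.lower_bound["R1"] = 2.0
        net.upper_bound["R1"] = 2.0
        ranges = fva(net, reactions=["R1"])
        assert ranges["R1"] == pytest.approx((2.0, 2.0), abs=1e-8)

    def test_infeasible_constraints_raise(self, parallel_network):
        with pytest.raises(InfeasibleModelError):
            fva(parallel_network, [LinearConstraint({"bio": 1.0}, ">=", 11.0)])

    def test_ranges_bracket_random_feasible_points(self, parallel_network):
        """Any feasible point (here: convex combinations of FVA vertices)
        lies inside the FVA box."""
        ranges, vertices = fva(parallel_network, keep_vertices=True)
        rng = np.random.default_rng(5)
        V = np.array(vertices)
        for _ in range(1000):
            lam = rng.dirichlet(np.ones(V.shape[0]))
            point = lam @ V
            for j, rid in enumerate(parallel_network.reaction_ids):
                lo, hi = ranges[rid]
                assert lo - 1e-7 <= point[j] <= hi + 1e-7


class TestWeightedPFBA:
    def test_cheap_route_takes_all_flux(self, parallel_network):
        weights = ReactionWeights(
            weight={"uptake": 0.5, "R1": 0.1, "R2": 0.9, "bio": 0.5}
        )
        dist, parsimony = weighted_pfba(parallel_network, weights, fraction=1.0)
        assert dist.flux["R1"] == pytest.approx(10.0, abs=1e-6)
        assert dist.flux["R2"] == pytest.approx(0.0, abs=1e-6)
        # uptake 10*0.5 + R1 10*0.1 + bio 10*0.5 = 11
        assert parsimony == pytest.approx(11.0, abs=1e-6)

    def test_equal_weights_tie_splits_demand(self, parallel_network):
        weights = ReactionWeights(weight={r: 0.5 for r in parallel_network.reaction_ids})
        dist, parsimony = weighted_pfba(parallel_network, weights, fraction=1.0)
        assert dist.flux["R1"] + dist.flux["R2"] == pytest.approx(10.0, abs=1e-6)
        assert parsimony == pytest.approx(0.5 * 30.0, abs=1e-6)

    def test_fraction_one_pins_objective(self, parallel_network):
        weights = ReactionWeights(weight={r: 1.0 for r in parallel_network.reaction_ids})
        dist, _ = weighted_pfba(parallel_network, weights, fraction=1.0)
        assert dist.objective_value == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_bad_fraction_rejected(self, parallel_network, fraction):
        weights = ReactionWeights(weight={r: 1.0 for r in parallel_network.reaction_ids})
        with pytest.raises(ValueError, match="fraction"):
            weighted_pfba(parallel_network, weights, fraction=fraction)

    def test_unit_weights_match_brute_force_total_flux_min(self):
        """With unit weights, weighted pFBA reproduces classical pFBA:
        checked against orthant + vertex enumeration on random networks."""
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 30:
            net = random_network(rng, n_reactions=int(rng.integers(4, 7)), freedom=2)
            z = fba(net).objective_value
            if z < 0.5:
                continue
            weights = ReactionWeights(weight={r: 1.0 for r in net.reaction_ids})
            _, parsimony = weighted_pfba(net, weights, fraction=1.0)
            oracle = brute_force_weighted_l1_min(
                net, {r: 1.0 for r in net.reaction_ids}, floor=z
            )
            assert parsimony == pytest.approx(oracle, abs=1e-6)
            checked += 1

    def test_unit_weights_match_cobra_pfba(self):
        """Independent implementation cross-check: cobrapy's pFBA objective
        (total |flux| at the optimum) equals our unit-weight parsimony value."""
        cobra = pytest.importorskip("cobra")
        from cobra.flux_analysis import pfba

        rng = np.random.default_rng(29)
        checked = 0
        while checked < 10:
            net = random_network(rng, n_reactions=6, freedom=2)
            z = fba(net).objective_value
            if z < 0.5:
                continue
            weights = ReactionWeights(weight={r: 1.0 for r in net.reaction_ids})
            _, parsimony = weighted_pfba(net, weights, fraction=1.0)
            sol = pfba(to_cobra(net), fraction_of_optimum=1.0)
            assert parsimony == pytest.approx(sol.objective_value, abs=1e-5)
            checked += 1

    def test_relaxing_fraction_never_raises_parsimony(self, parallel_network):
        weights = ReactionWeights(
            weight={"uptake": 0.5, "R1": 0.2, "R2": 0.7, "bio": 0.3}
        )
        values = [
            weighted_pfba(parallel_network, weights, fraction=f)[1]
            for f in (1.0, 0.9, 0.8, 0.5)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_mass_balance_and_bounds_hold(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            net = random_network(rng, freedom=2)
            z = fba(net).objective_value
            if z < 0.5:
                continue
            weights = ReactionWeights(
                weight={r: float(rng.uniform(0, 1)) for r in net.reaction_ids}
            )
            dist, _ = weighted_pfba(net, weights, fraction=1.0)
            assert _mass_balance_residual(net, dist) < 1e-6
            lb, ub = net.bounds_arrays()
            v = dist.as_array(net.reaction_ids)
            assert np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7)


def test_settings_validation():
    with pytest.raises(ValueError):
        LPSettings(feasibility_tolerance=0.0)
    with pytest.raises(ValueError):
        LPSettings(parsimony_slack=1e-2)


def test_abs_flux_cap_restricts_fva(parallel_network):
    weights = {"uptake": 0.0, "R1": 0.0, "R2": 1.0, "bio": 0.0}
    ranges = fva(
        parallel_network,
        [
            LinearConstraint({"bio": 1.0}, ">=", 10.0),
            AbsFluxCap(weights, 2.0),
        ],
    )
    assert ranges["R2"] == pytest.approx((0.0, 2.0), abs=1e-7)
    assert ranges["R1"] == pytest.approx((8.0, 10.0), abs=1e-7)
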