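"""Shapley module tests.

The additive mock model (output = sum of per-atom weights over unmasked
atoms) provides analytic ground truth: the Shapley value of any substructure
equals the sum of its members' weights, for any molecule and any L.
"""

import itertools
from math import factorial

import numpy as np
import pytest

from toxgat import subgraph_shapley as ss
from toxgat.mol_graph import featurize
from toxgat.synthetic_bench import AdditiveAtomModel, atom_weight_vector


class _ConstantModel:
    def predict_graphs(self, graphs):
        return np.full(len(graphs), 4.2)


def connected_subsets(graph, max_size):
    """All connected atom subsets up to max_size (enumeration oracle)."""
    m = graph.num_atoms
    out = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(range(m), size):
            atoms = set(combo)
            seen = {combo[0]}
            frontier = [combo[0]]
            while frontier:
                u = frontier.pop()
                for v in np.flatnonzero(graph.adjacency[u]):
                    if int(v) in atoms and int(v) not in seen:
                        seen.add(int(v))
                        frontier.append(int(v))
            if seen == atoms:
                out.append(combo)
    return out


class TestBuildGame:
    def test_path7_gamma(self, path7):
        game = ss.build_game(path7, {0}, L=4, value_kind="regression-output")
        assert game.gamma == 4
        assert game.n_players == 5

    def test_whole_molecule_gamma_zero(self, benzene):
        game = ss.build_game(benzene, set(range(6)), L=4,
                             value_kind="regression-output")
        assert game.gamma == 0

    def test_far_atoms_excluded(self):
        g = featurize("C" * 12)
        game = ss.build_game(g, {0}, L=4, value_kind="regression-output")
        assert set(game.context_atoms) == {1, 2, 3, 4}
        # atoms 5..11 are not players, hence masked in every evaluation

    def test_disconnected_substructure_rejected(self, path7):
        with pytest.raises(ValueError, match="connected"):
            ss.build_game(path7, {0, 3}, L=4, value_kind="regression-output")

    def test_bad_value_kind(self, path7):
        with pytest.raises(ValueError):
            ss.build_game(path7, {0}, value_kind="nonsense")


class TestValueFunction:
    def test_constant_model(self, path7):
        model = _ConstantModel()
        game = ss.build_game(path7, {0}, L=2, value_kind="regression-output")
        values = {
            ss.value_function(model, game, e, flag)
            for e in [set(), {1}, {1, 2}]
            for flag in (True, False)
        }
        assert values == {4.2}

    def test_additive_partial_sum(self):
        g = featurize("CCOCC")
        w = np.array([1.0, 2.0, -3.0, 0.5, 0.25])
        model = AdditiveAtomModel(w)
        game = ss.build_game(g, {2}, L=4, value_kind="regression-output")
        assert ss.value_function(model, game, {0, 1}, True) == pytest.approx(
            w[[0, 1, 2]].sum()
        )
        assert ss.value_function(model, game, {0, 1}, False) == pytest.approx(
            w[[0, 1]].sum()
        )

    def test_empty_coalition_without_s(self):
        g = featurize("CCC")
        model = AdditiveAtomModel(np.array([1.0, 1.0, 1.0]), offset=7.0)
        game = ss.build_game(g, {0}, L=2, value_kind="regression-output")
        assert ss.value_function(model, game, set(), False) == pytest.approx(7.0)

    def test_coalition_outside_context_rejected(self, path7):
        game = ss.build_game(path7, {0}, L=1, value_kind="regression-output")
        with pytest.raises(ValueError):
            ss.value_function(_ConstantModel(), game, {6}, True)


class TestShapleyExact:
    def test_constant_model_phi_zero(self, benzene):
        game = ss.build_game(benzene, {0}, L=3, value_kind="regression-output")
        assert ss.shapley(_ConstantModel(), game).phi == pytest.approx(0.0)

    @pytest.mark.parametrize("smiles", ["CCO", "NC(=S)NCC", "c1ccncc1C"])
    def test_additive_exactness_all_substructures(self, smiles):
        g = featurize(smiles)
        w = atom_weight_vector(smiles)
        model = AdditiveAtomModel(w)
        for atoms in connected_subsets(g, max_size=3):
            game = ss.build_game(g, set(atoms), L=4,
                                 value_kind="regression-output")
            phi = ss.shapley(model, game).phi
            assert phi == pytest.approx(w[list(atoms)].sum(), abs=1e-9)

    def test_gamma_zero_is_difference(self):
        g = featurize("CCC")
        w = np.array([1.0, -2.0, 0.5])
        model = AdditiveAtomModel(w, offset=1.0)
        game = ss.build_game(g, {0, 1, 2}, L=4, value_kind="regression-output")
        res = ss.shapley(model, game)
        full = ss.value_function(model, game, set(), True)
        empty = ss.value_function(model, game, set(), False)
        assert res.phi == pytest.approx(full - empty)

    def test_cap_exceeded_advises_sampling(self):
        g = featurize("C" * 17)
        game = ss.build_game(g, {8}, L=8, value_kind="regression-output")
        with pytest.raises(ValueError, match="sampled"):
            ss.shapley(_ConstantModel(), game)

    def test_evaluation_count_bounded(self, path7):
        game = ss.build_game(path7, {0}, L=2, value_kind="regression-output")
        res = ss.shapley(_ConstantModel(), game)
        assert res.n_evaluations <= 2 ** game.n_players

    def test_matches_sequential_evaluation(self, random_model):
        """Batched result equals the textbook one-coalition-at-a-time sum."""
        g = featurize("CCOC")
        game = ss.build_game(g, {0}, L=3, value_kind="regression-output")
        res = ss.shapley(random_model, game)
        n = game.n_players
        phi = 0.0
        for size in range(game.gamma + 1):
            for combo in itertools.combinations(game.context_atoms, size):
                weight = factorial(size) * factorial(n - size - 1) / factorial(n)
                with_s = ss.value_function(random_model, game, set(combo), True)
                without = ss.value_function(random_model, game, set(combo), False)
                phi += weight * (with_s - without)
        assert res.phi == pytest.approx(phi, abs=1e-6)


class TestShapleySampled:
    def test_additive_zero_variance(self):
        g = featurize("CCCCO")
        w = atom_weight_vector("CCCCO")
        model = AdditiveAtomModel(w)
        game = ss.build_game(g, {1}, L=4, value_kind="regression-output")
        res = ss.shapley_sampled(model, game, n_permutations=8, seed=1)
        assert res.phi == pytest.approx(w[1], abs=1e-12)
        assert res.standard_error == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_reproducible(self, random_model):
        g = featurize("CCOCCN")
        game = ss.build_game(g, {0}, L=4, value_kind="regression-output")
        a = ss.shapley_sampled(random_model, game, 16, seed=5)
        b = ss.shapley_sampled(random_model, game, 16, seed=5)
        assert a.phi == b.phi

    def test_close_to_exact_within_three_se(self, random_model):
        g = featurize("CCOCCNC")  # gamma = 6 for the end atom at L = 6
        game = ss.build_game(g, {0}, L=6, value_kind="regression-output")
        exact = ss.shapley(random_model, game).phi
        hits = 0
        runs = 20
        for seed in range(runs):
            est = ss.shapley_sampled(random_model, game, 64, seed=seed)
            if abs(est.phi - exact) < 3 * est.standard_error:
                hits += 1
        assert hits >= runs - 2  # ~99.7% nominal; allow slack

    def test_invalid_permutation_count(self, random_model, path7):
        game = ss.build_game(path7, {0}, L=2, value_kind="regression-output")
        with pytest.raises(ValueError):
            ss.shapley_sampled(random_model, game, 0)


class TestBruteForceOracle:
    def test_equals_restricted_game_beyond_diameter(self, random_model):
        for smiles in ["CCO", "c1ccccc1", "CC(N)C"]:
            g = featurize(smiles)
            game = ss.build_game(g, {0}, L=g.num_atoms,
                                 value_kind="regression-output")
            restricted = ss.shapley(random_model, game).phi
            full = ss.brute_force_full_shapley(
                random_model, g, {0}, value_kind="regression-output"
            )
            assert restricted == pytest.approx(full, abs=1e-6)

    def test_benzene_symmetry(self, random_model, benzene):
        phis = [
            ss.brute_force_full_shapley(random_model, benzene, {i},
                                        value_kind="regression-output")
            for i in range(6)
        ]
        assert max(phis) - min(phis) < 1e-5

    def test_additive_analytic(self):
        g = featurize("CCOC")
        w = np.array([0.5, -1.0, 2.0, 0.25])
        model = AdditiveAtomModel(w)
        phi = ss.brute_force_full_shapley(model, g, {1, 2},
                                          value_kind="regression-output")
        assert phi == pytest.approx(w[1] + w[2], abs=1e-12)

    def test_size_guard(self):
        g = featurize("C" * 20)
        with pytest.raises(ValueError, match="16"):
            ss.brute_force_full_shapley(_ConstantModel(), g, {0})


class TestAxioms:
    def test_efficiency(self, random_model):
        g = featurize("CCOCC")
        game = ss.build_game(g, {2}, L=4, value_kind="regression-output")
        phis = ss.shapley_all_players(random_model, game)
        grand = ss.value_function(random_model, game,
                                  set(game.context_atoms), True)
        empty = ss.value_function(random_model, game, set(), False)
        assert sum(phis) == pytest.approx(grand - empty, abs=1e-6)

    def test_dummy_player_zero(self, random_model):
        g = featurize("CCOCC")
        g.node_features[4, :] = 0.0  # atom 4 carries no information
        game = ss.build_game(g, {2}, L=4, value_kind="regression-output")
        phis = ss.shapley_all_players(random_model, game)
        dummy_position = 1 + game.context_atoms.index(4)
        assert phis[dummy_position] == pytest.approx(0.0, abs=1e-9)

    def test_order_invariance_under_relabeling(self, random_model):
        from conftest import permute_graph

        g = featurize("CCOCC")
        perm = np.array([4, 3, 2, 1, 0])
        gp = permute_graph(g, perm)
        game = ss.build_game(g, {2}, L=4, value_kind="regression-output")
        game_p = ss.build_game(gp, {int(perm[2])}, L=4,
                               value_kind="regression-output")
        a = ss.shapley(random_model, game).phi
        b = ss.shapley(random_model, game_p).phi
        assert a == pytest.approx(b, abs=1e-5)


class TestResultMetadata:
    def test_records_provenance(self, random_model, path7):
        game = ss.build_game(path7, {0}, L=2, value_kind="regression-output")
        res = ss.shapley(random_model, game)
        assert res.method == "exact"
        assert res.value_kind == "regression-output"
        assert res.L == 2
        assert res.substructure_atoms == (0,)

    def test_probability_value_kind(self, random_classifier, ethanol):
        game = ss.build_game(ethanol, {0}, L=2,
                             value_kind="classifier-probability")
        res = ss.shapley(random_classifier, game)
        assert np.isfinite(res.phi)
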