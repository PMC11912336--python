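"""Shapley values for substructures under zero-feature masking.

A substructure is one player; the other players are the individual atoms
reachable from it within L bonds.  Everything else is permanently masked in
every evaluation (locality restriction).  The value function runs the model
on the masked graph; atoms/bonds outside the coalition and the substructure
are zeroed, never removed.

Exact computation enumerates all coalitions (capped at ``exact_cap`` context
atoms); beyond that a seeded permutation-sampling estimator is available.
Model evaluations are batched, and the result is independent of evaluation
order and batching.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from . import gat_net
from .attn_correct import Substructure
from .mol_graph import MaskSpec, MoleculeGraph, apply_mask, reachable_atoms

__all__ = [
    "CoalitionGame",
    "ShapleyResult",
    "build_game",
    "value_function",
    "shapley",
    "shapley_sampled",
    "brute_force_full_shapley",
]

DEFAULT_L = 4
DEFAULT_EXACT_CAP = 14
VALUE_KINDS = ("regression-output", "classifier-logit", "classifier-probability")


@dataclass
class CoalitionGame:
    graph: MoleculeGraph
    substructure_atoms: frozenset[int]
    context_atoms: tuple[int, ...]  # sorted individual-atom players
    L: int
    value_kind: str

    @property
    def n_players(self) -> int:
        return len(self.context_atoms) + 1

    @property
    def gamma(self) -> int:
        return len(self.context_atoms)


@dataclass
class ShapleyResult:
    phi: float
    n_evaluations: int
    method: str  # "exact" | "permutation-sampled"
    value_kind: str
    L: int
    substructure_atoms: tuple[int, ...]
    seed: int | None = None
    standard_error: float | None = None


def _check_connected(graph: MoleculeGraph, atoms: frozenset[int]) -> None:
    atoms = set(atoms)
    start = next(iter(atoms))
    seen = {start}
    frontier = [start]
    while frontier:
        u = frontier.pop()
        for v in np.flatnonzero(graph.adjacency[u]):
            v = int(v)
            if v in atoms and v not in seen:
                seen.add(v)
                frontier.append(v)
    if seen != atoms:
        raise ValueError(f"substructure atoms {sorted(atoms)} are not connected")


def build_game(graph: MoleculeGraph, substructure: Substructure | frozenset | set,
               L: int = DEFAULT_L, value_kind: str = "classifier-logit") -> CoalitionGame:
    """Restrict the game to atoms reachable from the substructure within L bonds."""
    if value_kind not in VALUE_KINDS:
        raise ValueError(f"unknown value_kind {value_kind!r}")
    if isinstance(substructure, Substructure):
        atoms = frozenset(substructure.atom_indices)
    else:
        atoms = frozenset(int(a) for a in substructure)
    if not atoms:
        raise ValueError("substructure must be nonempty")
    for a in atoms:
        if not 0 <= a < graph.num_atoms:
            raise IndexError(f"substructure atom {a} out of range")
    _check_connected(graph, atoms)
    context = tuple(sorted(reachable_atoms(graph, atoms, L)))
    return CoalitionGame(
        graph=graph, substructure_atoms=atoms, context_atoms=context,
        L=L, value_kind=value_kind,
    )


def _predict(model, graphs: list[MoleculeGraph], value_kind: str) -> np.ndarray:
    """Dispatch to a ModelState or any object with ``predict_graphs``."""
    if hasattr(model, "predict_graphs"):
        values = np.asarray(model.predict_graphs(graphs), dtype=float)
        if value_kind == "classifier-probability":
            values = 1.0 / (1.0 + np.exp(-values))
        return values
    raw = gat_net.predict_batch(model, graphs)
    if value_kind == "classifier-probability":
        if model.config.head_kind != "binary-classification":
            raise ValueError("probability value_kind needs a classification head")
        return 1.0 / (1.0 + np.exp(-raw))
    return raw


def value_function(model, game: CoalitionGame, coalition, include_S: bool) -> float:
    """Model output with only ``coalition`` (and optionally S_i) unmasked."""
    coalition = frozenset(int(a) for a in coalition)
    if not coalition <= set(game.context_atoms):
        raise ValueError("coalition must be a subset of the context players")
    unmasked = coalition | (game.substructure_atoms if include_S else frozenset())
    masked = apply_mask(game.graph, MaskSpec(unmasked))
    return float(_predict(model, [masked], game.value_kind)[0])


def _batch_values(model, game: CoalitionGame,
                  unmasked_sets: list[frozenset[int]]) -> np.ndarray:
    graphs = [apply_mask(game.graph, MaskSpec(s)) for s in unmasked_sets]
    return _predict(model, graphs, game.value_kind)


def _subset_values(model, game: CoalitionGame) -> dict[int, float]:
    """Value of every player subset, keyed by bitmask (bit 0 = substructure)."""
    players = [game.substructure_atoms] + [frozenset([a]) for a in game.context_atoms]
    n = len(players)
    unmasked_sets = []
    for mask in range(1 << n):
        atoms: frozenset[int] = frozenset()
        for bit in range(n):
            if mask >> bit & 1:
                atoms = atoms | players[bit]
        unmasked_sets.append(atoms)
    values = _batch_values(model, game, unmasked_sets)
    return {mask: float(v) for mask, v in zip(range(1 << n), values)}


def _exact_phi_from_values(values: dict[int, float], n_players: int,
                           player_bit: int) -> float:
    """Shapley value of one player from the full subset-value table."""
    others = [b for b in range(n_players) if b != player_bit]
    n_fact = factorial(n_players)
    weights = [
        factorial(size) * factorial(n_players - size - 1) / n_fact
        for size in range(n_players)
    ]
    phi = 0.0
    for sub in range(1 << len(others)):
        mask = 0
        size = 0
        for i, bit in enumerate(others):
            if sub >> i & 1:
                mask |= 1 << bit
                size += 1
        phi += weights[size] * (values[mask | (1 << player_bit)] - values[mask])
    return phi


def shapley(model, game: CoalitionGame,
            exact_cap: int = DEFAULT_EXACT_CAP) -> ShapleyResult:
    """Exact Shapley value of the substructure player (coalition enumeration)."""
    if game.gamma > exact_cap:
        raise ValueError(
            f"gamma={game.gamma} exceeds exact_cap={exact_cap}; "
            "use shapley_sampled() instead"
        )
    values = _subset_values(model, game)
    phi = _exact_phi_from_values(values, game.n_players, player_bit=0)
    return ShapleyResult(
        phi=phi, n_evaluations=len(values), method="exact",
        value_kind=game.value_kind, L=game.L,
        substructure_atoms=tuple(sorted(game.substructure_atoms)),
    )


def shapley_all_players(model, game: CoalitionGame,
                        exact_cap: int = DEFAULT_EXACT_CAP) -> list[float]:
    """Exact Shapley values of every player (substructure first).

    Useful for checking efficiency: the values sum to
    v(all players) - v(empty coalition).
    """
    if game.gamma > exact_cap:
        raise ValueError("too many context players for exact enumeration")
    values = _subset_values(model, game)
    return [
        _exact_phi_from_values(values, game.n_players, player_bit=b)
        for b in range(game.n_players)
    ]


def shapley_sampled(model, game: CoalitionGame, n_permutations: int,
                    seed: int = 0) -> ShapleyResult:
    """Unbiased permutation-sampling estimate of the substructure's Shapley value."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    players = [game.substructure_atoms] + [frozenset([a]) for a in game.context_atoms]
    n = len(players)
    needed: dict[frozenset[int], int] = {}
    pairs: list[tuple[frozenset[int], frozenset[int]]] = []
    for _ in range(n_permutations):
        order = rng.permutation(n)
        before: frozenset[int] = frozenset()
        for b in order:
            if b == 0:
                break
            before = before | players[b]
        with_s = before | players[0]
        pairs.append((with_s, before))
        for key in (with_s, before):
            needed.setdefault(key, len(needed))
    unique_sets = sorted(needed, key=needed.get)
    values = _batch_values(model, game, unique_sets)
    table = {s: float(v) for s, v in zip(unique_sets, values)}
    marginals = np.array([table[a] - table[b] for a, b in pairs])
    se = (
        float(np.std(marginals, ddof=1) / np.sqrt(n_permutations))
        if n_permutations > 1 else float("nan")
    )
    return ShapleyResult(
        phi=float(marginals.mean()), n_evaluations=len(unique_sets),
        method="permutation-sampled", value_kind=game.value_kind, L=game.L,
        substructure_atoms=tuple(sorted(game.substructure_atoms)),
        seed=seed, standard_error=se,
    )


def brute_force_full_shapley(model, graph: MoleculeGraph, substructure,
                             value_kind: str = "classifier-logit") -> float:
    """Testing oracle: exact Shapley with ALL non-substructure atoms as players.

    No locality restriction and no permanently masked atoms.  Guarded to
    molecules with at most 16 non-substructure atoms.
    """
    if isinstance(substructure, Substructure):
        atoms = frozenset(substructure.atom_indices)
    else:
        atoms = frozenset(int(a) for a in substructure)
    m = graph.num_atoms
    if m - len(atoms) > 16:
        raise ValueError("brute force limited to m - k <= 16 non-substructure atoms")
    _check_connected(graph, atoms)
    context = tuple(sorted(set(range(m)) - atoms))
    game = CoalitionGame(
        graph=graph, substructure_atoms=atoms, context_atoms=context,
        L=m, value_kind=value_kind,
    )
    values = _subset_values(model, game)
    return _exact_phi_from_values(values, game.n_players, player_bit=0)
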