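"""Attention correction: re-attribute global attention to original atoms.

After message passing, each atom's representation is a mixture of its
neighborhood, so raw global attention does not refer to original atoms.  The
correction composes the per-layer local attention matrices into a composite
contribution matrix C (successive left-multiplication, last layer outermost),
multiplies the head-averaged global attention with C, and adds C back to
mirror the residual connection:  M = A_avg @ C + C.  Per-atom scores are the
renormalized column means of M.

The decomposition deliberately ignores the per-layer linear transforms,
batch normalization and nonlinearities: it tracks attention mass only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .gat_net import AttentionTrace
from .mol_graph import MoleculeGraph, mol_from_smiles

__all__ = [
    "ContributionMatrices",
    "CorrectedAttention",
    "Substructure",
    "SelectionPolicy",
    "layer_contribution",
    "compose",
    "correct",
    "correct_from_trace",
    "select_substructures",
]

_ROW_TOL = 1e-5


@dataclass
class ContributionMatrices:
    per_layer: list[np.ndarray]
    composite: np.ndarray


@dataclass
class CorrectedAttention:
    matrix: np.ndarray        # M, rows sum to 2
    atom_scores: np.ndarray   # nonnegative, sums to 1


@dataclass(frozen=True)
class Substructure:
    """Connected set of atom indices (with induced bonds) in one molecule."""

    smiles: str
    atom_indices: tuple[int, ...]
    bonds: tuple[tuple[int, int], ...]

    @staticmethod
    def from_atoms(graph: MoleculeGraph, atoms) -> "Substructure":
        atoms = tuple(sorted(int(a) for a in atoms))
        atom_set = set(atoms)
        bonds = tuple(
            (i, j) for (i, j) in graph.bond_list if i in atom_set and j in atom_set
        )
        return Substructure(graph.smiles, atoms, bonds)

    def to_smarts(self) -> str:
        mol = mol_from_smiles(self.smiles, keep_largest_fragment=True)
        return Chem.MolFragmentToSmarts(mol, atomsToUse=list(self.atom_indices))

    def canonical_key(self) -> str:
        """Canonical fragment SMILES used to group equal substructures."""
        mol = mol_from_smiles(self.smiles, keep_largest_fragment=True)
        return Chem.MolFragmentToSmiles(
            mol, atomsToUse=list(self.atom_indices), canonical=True,
            isomericSmiles=False,
        )


@dataclass
class SelectionPolicy:
    """Above-mean seed selection with a per-substructure size cap."""

    max_atoms: int = 8


def _check_row_stochastic(matrix: np.ndarray, what: str) -> None:
    sums = matrix.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_TOL)
    if bad.size:
        raise ValueError(
            f"{what}: row {int(bad[0])} sums to {sums[bad[0]]:.6f}, expected 1"
        )
    if (matrix < -_ROW_TOL).any():
        raise ValueError(f"{what}: negative attention entries")


def layer_contribution(trace_layer) -> np.ndarray:
    """Per-layer contribution matrix C_l: mean over conv heads if several."""
    if isinstance(trace_layer, np.ndarray):
        heads = [trace_layer]
    else:
        heads = [np.asarray(h) for h in trace_layer]
    for idx, head in enumerate(heads):
        _check_row_stochastic(head, f"local attention head {idx}")
    return np.mean(heads, axis=0)


def compose(per_layer: list[np.ndarray]) -> np.ndarray:
    """Composite contribution C = C_last @ ... @ C_1 (layers given first-to-last).

    Row i of C expresses the final representation of atom i as a convex
    combination of original atoms; products of row-stochastic matrices stay
    row-stochastic, which is verified numerically.
    """
    if not per_layer:
        raise ValueError("need at least one layer matrix")
    m = per_layer[0].shape[0]
    composite = np.eye(m)
    for idx, c_l in enumerate(per_layer):
        if c_l.shape != (m, m):
            raise ValueError(f"layer {idx} has shape {c_l.shape}, expected {(m, m)}")
        composite = c_l @ composite
    _check_row_stochastic(composite, "composite contribution matrix")
    return composite


def correct(global_heads: list[np.ndarray], composite: np.ndarray) -> CorrectedAttention:
    """Residual-consistent correction: M = mean(A_i) @ C + C.

    Every row of M sums to 2; per-atom scores are the column means of M
    divided by 2 and renormalized to sum to 1.
    """
    if not global_heads:
        raise ValueError("need at least one global attention head")
    m = composite.shape[0]
    for idx, head in enumerate(global_heads):
        if np.asarray(head).shape != (m, m):
            raise ValueError(
                f"global head {idx} has shape {np.asarray(head).shape}, "
                f"expected {(m, m)}"
            )
        _check_row_stochastic(np.asarray(head), f"global attention head {idx}")
    a_avg = np.mean(global_heads, axis=0)
    corrected = a_avg @ composite + composite
    scores = corrected.mean(axis=0) / 2.0
    scores = scores / scores.sum()
    return CorrectedAttention(matrix=corrected, atom_scores=scores)


def correct_from_trace(trace: AttentionTrace) -> CorrectedAttention:
    """Full correction pipeline from a captured forward-pass trace."""
    per_layer = [layer_contribution(layer) for layer in trace.local]
    composite = compose(per_layer)
    return correct(trace.global_heads, composite)


def _connected_components(atoms: set[int], adjacency: np.ndarray) -> list[set[int]]:
    remaining = set(atoms)
    components = []
    while remaining:
        start = remaining.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            u = frontier.pop()
            for v in np.flatnonzero(adjacency[u]):
                v = int(v)
                if v in remaining:
                    remaining.remove(v)
                    comp.add(v)
                    frontier.append(v)
        components.append(comp)
    return components


def _trim_component(comp: set[int], scores: np.ndarray, adjacency: np.ndarray,
                    max_atoms: int) -> set[int]:
    """Drop lowest-score atoms until |comp| <= max_atoms, keeping connectivity."""
    comp = set(comp)
    while len(comp) > max_atoms:
        removable = [
            a for a in comp
            if len(_connected_components(comp - {a}, adjacency)) == 1
        ]
        candidates = removable if removable else list(comp)
        comp.remove(min(candidates, key=lambda a: (scores[a], a)))
    return comp


def select_substructures(graph: MoleculeGraph, atom_scores,
                         policy: SelectionPolicy | None = None) -> list[Substructure]:
    """Candidate substructures: connected components of above-mean-score atoms.

    Deterministic given the scores.  Components larger than the policy cap
    are trimmed by removing their lowest-score atoms (preferring removals
    that keep the component connected).
    """
    policy = policy or SelectionPolicy()
    scores = np.asarray(atom_scores, dtype=float)
    if scores.shape[0] != graph.num_atoms:
        raise ValueError("scores length must equal atom count")
    seeds = set(np.flatnonzero(scores > scores.mean()).tolist())
    if not seeds:
        import warnings

        warnings.warn("no atom scores above the mean; no substructures selected")
        return []
    substructures = []
    for comp in _connected_components(seeds, graph.adjacency):
        comp = _trim_component(comp, scores, graph.adjacency, policy.max_atoms)
        substructures.append(Substructure.from_atoms(graph, comp))
    substructures.sort(key=lambda s: s.atom_indices)
    return substructures
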