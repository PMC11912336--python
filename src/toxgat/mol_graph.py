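"""SMILES featurization, zero-feature masking, and bond-distance reachability.

The featurization follows the general graph-convolution dialect: one-hot
atom type over a fixed element list plus named scalar/one-hot blocks.  The
layout is frozen in :data:`NODE_FEATURE_LAYOUT` / :data:`BOND_FEATURE_LAYOUT`
and must not be reordered between versions — trained checkpoints depend on it.
Hydrogens are implicit; the hydrogen count is a node feature.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdPartialCharges

__all__ = [
    "MoleculeGraph",
    "MaskSpec",
    "featurize",
    "apply_mask",
    "reachable_atoms",
    "read_smiles_table",
    "NODE_FEATURE_LAYOUT",
    "BOND_FEATURE_LAYOUT",
    "NUM_NODE_FEATURES",
    "NUM_BOND_FEATURES",
]

ATOM_TYPES = ["C", "N", "O", "F", "P", "S", "Cl", "Br", "I"]
HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
]
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
BOND_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
]

# (name, width) blocks, concatenated in order.
NODE_FEATURE_LAYOUT: tuple[tuple[str, int], ...] = (
    ("atom_type_onehot", len(ATOM_TYPES) + 1),  # + "other" slot
    ("formal_charge", 1),
    ("hybridization_onehot", len(HYBRIDIZATIONS)),
    ("h_bond_donor", 1),
    ("h_bond_acceptor", 1),
    ("aromatic", 1),
    ("degree_onehot", 6),  # degrees 0..5
    ("num_hydrogens_onehot", 5),  # 0..4
    ("chirality_onehot", 2),  # R, S
    ("gasteiger_charge", 1),
)
BOND_FEATURE_LAYOUT: tuple[tuple[str, int], ...] = (
    ("bond_type_onehot", len(BOND_TYPES)),
    ("in_ring", 1),
    ("conjugated", 1),
    ("stereo_onehot", len(BOND_STEREO) + 1),  # + "other" slot
)

NUM_NODE_FEATURES = sum(w for _, w in NODE_FEATURE_LAYOUT)
NUM_BOND_FEATURES = sum(w for _, w in BOND_FEATURE_LAYOUT)

# SMARTS used by the reference featurizer family for H-bonding roles
_DONOR = Chem.MolFromSmarts("[$([N;!H0;v3]),$([N;!H0;+1;v4]),$([O,S;H1;+0]),$([n;H1;+0])]")
_ACCEPTOR = Chem.MolFromSmarts(
    "[$([O,S;H1;v2]-[!$(*=[O,N,P,S])]),$([O,S;H0;v2]),$([O,S;-]),"
    "$([N;v3;!$(N-*=!@[O,N,P,S])]),$([nH0,o,s;+0])]"
)


@dataclass
class MoleculeGraph:
    """Featurized heavy-atom graph of one molecule.

    ``bond_list`` pairs are 0-based, undirected, stored once with ``i < j``.
    ``adjacency`` is the dense symmetric 0/1 matrix with zero diagonal.
    """

    smiles: str
    node_features: np.ndarray
    bond_list: list[tuple[int, int]]
    bond_features: np.ndarray
    adjacency: np.ndarray

    @property
    def num_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_bonds(self) -> int:
        return len(self.bond_list)

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(
            smiles=self.smiles,
            node_features=self.node_features.copy(),
            bond_list=list(self.bond_list),
            bond_features=self.bond_features.copy(),
            adjacency=self.adjacency.copy(),
        )


@dataclass
class MaskSpec:
    """A zero-feature mask: atoms in ``unmasked_atoms`` keep their features.

    A bond keeps its features iff both endpoints are unmasked.
    """

    unmasked_atoms: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        self.unmasked_atoms = frozenset(int(a) for a in self.unmasked_atoms)

    def derived_unmasked_bonds(self, graph: MoleculeGraph) -> list[tuple[int, int]]:
        keep = self.unmasked_atoms
        return [(i, j) for (i, j) in graph.bond_list if i in keep and j in keep]


def _one_hot(value, choices) -> list[float]:
    return [1.0 if value == c else 0.0 for c in choices]


def mol_from_smiles(smiles: str, keep_largest_fragment: bool = False) -> Chem.Mol:
    """Parse SMILES to a sanitized RDKit mol; reject disconnected inputs."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"Invalid SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        if not keep_largest_fragment:
            raise ValueError(
                f"Disconnected SMILES (salt/mixture): {smiles!r}; "
                "pass keep_largest_fragment=True to keep the biggest fragment"
            )
        mol = max(frags, key=lambda f: f.GetNumAtoms())
    if mol.GetNumAtoms() < 1:
        raise ValueError(f"Empty molecule: {smiles!r}")
    return mol


def featurize(smiles: str, keep_largest_fragment: bool = False) -> MoleculeGraph:
    """Convert a SMILES string into a :class:`MoleculeGraph`.

    Node features encode atom type, formal charge, hybridization,
    hydrogen-bond donor/acceptor role, aromaticity, degree, hydrogen count,
    chirality and Gasteiger partial charge; bond features encode bond type,
    ring membership, conjugation and stereo, per the frozen layouts above.
    """
    mol = mol_from_smiles(smiles, keep_largest_fragment)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rdPartialCharges.ComputeGasteigerCharges(mol)

    donors = {a for match in mol.GetSubstructMatches(_DONOR) for a in match}
    acceptors = {a for match in mol.GetSubstructMatches(_ACCEPTOR) for a in match}

    m = mol.GetNumAtoms()
    rows = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        chiral = atom.GetProp("_CIPCode") if atom.HasProp("_CIPCode") else ""
        charge = atom.GetDoubleProp("_GasteigerCharge")
        if not np.isfinite(charge):
            charge = 0.0
        row = (
            _one_hot(sym, ATOM_TYPES)
            + [0.0 if sym in ATOM_TYPES else 1.0]
            + [float(atom.GetFormalCharge())]
            + _one_hot(atom.GetHybridization(), HYBRIDIZATIONS)
            + [1.0 if atom.GetIdx() in donors else 0.0]
            + [1.0 if atom.GetIdx() in acceptors else 0.0]
            + [1.0 if atom.GetIsAromatic() else 0.0]
            + _one_hot(atom.GetDegree(), list(range(6)))
            + _one_hot(min(atom.GetTotalNumHs(), 4), list(range(5)))
            + _one_hot(chiral, ["R", "S"])
            + [charge]
        )
        rows.append(row)
    node_features = np.asarray(rows, dtype=np.float64)

    bond_list: list[tuple[int, int]] = []
    bond_rows = []
    adjacency = np.zeros((m, m), dtype=np.float64)
    for bond in mol.GetBonds():
        i, j = sorted((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        bond_list.append((i, j))
        stereo = bond.GetStereo()
        bond_rows.append(
            _one_hot(bond.GetBondType(), BOND_TYPES)
            + [1.0 if bond.IsInRing() else 0.0]
            + [1.0 if bond.GetIsConjugated() else 0.0]
            + _one_hot(stereo, BOND_STEREO)
            + [0.0 if stereo in BOND_STEREO else 1.0]
        )
        adjacency[i, j] = adjacency[j, i] = 1.0
    bond_features = (
        np.asarray(bond_rows, dtype=np.float64)
        if bond_rows
        else np.zeros((0, NUM_BOND_FEATURES), dtype=np.float64)
    )
    return MoleculeGraph(
        smiles=smiles,
        node_features=node_features,
        bond_list=bond_list,
        bond_features=bond_features,
        adjacency=adjacency,
    )


def apply_mask(graph: MoleculeGraph, spec: MaskSpec) -> MoleculeGraph:
    """Return a copy of ``graph`` with masked atom/bond feature rows zeroed.

    Adjacency and the bond list are untouched: masking hides information but
    preserves the molecular topology.
    """
    m = graph.num_atoms
    for a in spec.unmasked_atoms:
        if not 0 <= a < m:
            raise IndexError(f"atom index {a} out of range for {m}-atom molecule")
    out = graph.copy()
    keep = spec.unmasked_atoms
    for i in range(m):
        if i not in keep:
            out.node_features[i, :] = 0.0
    for b, (i, j) in enumerate(graph.bond_list):
        if i not in keep or j not in keep:
            out.bond_features[b, :] = 0.0
    return out


def reachable_atoms(graph: MoleculeGraph, seed_atoms, L: int) -> set[int]:
    """Atoms at bond distance 1..L from any seed, excluding the seeds (BFS)."""
    if L < 0:
        raise ValueError("L must be >= 0")
    m = graph.num_atoms
    seeds = {int(a) for a in seed_atoms}
    for a in seeds:
        if not 0 <= a < m:
            raise IndexError(f"seed atom {a} out of range")
    dist = {a: 0 for a in seeds}
    queue = deque(seeds)
    neighbors = [np.flatnonzero(graph.adjacency[i]) for i in range(m)]
    while queue:
        u = queue.popleft()
        if dist[u] == L:
            continue
        for v in neighbors[u]:
            v = int(v)
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return {a for a, d in dist.items() if 0 < d <= L}


def read_smiles_table(path, target_kind: str) -> list[tuple[str, float]]:
    """Read a delimited table with columns ``smiles`` and ``value``/``label``.

    Records preserve file order; duplicated SMILES keep the first occurrence
    (with a warning).  ``target_kind`` selects the target column: ``value``
    for regression, ``label`` for classification (labels must be 0/1).
    """
    if target_kind not in ("regression", "classification"):
        raise ValueError(f"unknown target_kind: {target_kind!r}")
    target_col = "value" if target_kind == "regression" else "label"
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"empty data file: {path}")
    if "smiles" not in df.columns:
        raise ValueError(f"missing 'smiles' column in {path}")
    if target_col not in df.columns:
        raise ValueError(f"missing '{target_col}' column in {path}")

    records: list[tuple[str, float]] = []
    seen: set[str] = set()
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        smiles = str(getattr(row, "smiles"))
        raw = getattr(row, target_col)
        try:
            target = float(raw)
        except (TypeError, ValueError):
            raise ValueError(
                f"unparsable {target_col} {raw!r} at row {row_number} of {path}"
            ) from None
        if not np.isfinite(target):
            raise ValueError(f"non-finite {target_col} at row {row_number} of {path}")
        if target_kind == "classification" and target not in (0.0, 1.0):
            raise ValueError(
                f"label must be 0 or 1, got {raw!r} at row {row_number} of {path}"
            )
        if smiles in seen:
            warnings.warn(f"duplicate SMILES {smiles!r}; keeping first occurrence")
            continue
        seen.add(smiles)
        records.append((smiles, target))
    return records
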