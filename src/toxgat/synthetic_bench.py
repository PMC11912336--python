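"""Synthetic benchmark: molecules with an additive lipophilicity surrogate
and a binary toxicity label partly driven by planted alert substructures.

The surrogate property is an exact sum of per-atom weights, so the generator
doubles as ground truth for attribution tests: under the additive mock model
built from the same weights, the Shapley value of any substructure equals
the sum of its atoms' weights.  The default planted alert (a thiourea-like
fragment) has negative total atom weight but a strongly positive label
effect, reproducing the positive-toxicity / negative-lipophilicity sign
pattern that flags specific modes of action.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .mol_graph import MoleculeGraph, mol_from_smiles

__all__ = [
    "SyntheticConfig",
    "LabeledSet",
    "AdditiveAtomModel",
    "gen_molecules",
    "surrogate_logp",
    "atom_weight_vector",
    "make_pretrain_set",
    "make_task_set",
    "additive_model_for",
]

DEFAULT_ATOM_WEIGHTS = {
    ("C", False): 0.5,
    ("C", True): 0.3,
    ("N", False): -1.0,
    ("N", True): -1.0,
    ("O", False): -0.7,
    ("O", True): -0.7,
    ("S", False): 0.2,
    ("S", True): 0.2,
    ("Cl", False): 0.9,
    ("Br", False): 1.1,
}

THIOUREA_SMARTS = "NC(=S)N"


@dataclass
class SyntheticConfig:
    atom_weights: dict = field(default_factory=lambda: dict(DEFAULT_ATOM_WEIGHTS))
    noise_sd: float = 0.2
    alert_patterns: dict = field(
        default_factory=lambda: {THIOUREA_SMARTS: 3.0}
    )
    logp_coefficient: float = 1.0
    target_positive_fraction: float = 0.60
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for pattern in self.alert_patterns:
            if Chem.MolFromSmarts(pattern) is None:
                raise ValueError(f"invalid alert SMARTS: {pattern!r}")


@dataclass
class LabeledSet:
    records: list[tuple[str, float]]
    kind: str  # "regression" | "classification"
    config: SyntheticConfig
    seed: int
    threshold: float | None = None  # classification label threshold on z


# ---------------------------------------------------------------------------
# molecule generation
# ---------------------------------------------------------------------------

_SCAFFOLDS = [
    "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC",
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1ccoc1",
]
# substituent SMILES; attachment is atom 0
_SUBSTITUENTS = ["Cl", "Br", "O", "N", "S", "C#C", "C", "CC", "NC(=S)N"]


def _attach(scaffold: Chem.Mol, substituent: Chem.Mol,
            scaffold_atom: int) -> Chem.Mol | None:
    combined = Chem.RWMol(Chem.CombineMols(scaffold, substituent))
    combined.AddBond(scaffold_atom, scaffold.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combined.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def gen_molecules(n: int, seed: int, alert_probability: float = 0.3) -> list[str]:
    """Assemble ``n`` valid 4-20-heavy-atom SMILES from a seeded template grammar.

    Scaffolds are alkyl chains and small (hetero)aromatic rings; substituents
    come from a fixed fragment list including the planted thiourea-like alert.
    Invalid assemblies are rejected and resampled.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    scaffold_mols = [Chem.MolFromSmiles(s) for s in _SCAFFOLDS]
    sub_mols = {s: Chem.MolFromSmiles(s) for s in _SUBSTITUENTS}
    out: list[str] = []
    while len(out) < n:
        scaffold = scaffold_mols[rng.integers(len(scaffold_mols))]
        mol = scaffold
        n_subs = int(rng.integers(0, 4))
        chosen = [str(_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))])
                  for _ in range(n_subs)]
        if rng.random() < alert_probability:
            chosen.append(THIOUREA_SMARTS)
        ok = True
        for sub_smiles in chosen:
            candidates = [
                a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0
            ]
            if not candidates:
                ok = False
                break
            site = int(candidates[rng.integers(len(candidates))])
            attached = _attach(mol, sub_mols[sub_smiles], site)
            if attached is None:
                ok = False
                break
            mol = attached
        if not ok:
            continue
        if not 4 <= mol.GetNumAtoms() <= 20:
            continue
        smiles = Chem.MolToSmiles(mol)
        if Chem.MolFromSmiles(smiles) is None:  # paranoid round-trip check
            continue
        out.append(smiles)
    return out


# ---------------------------------------------------------------------------
# additive surrogate property
# ---------------------------------------------------------------------------

def atom_weight_vector(smiles: str, config: SyntheticConfig | None = None) -> np.ndarray:
    """Ground-truth per-atom contribution of each heavy atom (generator ledger)."""
    config = config or SyntheticConfig()
    mol = mol_from_smiles(smiles)
    weights = np.zeros(mol.GetNumAtoms())
    for atom in mol.GetAtoms():
        key = (atom.GetSymbol(), atom.GetIsAromatic())
        if key in config.atom_weights:
            weights[atom.GetIdx()] = config.atom_weights[key]
        else:
            weights[atom.GetIdx()] = config.atom_weights.get(
                (atom.GetSymbol(), False), 0.0
            )
    return weights


def surrogate_logp(smiles: str, config: SyntheticConfig | None = None) -> float:
    """Noise-free additive surrogate: sum of per-atom weights."""
    return float(atom_weight_vector(smiles, config).sum())


def count_alert_matches(smiles: str, pattern: str) -> int:
    mol = mol_from_smiles(smiles)
    query = Chem.MolFromSmarts(pattern)
    return len(mol.GetSubstructMatches(query))


def make_pretrain_set(n: int, config: SyntheticConfig | None = None) -> LabeledSet:
    """Regression records: surrogate log P plus seeded Gaussian noise."""
    config = config or SyntheticConfig()
    if n < 10:
        raise ValueError("pretraining set needs n >= 10")
    smiles = gen_molecules(n, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    records = [
        (s, surrogate_logp(s, config) + rng.normal(0.0, config.noise_sd))
        for s in smiles
    ]
    return LabeledSet(records=records, kind="regression", config=config,
                      seed=config.seed)


def make_task_set(n: int, config: SyntheticConfig | None = None) -> LabeledSet:
    """Classification records: threshold on latent
    z = a * surrogate + sum_j b_j * alert_count_j + noise.

    The threshold is the (1 - target fraction) quantile of z, so the positive
    fraction lands on the target (0.60 by default, mirroring a 172:116 split).
    """
    config = config or SyntheticConfig()
    if n < 20:
        raise ValueError("task set needs n >= 20")
    smiles = gen_molecules(n, seed=config.seed + 1000)
    rng = np.random.default_rng(config.seed + 2000)
    z = np.empty(n)
    for i, s in enumerate(smiles):
        effect = sum(
            b * count_alert_matches(s, pattern)
            for pattern, b in config.alert_patterns.items()
        )
        z[i] = (
            config.logp_coefficient * surrogate_logp(s, config)
            + effect
            + rng.normal(0.0, config.noise_sd)
        )
    threshold = float(np.quantile(z, 1.0 - config.target_positive_fraction))
    labels = (z > threshold).astype(float)
    records = list(zip(smiles, labels.tolist()))
    return LabeledSet(records=records, kind="classification", config=config,
                      seed=config.seed, threshold=threshold)


# ---------------------------------------------------------------------------
# additive mock model (attribution ground truth)
# ---------------------------------------------------------------------------

class AdditiveAtomModel:
    """Mock model: sum of per-atom weights over atoms with nonzero features.

    Masked atoms have exactly-zero feature rows, so the model output on a
    masked graph is the partial sum over unmasked atoms — which makes every
    Shapley marginal contribution identical and analytic.
    """

    def __init__(self, weights: np.ndarray, offset: float = 0.0):
        self.weights = np.asarray(weights, dtype=float)
        self.offset = float(offset)

    def predict_graphs(self, graphs: list[MoleculeGraph]) -> np.ndarray:
        out = np.empty(len(graphs))
        for i, g in enumerate(graphs):
            active = np.abs(g.node_features).sum(axis=1) > 0
            out[i] = self.offset + self.weights[: g.num_atoms][active].sum()
        return out


def additive_model_for(smiles: str, config: SyntheticConfig | None = None,
                       sign: float = 1.0) -> AdditiveAtomModel:
    """Additive mock model wired to the generator's ground-truth atom weights."""
    return AdditiveAtomModel(sign * atom_weight_vector(smiles, config))
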