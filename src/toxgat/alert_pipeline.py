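"""End-to-end structural-alert discovery.

Substructures are proposed from the toxicity model's corrected attention,
scored by Shapley values under both the toxicity and the lipophilicity
model (identical masks), grouped by canonical fragment, categorized by
element content, and flagged as specific-mode-of-action candidates when
they contribute positively to toxicity but negatively to lipophilicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.stats import gaussian_kde

from . import gat_net
from .attn_correct import (
    SelectionPolicy,
    Substructure,
    correct_from_trace,
    select_substructures,
)
from .mol_graph import featurize, mol_from_smiles
from .subgraph_shapley import (
    DEFAULT_EXACT_CAP,
    DEFAULT_L,
    build_game,
    shapley,
    shapley_sampled,
)

__all__ = [
    "AlertRecord",
    "AlertConfig",
    "explain_molecule",
    "categorize",
    "aggregate_alerts",
    "score_pattern",
    "distribution_overlap",
]

CATEGORIES = ("nitrogen", "sulfur", "nitrogen-sulfur", "halogen", "other")
_HALOGENS = {"Cl", "Br", "I"}


@dataclass
class AlertRecord:
    smarts: str
    canonical_key: str
    example_smiles: list[str]
    mean_phi_tox: float
    mean_phi_lipo: float
    category: str
    support: int
    moa_flag: str = field(init=False)

    def __post_init__(self):
        self.moa_flag = (
            "specific-moa-candidate"
            if self.mean_phi_tox > 0 and self.mean_phi_lipo < 0
            else "baseline-consistent"
        )


@dataclass
class AlertConfig:
    L: int = DEFAULT_L
    min_support: int = 2
    exact_cap: int = DEFAULT_EXACT_CAP
    n_permutations: int = 30  # sampling fallback beyond exact_cap
    seed: int = 0
    max_atoms: int = 8
    tox_value_kind: str = "classifier-logit"
    lipo_value_kind: str = "regression-output"


def _score_substructure(tox_state, lipo_state, graph, atoms, config: AlertConfig):
    """Shapley value of one atom set under both models, identical masks."""
    phis = []
    for model, kind in ((tox_state, config.tox_value_kind),
                        (lipo_state, config.lipo_value_kind)):
        game = build_game(graph, frozenset(atoms), L=config.L, value_kind=kind)
        if game.gamma <= config.exact_cap:
            result = shapley(model, game, exact_cap=config.exact_cap)
        else:
            result = shapley_sampled(model, game, config.n_permutations,
                                     seed=config.seed)
        phis.append(result.phi)
    return phis[0], phis[1]


def explain_molecule(tox_state, lipo_state, smiles: str,
                     config: AlertConfig | None = None
                     ) -> list[tuple[Substructure, float, float]]:
    """Select substructures by corrected attention and score them by Shapley
    values under the toxicity and lipophilicity models."""
    config = config or AlertConfig()
    if (getattr(tox_state, "config", None) is not None
            and getattr(lipo_state, "config", None) is not None
            and tox_state.config.n_node_features != lipo_state.config.n_node_features):
        raise ValueError("models disagree on featurization layout")
    graph = featurize(smiles)
    _, trace = gat_net.forward(tox_state, graph, capture=True)
    corrected = correct_from_trace(trace)
    substructures = select_substructures(
        graph, corrected.atom_scores, SelectionPolicy(max_atoms=config.max_atoms)
    )
    results = []
    for sub in substructures:
        phi_tox, phi_lipo = _score_substructure(
            tox_state, lipo_state, graph, sub.atom_indices, config
        )
        results.append((sub, phi_tox, phi_lipo))
    return results


def categorize(substructure: Substructure) -> str:
    """Element category with fixed precedence:
    N and S -> nitrogen-sulfur; only N -> nitrogen; only S -> sulfur;
    halogen without N or S -> halogen; everything else -> other.
    """
    mol = mol_from_smiles(substructure.smiles, keep_largest_fragment=True)
    symbols = {mol.GetAtomWithIdx(a).GetSymbol() for a in substructure.atom_indices}
    has_n = "N" in symbols
    has_s = "S" in symbols
    has_hal = bool(symbols & _HALOGENS)
    if has_n and has_s:
        return "nitrogen-sulfur"
    if has_n and not has_s and not has_hal:
        return "nitrogen"
    if has_s and not has_n and not has_hal:
        return "sulfur"
    if has_hal and not has_n and not has_s:
        return "halogen"
    return "other"


def aggregate_alerts(dataset, tox_state, lipo_state,
                     config: AlertConfig | None = None) -> list[AlertRecord]:
    """Group substructures across molecules and keep positive-toxicity alerts.

    Records are grouped by canonical fragment, filtered to mean phi_tox > 0
    and support >= min_support, and sorted by mean phi_tox descending (ties:
    support, then SMARTS).  Output is invariant to dataset row order.
    """
    config = config or AlertConfig()
    groups: dict[str, dict] = {}
    for smiles, _target in dataset:
        for sub, phi_tox, phi_lipo in explain_molecule(
            tox_state, lipo_state, smiles, config
        ):
            key = sub.canonical_key()
            entry = groups.setdefault(
                key, {"phi_tox": [], "phi_lipo": [], "smiles": [], "sub": sub}
            )
            entry["phi_tox"].append(phi_tox)
            entry["phi_lipo"].append(phi_lipo)
            entry["smiles"].append(smiles)
    records = []
    for key, entry in groups.items():
        support = len(set(entry["smiles"]))
        mean_tox = float(np.mean(entry["phi_tox"]))
        if support < config.min_support or mean_tox <= 0:
            continue
        records.append(
            AlertRecord(
                smarts=entry["sub"].to_smarts(),
                canonical_key=key,
                example_smiles=sorted(set(entry["smiles"])),
                mean_phi_tox=mean_tox,
                mean_phi_lipo=float(np.mean(entry["phi_lipo"])),
                category=categorize(entry["sub"]),
                support=support,
            )
        )
    records.sort(key=lambda r: (-r.mean_phi_tox, -r.support, r.canonical_key))
    return records


def score_pattern(dataset, tox_state, lipo_state, pattern: str,
                  config: AlertConfig | None = None,
                  max_molecules: int | None = None) -> AlertRecord | None:
    """Score every occurrence of a SMARTS pattern across a dataset.

    Returns the aggregated :class:`AlertRecord` for the pattern's matches
    (or None if the pattern matches no molecule).  This scores a *given*
    substructure directly, bypassing attention-based selection.
    """
    config = config or AlertConfig()
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ValueError(f"invalid SMARTS: {pattern!r}")
    phi_tox_all, phi_lipo_all, supporting = [], [], []
    representative = None
    for smiles, _target in dataset:
        mol = mol_from_smiles(smiles)
        matches = mol.GetSubstructMatches(query)
        if not matches:
            continue
        if max_molecules is not None and len(supporting) >= max_molecules:
            break
        graph = featurize(smiles)
        for match in matches:
            phi_tox, phi_lipo = _score_substructure(
                tox_state, lipo_state, graph, match, config
            )
            phi_tox_all.append(phi_tox)
            phi_lipo_all.append(phi_lipo)
            if representative is None:
                representative = Substructure.from_atoms(graph, match)
        supporting.append(smiles)
    if representative is None:
        return None
    return AlertRecord(
        smarts=pattern,
        canonical_key=representative.canonical_key(),
        example_smiles=supporting,
        mean_phi_tox=float(np.mean(phi_tox_all)),
        mean_phi_lipo=float(np.mean(phi_lipo_all)),
        category=categorize(representative),
        support=len(supporting),
    )


def distribution_overlap(samples_a, samples_b) -> float:
    """Area under the pointwise minimum of two Gaussian KDEs, in [0, 1].

    Bandwidth follows Scott's reference rule; zero-variance samples fall
    back to a widened minimal bandwidth with a warning.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample set needs at least 5 points")

    def _kde(x):
        if np.ptp(x) == 0 or np.std(x) == 0:
            warnings.warn("zero-variance sample; widening bandwidth")
            x = x + np.linspace(-1e-3, 1e-3, x.size)
        kde = gaussian_kde(x)
        bw = float(kde.factor * np.std(x, ddof=1))
        return kde, bw

    kde_a, bw_a = _kde(a)
    kde_b, bw_b = _kde(b)
    lo = min(a.min() - 3 * bw_a, b.min() - 3 * bw_b)
    hi = max(a.max() + 3 * bw_a, b.max() + 3 * bw_b)
    grid = np.linspace(lo, hi, 2048)
    overlap = np.trapezoid(np.minimum(kde_a(grid), kde_b(grid)), grid)
    return float(np.clip(overlap, 0.0, 1.0))
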