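"""SMILES → molecular graph with 75-dimensional binary atom features.

Each heavy atom becomes a node carrying a fixed-layout 75-bit feature
vector; bonds become undirected edges (hydrogens are implicit).  The layout
follows the de-facto standard graph-convolution featurization:

===========================  =====  =========================================
block                        bits   encoding
===========================  =====  =========================================
element                      44     one-hot over a fixed symbol list,
                                    last slot = "Unknown"
degree                       11     one-hot 0–10 (heavy-atom neighbours)
implicit valence             7      one-hot 0–6
formal charge                1      presence bit (charge ≠ 0)
radical electrons            1      presence bit (unpaired electrons ≠ 0)
hybridization                5      one-hot {SP, SP2, SP3, SP3D, SP3D2};
                                    anything else maps to the SP3 slot
aromaticity                  1      flag
total hydrogens              5      one-hot 0–4
===========================  =====  =========================================

Out-of-range categories clamp to the last slot of their block, so every
one-hot block always has exactly one bit set.  Formal charge and radical
count are collapsed to presence bits to keep the vector strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

N_ATOM_FEATURES = 75

ELEMENTS = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "Unknown",
)

HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)

#: (name, start, stop, kind) for each feature block; kind is "onehot" or "flag".
FEATURE_BLOCKS = (
    ("element", 0, 44, "onehot"),
    ("degree", 44, 55, "onehot"),
    ("implicit_valence", 55, 62, "onehot"),
    ("formal_charge", 62, 63, "flag"),
    ("radical_electrons", 63, 64, "flag"),
    ("hybridization", 64, 69, "onehot"),
    ("aromatic", 69, 70, "flag"),
    ("total_hydrogens", 70, 75, "onehot"),
)


class FeaturizationError(ValueError):
    """Raised when a SMILES cannot be parsed; carries the offending string."""

    def __init__(self, smiles: str, reason: str = "unparseable"):
        super().__init__(f"cannot featurize SMILES {smiles!r}: {reason}")
        self.smiles = smiles


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """75-component binary feature vector for one parsed atom."""
    vec = np.zeros(N_ATOM_FEATURES, dtype=np.float32)
    symbol = atom.GetSymbol()
    vec[ELEMENTS.index(symbol) if symbol in ELEMENTS else len(ELEMENTS) - 1] = 1
    vec[44 + min(atom.GetDegree(), 10)] = 1
    vec[55 + min(atom.GetImplicitValence(), 6)] = 1
    vec[62] = atom.GetFormalCharge() != 0
    vec[63] = atom.GetNumRadicalElectrons() != 0
    hyb = atom.GetHybridization()
    vec[64 + (HYBRIDIZATIONS.index(hyb) if hyb in HYBRIDIZATIONS else 2)] = 1
    vec[69] = atom.GetIsAromatic()
    vec[70 + min(atom.GetTotalNumHs(), 4)] = 1
    return vec


@dataclass
class MolecularGraph:
    """Per-atom features plus an undirected neighbour structure."""

    smiles: str
    n_atoms: int
    atom_feats: np.ndarray  # (n_atoms, 75) float32, binary entries
    neighbors: list = field(repr=False)  # per-atom lists of atom indices

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed edge arrays (src, dst) covering both bond directions."""
        src = [u for v, nb in enumerate(self.neighbors) for u in nb]
        dst = [v for v, nb in enumerate(self.neighbors) for _ in nb]
        return np.asarray(src, dtype=np.int64), np.asarray(dst, dtype=np.int64)

    def to_debug_dict(self) -> dict:
        return {
            "smiles": self.smiles,
            "n_atoms": self.n_atoms,
            "atom_features": self.atom_feats.astype(int).tolist(),
            "neighbors": [list(map(int, nb)) for nb in self.neighbors],
        }


def featurize_molecule(smiles: str) -> MolecularGraph:
    """Parse a SMILES into a :class:`MolecularGraph` (one node per heavy atom)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(smiles)
    if mol.GetNumAtoms() == 0:
        raise FeaturizationError(smiles, "no heavy atoms")
    feats = np.stack([atom_features(a) for a in mol.GetAtoms()])
    neighbors = [
        [n.GetIdx() for n in a.GetNeighbors()] for a in mol.GetAtoms()
    ]
    return MolecularGraph(
        smiles=smiles, n_atoms=mol.GetNumAtoms(), atom_feats=feats, neighbors=neighbors
    )


def featurize_many(smiles_list) -> list[MolecularGraph]:
    """Featurize a sequence of SMILES, raising on the first failure."""
    return [featurize_molecule(s) for s in smiles_list]


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a SMILES file (one molecule per line, optional id column).

    Returns (id, smiles) pairs; ids default to the line number.
    """
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            smiles = parts[0]
            ident = parts[1] if len(parts) > 1 else str(i + 1)
            out.append((ident, smiles))
    return out
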