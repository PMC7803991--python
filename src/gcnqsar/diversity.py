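"""Scaffold-diversity diagnostics: carbon skeletons, Shannon H, and KLD.

A compound's *carbon skeleton* is its Murcko framework (ring systems plus
the linkers connecting them, side chains removed) with every heavy atom
replaced by carbon and every bond by a single bond.  Acyclic molecules map
to a designated empty skeleton of size 0, so every compound lands in some
bin and the histogram stays a probability distribution.

A *binning scheme* sorts a reference list of skeletons in ascending order
of size (canonical-SMILES tiebreak) and chunks it into consecutive bins of
fixed capacity (10,000 per bin for the full ChEMBL-scale reference; the
last bin may be smaller).  A dataset's *scaffold histogram* counts
compounds — not scaffolds — per bin and normalizes, p_i = c_i / c.

Diversity is the Shannon entropy in bits, H = −Σ p_i log2 p_i (maximum
log2(n_bins), e.g. 3.91 for 15 bins); the distribution shift introduced by
a random split is the Kullback–Leibler divergence in bits,
KLD(p‖q) = Σ p_i log2(p_i / q_i) ≥ 0, between a subset's histogram p and
the unsplit dataset's histogram q.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.special import rel_entr
from scipy.stats import entropy

_LN2 = float(np.log(2.0))

#: Canonical spelling of the empty (acyclic) skeleton.
EMPTY_SKELETON = ""


@dataclass(frozen=True, order=True)
class Skeleton:
    """All-carbon, all-single-bond ring framework of a molecule."""

    size: int
    smiles: str

    def __post_init__(self):
        if (self.size == 0) != (self.smiles == EMPTY_SKELETON):
            raise ValueError("empty skeleton must have size 0 and vice versa")


@lru_cache(maxsize=200_000)
def carbon_skeleton(smiles: str) -> Skeleton:
    """Murcko framework with all heavy atoms → C and all bonds → single.

    Acyclic molecules yield the empty skeleton of size 0.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES for skeleton extraction: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold.GetNumAtoms() == 0:
        return Skeleton(0, EMPTY_SKELETON)
    rw = Chem.RWMol(scaffold)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetIsAromatic(False)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Skeleton(out.GetNumAtoms(), Chem.MolToSmiles(out))


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass
class BinningScheme:
    """Size-ordered reference scaffolds chunked into fixed-capacity bins."""

    skeletons: list  # sorted by (size, smiles)
    capacity: int
    n_bins: int
    _bin_of: dict = field(repr=False, default_factory=dict)

    def bin_members(self, i: int) -> list:
        return self.skeletons[i * self.capacity : (i + 1) * self.capacity]

    def assign(self, skeleton: Skeleton) -> int:
        """Bin index for a skeleton; unseen skeletons map to the bin whose
        size range brackets them (by sort position)."""
        hit = self._bin_of.get(skeleton.smiles)
        if hit is not None:
            return hit
        pos = bisect.bisect_left(self.skeletons, skeleton)
        return min(pos // self.capacity, self.n_bins - 1)


def read_skeleton_list(path) -> list[Skeleton]:
    """Read skeletons from a SMILES-per-line file (blank lines ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            smiles = line.split()[0] if line.split() else ""
            if smiles:
                out.append(carbon_skeleton(smiles))
    return out


def write_skeleton_list(skeletons, path) -> None:
    """Write skeletons as one SMILES per line."""
    with open(path, "w") as fh:
        for sk in skeletons:
            fh.write(sk.smiles + "\n")


def build_binning(reference_skeletons, capacity: int = 10_000) -> BinningScheme:
    """Sort a deduplicated reference scaffold list by ascending size
    (canonical-SMILES tiebreak) and chunk it into bins of ``capacity``."""
    if capacity < 1:
        raise ValueError("bin capacity must be positive")
    unique = sorted(set(reference_skeletons))
    if not unique:
        raise ValueError("empty reference scaffold list")
    n_bins = -(-len(unique) // capacity)
    scheme = BinningScheme(skeletons=unique, capacity=capacity, n_bins=n_bins)
    scheme._bin_of = {s.smiles: i // capacity for i, s in enumerate(unique)}
    return scheme


# ---------------------------------------------------------------------------
# Histograms, H and KLD
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldHistogram:
    """Per-bin probability mass of compounds over a binning scheme."""

    p: np.ndarray
    counts: np.ndarray
    c: int

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must be non-negative and sum to 1")

    @classmethod
    def from_probabilities(cls, p) -> "ScaffoldHistogram":
        p = np.asarray(p, dtype=float)
        return cls(p=p, counts=np.round(p * 0), c=0)

    @property
    def n_bins(self) -> int:
        return len(self.p)


def dataset_histogram(dataset, scheme: BinningScheme) -> ScaffoldHistogram:
    """Histogram of compounds (not scaffolds) over the scheme's bins.

    ``dataset`` is a curated table with a ``canonical_smiles`` column or a
    plain iterable of SMILES.
    """
    if isinstance(dataset, pd.DataFrame):
        smiles = dataset["canonical_smiles"].tolist()
    else:
        smiles = list(dataset)
    if not smiles:
        raise ValueError("cannot build a scaffold histogram of an empty dataset")
    counts = np.zeros(scheme.n_bins, dtype=np.int64)
    for s in smiles:
        counts[scheme.assign(carbon_skeleton(s))] += 1
    c = int(counts.sum())
    return ScaffoldHistogram(p=counts / c, counts=counts, c=c)


def shannon_H(hist: ScaffoldHistogram) -> float:
    """Shannon scaffold-diversity index in bits, −Σ p_i log2 p_i."""
    return float(entropy(hist.p, base=2))


def kld(p: ScaffoldHistogram, q: ScaffoldHistogram, smooth: bool = True) -> float:
    """Kullback–Leibler divergence Σ p_i log2(p_i/q_i) in bits.

    With ``smooth`` (default), q receives additive smoothing ε = 1/(10·c)
    — c being q's compound count (fallback 10·n_bins when q was built from
    bare probabilities) — since random splits of small datasets routinely
    leave bins of q's support empty in p's complement.  With smoothing
    disabled, any p_i > 0 where q_i = 0 yields ``inf``.
    """
    if p.n_bins != q.n_bins:
        raise ValueError("histograms use different binning schemes")
    qp = q.p
    if smooth:
        eps = 1.0 / (10.0 * q.c) if q.c > 0 else 1.0 / (10.0 * q.n_bins)
        qp = (qp + eps) / (1.0 + q.n_bins * eps)
    elif np.any((p.p > 0) & (qp == 0)):
        return float("inf")
    return float(rel_entr(p.p, qp).sum() / _LN2)
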