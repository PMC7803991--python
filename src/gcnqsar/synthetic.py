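"""ChEMBL-shaped synthetic activity tables with a planted additive SAR.

Molecules are assembled from a small grammar — a ring-scaffold library and
a substituent library — by attaching 0–3 substituents via single bonds at
scaffold carbons with a free valence.  The planted structure–activity
relationship is additive on the pIC50 scale:

    true pIC50 = baseline + Σ_f w_f · count(f attached)

Measured activities add Gaussian noise ε ~ N(0, noise_sd²) and are emitted
as nM values, v = 10^(9 − (true + ε)).  The generator can corrupt a
controlled portion of the table the way a real database extract is dirty:
censored rows (values forced to an assay limit with relation "<" or ">"),
duplicated compound–target measurements with independent noise, salt-form
SMILES, and junk rows that each violate exactly one curation filter (low
confidence, wrong units, banned comment, duplicate flag, wrong assay type,
bad validity comment, or a corrupted SMILES).  Quotas are exact by
construction and all randomness flows from the seed, so tables are
byte-identical across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import REQUIRED_COLUMNS
from .diversity import BinningScheme, Skeleton, carbon_skeleton

# ---------------------------------------------------------------------------
# Default libraries
# ---------------------------------------------------------------------------

#: Ring-system scaffolds spanning skeleton sizes 5–17, with sampling weights.
DEFAULT_SCAFFOLDS = (
    ("C1CCCC1", 1.0),                 # cyclopentane (5)
    ("c1ccncc1", 1.0),                # pyridine (6)
    ("C1CCCCCC1", 1.0),               # cycloheptane (7)
    ("c1ccc2c(c1)CC2", 1.0),          # benzocyclobutene (8)
    ("C1Cc2ccccc2C1", 1.0),           # indane (9)
    ("c1ccc2ccccc2c1", 1.0),          # naphthalene (10)
    ("C1CCc2ccccc2CC1", 1.0),         # benzosuberane (11)
    ("c1ccc(-c2ccccc2)cc1", 1.0),     # biphenyl (12)
    ("c1ccc2c(c1)[nH]c1ccccc12", 1.0),  # carbazole (13)
    ("C(c1ccccc1)Cc1ccccc1", 1.0),    # bibenzyl (14)
    ("c1ccc(CCCc2ccccc2)cc1", 1.0),   # 1,3-diphenylpropane (15)
    ("C1CCC(c2ccc3ccccc3c2)CC1", 1.0),  # cyclohexyl-naphthalene (16)
    ("C1CCC(Cc2ccc3ccccc3c2)CC1", 1.0),  # one-carbon-linked variant (17)
)

#: Substituent fragments (attachment at atom 0) and their planted pIC50
#: contributions w_f, spanning [−1.5, +1.5].
DEFAULT_SUBSTITUENTS = (
    ("C", 0.35), ("CC", 0.6), ("CCC", 0.8), ("C(C)C", 0.9),
    ("F", 0.25), ("Cl", 0.7), ("Br", 1.2), ("O", -0.7),
    ("OC", 0.45), ("OCC", 0.55), ("N", -1.1), ("NC", -0.5),
    ("N(C)C", 0.5), ("C#N", -0.9), ("C(=O)O", -1.5), ("C(=O)N", -1.3),
    ("C(F)(F)F", 1.5), ("S", 0.3), ("SC", 0.65), ("CO", -0.4),
)


@dataclass
class SARSpec:
    """Generator settings: the molecule grammar, the planted SAR, the noise
    level, and the corruption quotas (fractions of the n emitted rows)."""

    scaffold_library: tuple = DEFAULT_SCAFFOLDS
    substituent_library: tuple = DEFAULT_SUBSTITUENTS
    baseline: float = 6.0
    noise_sd: float = 0.3
    censor_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    junk_fraction: float = 0.0
    n: int = 1000
    seed: int = 0
    max_substituents: int = 3
    v_min: float = 0.1        # nM; pIC50 10 assay ceiling
    v_max: float = 1.0e6      # nM; pIC50 3 assay floor
    target_id: str = "SYNT1"
    salt_every: int = 6       # every k-th clean row is emitted as an HCl salt

    def validate(self) -> None:
        if not self.scaffold_library or not self.substituent_library:
            raise ValueError("scaffold and substituent libraries must be non-empty")
        weights = [w for _, w in self.scaffold_library]
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("scaffold sampling weights must be >=0 and not all zero")
        for name in ("censor_fraction", "duplicate_fraction", "junk_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.duplicate_fraction + self.junk_fraction > 1.0:
            raise ValueError("duplicate_fraction + junk_fraction exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0 < self.v_min < self.v_max:
            raise ValueError("require 0 < v_min < v_max")


# ---------------------------------------------------------------------------
# Molecule assembly
# ---------------------------------------------------------------------------

def _attach(scaffold: Chem.Mol, fragment: Chem.Mol, site: int) -> Chem.Mol:
    combined = Chem.RWMol(Chem.CombineMols(scaffold, fragment))
    combined.AddBond(site, scaffold.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combined.GetMol()
    Chem.SanitizeMol(mol)
    return mol


class SARGenerator:
    """Deterministic molecule factory with a planted additive SAR.

    Keeps a registry mapping each emitted canonical SMILES to its noiseless
    activity, so ``true_activity`` is decidable for every generated
    compound.
    """

    def __init__(self, spec: SARSpec):
        spec.validate()
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self._scaffolds = [Chem.MolFromSmiles(s) for s, _ in spec.scaffold_library]
        if any(m is None for m in self._scaffolds):
            raise ValueError("unparseable scaffold in library")
        self._fragments = [Chem.MolFromSmiles(s) for s, _ in spec.substituent_library]
        if any(m is None for m in self._fragments):
            raise ValueError("unparseable substituent in library")
        w = np.array([w for _, w in spec.scaffold_library], dtype=float)
        self._scaffold_p = w / w.sum()
        self._registry: dict[str, float] = {}

    # -- one molecule ------------------------------------------------------
    def sample_molecule(self) -> tuple[str, float]:
        """Assemble one molecule; returns (canonical SMILES, true pIC50)."""
        spec = self.spec
        s_idx = int(self.rng.choice(len(self._scaffolds), p=self._scaffold_p))
        mol = Chem.Mol(self._scaffolds[s_idx])
        contribution = 0.0
        k = int(self.rng.integers(0, spec.max_substituents + 1))
        for _ in range(k):
            sites = [
                a.GetIdx()
                for a in mol.GetAtoms()
                if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
            ]
            if not sites:
                break
            site = int(self.rng.choice(sites))
            f_idx = int(self.rng.integers(0, len(self._fragments)))
            mol = _attach(mol, Chem.Mol(self._fragments[f_idx]), site)
            contribution += spec.substituent_library[f_idx][1]
        smiles = Chem.MolToSmiles(mol)
        true_p = spec.baseline + contribution
        known = self._registry.get(smiles)
        if known is not None and abs(known - true_p) > 1e-9:
            # same canonical SMILES reachable with a different fragment sum:
            # treat as a failed draw so the SAR stays a function of structure
            return self.sample_molecule()
        self._registry[smiles] = true_p
        return smiles, true_p

    def sample_unique(self, count: int) -> list[tuple[str, float]]:
        seen: set[str] = set()
        out = []
        attempts = 0
        while len(out) < count:
            attempts += 1
            if attempts > 60 * count:
                raise RuntimeError("molecule grammar too small for requested uniqueness")
            smiles, p = self.sample_molecule()
            if smiles not in seen:
                seen.add(smiles)
                out.append((smiles, p))
        return out

    def true_activity(self, smiles: str) -> float:
        """Noiseless planted pIC50 of a generated molecule."""
        canonical = Chem.CanonSmiles(smiles)
        if canonical not in self._registry:
            raise KeyError(f"molecule was not produced by this generator: {smiles!r}")
        return self._registry[canonical]

    # -- the table ---------------------------------------------------------
    def generate_table(self) -> pd.DataFrame:
        spec = self.spec
        rng = self.rng
        n_junk = round(spec.junk_fraction * spec.n)
        n_dup = round(spec.duplicate_fraction * spec.n)
        n_base = spec.n - n_junk - n_dup
        if n_base < 1:
            raise ValueError("corruption fractions leave no clean rows")

        base = self.sample_unique(n_base)
        rows = []

        def activity_row(cid, smiles, true_p):
            p_noisy = true_p + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            return {
                "compound_id": cid,
                "smiles": smiles,
                "standard_type": "IC50",
                "standard_value": 10.0 ** (9.0 - p_noisy),
                "standard_units": "nM",
                "standard_relation": "=",
                "assay_type": "B",
                "confidence_score": 9,
                "activity_comment": "",
                "potential_duplicates": 0,
                "data_validity_comment": "",
                "target_id": spec.target_id,
            }

        for i, (smiles, true_p) in enumerate(base):
            row = activity_row(f"SYN{i + 1:06d}", smiles, true_p)
            if spec.salt_every and (i + 1) % spec.salt_every == 0:
                row["smiles"] = smiles + ".Cl"
            rows.append(row)

        dup_choices = rng.integers(0, n_base, size=n_dup)
        for j in dup_choices:
            smiles, true_p = base[int(j)]
            rows.append(activity_row(f"SYN{int(j) + 1:06d}", smiles, true_p))

        # censoring: emulate assay limits on a quota of the clean rows
        n_cens = round(spec.censor_fraction * len(rows))
        if n_cens:
            p_mid = 9.0 - 0.5 * (np.log10(spec.v_min) + np.log10(spec.v_max))
            for k in rng.choice(len(rows), size=n_cens, replace=False):
                row = rows[int(k)]
                p_val = 9.0 - np.log10(row["standard_value"])
                if p_val >= p_mid:  # very active: below the lower value limit
                    row["standard_value"] = spec.v_min
                    row["standard_relation"] = "<"
                else:               # inactive: beyond the upper value limit
                    row["standard_value"] = spec.v_max
                    row["standard_relation"] = ">"

        violations = itertools.cycle(
            (
                {"confidence_score": 5},
                {"standard_units": "ug.mL-1"},
                {"activity_comment": "Inconclusive"},
                {"potential_duplicates": 1},
                {"data_validity_comment": "Potential author error"},
                {"assay_type": "F"},
                {"smiles": "C1CC("},  # corrupted structure
            )
        )
        for j in range(n_junk):
            smiles, true_p = self.sample_molecule()
            row = activity_row(f"JNK{j + 1:06d}", smiles, true_p)
            row.update(next(violations))
            rows.append(row)

        table = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
        return table.iloc[rng.permutation(len(table))].reset_index(drop=True)


def true_activity(smiles: str, generator: SARGenerator) -> float:
    """Noiseless planted pIC50 of a molecule emitted by ``generator``."""
    return generator.true_activity(smiles)


def generate_activity_table(spec: SARSpec) -> pd.DataFrame:
    """Generate one raw activity table (see :class:`SARGenerator`)."""
    return SARGenerator(spec).generate_table()


# ---------------------------------------------------------------------------
# Scaffold-profile harness for the diversity metrics
# ---------------------------------------------------------------------------

def enumerate_carbon_skeletons(count: int) -> list[Skeleton]:
    """Deterministic list of distinct carbon skeletons (single rings and
    linker-joined ring pairs), sorted ascending by size; a desk-scale
    stand-in for a database-wide scaffold inventory."""

    def ring(k: int, digit: int) -> str:
        return f"C{digit}" + "C" * (k - 2) + f"C{digit}"

    raw = [ring(k, 1) for k in range(3, 21)]
    raw += [
        ring(a, 1) + "C" * link + ring(b, 2)
        for a in range(3, 13)
        for b in range(a, 13)
        for link in range(0, 5)
    ]
    seen = {}
    for smi in raw:
        mol = Chem.MolFromSmiles(smi)
        canonical = Chem.MolToSmiles(mol)
        seen.setdefault(canonical, Skeleton(mol.GetNumAtoms(), canonical))
    skeletons = sorted(seen.values())
    if count > len(skeletons):
        raise ValueError(f"can enumerate at most {len(skeletons)} skeletons")
    return skeletons[:count]


def generate_scaffold_profile(
    bin_probabilities, scheme: BinningScheme, n: int, seed: int
) -> pd.DataFrame:
    """Curated-style dataset whose compounds fall in the scheme's bins per a
    multinomial draw from ``bin_probabilities``."""
    p = np.asarray(bin_probabilities, dtype=float)
    if len(p) != scheme.n_bins:
        raise ValueError(f"expected {scheme.n_bins} bin probabilities, got {len(p)}")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("bin probabilities must be non-negative and sum to 1")
    for i in np.nonzero(p > 0)[0]:
        if not scheme.bin_members(int(i)):
            raise ValueError(f"probability mass on empty bin {i}")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, p)
    smiles = []
    for i, c in enumerate(counts):
        if c == 0:
            continue
        members = scheme.bin_members(i)
        picks = rng.integers(0, len(members), size=c)
        smiles.extend(members[int(j)].smiles for j in picks)
    rng.shuffle(smiles)
    return pd.DataFrame(
        {
            "canonical_smiles": smiles,
            "p_activity": 6.0,
            "relation": "=",
            "target_id": "PROFILE",
        }
    )
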