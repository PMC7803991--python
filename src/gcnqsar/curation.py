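"""Curation of ChEMBL-style activity tables into per-target regression datasets.

The raw input is a table of assay measurements (one row per measurement)
with the usual ChEMBL activity columns.  Curation proceeds in four steps:

1. **Filtering** — keep only binding-assay rows (``assay_type = B``) with a
   target-assignment confidence score of at least 6, values in nM, a
   recognised censoring relation, no disqualifying activity or validity
   comment, and no potential-duplicate flag.
2. **Structure standardization** — strip salts/solvents (keep the largest
   organic fragment), neutralize simple protonation states, and emit a
   canonical SMILES (rejecting strings longer than 1000 characters).
3. **Transformation** — convert the measured value ``v`` (nM) to the
   p-activity scale, pIC50 = 9 − log10(v), i.e. −log10 of the molar value.
4. **Deduplication** — when a compound–target pair has several measurements,
   keep the most active one (maximum pIC50).

Censored measurements (relation ``>`` or ``<``) are retained as-is and
regressed as point values; the relation is kept for provenance.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # parse failures are reported, not printed

# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

#: Columns a raw activity table must provide.
REQUIRED_COLUMNS = (
    "compound_id",
    "smiles",
    "standard_type",
    "standard_value",
    "standard_units",
    "standard_relation",
    "assay_type",
    "confidence_score",
    "activity_comment",
    "potential_duplicates",
    "data_validity_comment",
    "target_id",
)

#: Columns of a curated dataset.
CURATED_COLUMNS = ("canonical_smiles", "p_activity", "relation", "target_id")

ALLOWED_TYPES = ("IC50", "EC50", "Ki", "Kd", "Km")

#: Unicode relation spellings normalised to ASCII.
_RELATION_ALIASES = {"≥": ">=", "≤": "<=", "=>": ">=", "=<": "<="}


class SchemaError(ValueError):
    """A required column is missing from the input table."""


@dataclass(frozen=True)
class ActivityRecord:
    """One raw assay measurement with every curation-relevant field."""

    compound_id: str
    smiles: str
    standard_type: str
    standard_value: float
    standard_units: str
    standard_relation: str
    assay_type: str
    confidence_score: int
    activity_comment: str = ""
    potential_duplicates: int = 0
    data_validity_comment: str = ""
    target_id: str = ""


@dataclass(frozen=True)
class CuratedRecord:
    """One deduplicated (compound, target) activity on the pIC50 scale."""

    canonical_smiles: str
    p_activity: float
    relation: str
    target_id: str


@dataclass
class FilterConfig:
    """Row-level filter settings mirroring the extraction protocol."""

    min_confidence: int = 6
    allowed_assay_types: frozenset = frozenset({"B"})
    allowed_units: frozenset = frozenset({"nM"})
    allowed_types: frozenset = frozenset(ALLOWED_TYPES)
    allowed_relations: frozenset = frozenset({">", ">=", "=", "<=", "<"})
    banned_activity_comments: frozenset = frozenset({"Inconclusive", "Not determined"})
    banned_validity_comments: frozenset = frozenset({"Potential author error"})


@dataclass
class CurationReport:
    """Bookkeeping for one curation run.

    Invariant: ``sum(drops.values()) + n_standardization_failures +
    n_collapsed + n_survivors == n_input``.
    """

    n_input: int = 0
    drops: dict = field(default_factory=dict)
    n_standardization_failures: int = 0
    n_collapsed: int = 0
    n_survivors: int = 0

    @property
    def n_dropped(self) -> int:
        return sum(self.drops.values())

    def check(self) -> None:
        total = self.n_dropped + self.n_standardization_failures + self.n_collapsed + self.n_survivors
        if total != self.n_input:
            raise AssertionError(
                f"curation bookkeeping broken: {total} accounted vs {self.n_input} input rows"
            )

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def normalize_relation(rel) -> str:
    rel = "" if rel is None or (isinstance(rel, float) and math.isnan(rel)) else str(rel).strip()
    rel = rel.strip("'\"")
    return _RELATION_ALIASES.get(rel, rel)


def _validate_schema(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"required column missing from activity table: {col!r}")


def filter_records(
    table: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, CurationReport]:
    """Apply the row-level selection predicates to a raw activity table.

    Returns the surviving rows (input order preserved) and a report
    itemising how many rows each rule removed.  A row is charged to the
    first rule it fails, in a fixed rule order.
    """
    config = config or FilterConfig()
    _validate_schema(table)

    value = pd.to_numeric(table["standard_value"], errors="coerce")
    relation = table["standard_relation"].map(normalize_relation)
    comment = table["activity_comment"].fillna("").astype(str).str.strip()
    validity = table["data_validity_comment"].fillna("").astype(str).str.strip()
    dup_flag = pd.to_numeric(table["potential_duplicates"], errors="coerce").fillna(1)
    confidence = pd.to_numeric(table["confidence_score"], errors="coerce").fillna(-1)

    rules = [
        ("nonpositive_value", ~(value > 0)),
        ("standard_type", ~table["standard_type"].isin(config.allowed_types)),
        ("confidence_score", confidence < config.min_confidence),
        ("assay_type", ~table["assay_type"].isin(config.allowed_assay_types)),
        ("standard_units", ~table["standard_units"].isin(config.allowed_units)),
        ("standard_relation", ~relation.isin(config.allowed_relations)),
        ("activity_comment", comment.isin(config.banned_activity_comments)),
        ("potential_duplicates", dup_flag != 0),
        ("data_validity_comment", validity.isin(config.banned_validity_comments)),
    ]

    report = CurationReport(n_input=len(table))
    dropped = np.zeros(len(table), dtype=bool)
    for name, mask in rules:
        hits = np.asarray(mask, dtype=bool) & ~dropped
        report.drops[name] = int(hits.sum())
        dropped |= hits

    survivors = table.loc[~dropped].copy()
    survivors["standard_relation"] = relation.loc[~dropped]
    report.n_survivors = len(survivors)
    return survivors, report


# ---------------------------------------------------------------------------
# Structure standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizationFailure:
    """Failure value carrying the reason a SMILES could not be standardized."""

    smiles: str
    reason: str


MAX_SMILES_LENGTH = 1000

# Atoms carrying a +1/-1 charge that is not part of a zwitterionic pair and
# can be fixed by adding/removing a proton (simple acids and bases).
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    if not matches:
        return mol
    mol = Chem.RWMol(mol)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(h_count - charge, 0))
        atom.UpdatePropertyCache()
    return mol.GetMol()


def standardize_structure(smiles: str) -> str | StandardizationFailure:
    """Standardize one SMILES: largest organic fragment, neutralized, canonical.

    This approximates the proprietary standardizer used to prepare the
    original extract: counter-ions and solvents are removed by keeping the
    fragment with the most heavy atoms (preferring carbon-containing
    fragments), simple protonated/deprotonated groups are returned to their
    neutral form, and the toolkit's canonical SMILES is emitted.  Outputs
    longer than 1000 characters are rejected.  Failures are returned as
    values, never raised, so a batch is never aborted by one bad row.
    """
    if not smiles or not str(smiles).strip():
        return StandardizationFailure(smiles, "empty")
    smiles = str(smiles).strip()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return StandardizationFailure(smiles, "unparseable")
    try:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
        pool = organic or list(frags)
        mol = max(pool, key=lambda m: m.GetNumHeavyAtoms())
        mol = _neutralize(mol)
        Chem.SanitizeMol(mol)
        canonical = Chem.MolToSmiles(mol)
    except Exception as exc:  # pragma: no cover - rdkit edge cases
        return StandardizationFailure(smiles, f"sanitization: {exc}")
    if len(canonical) > MAX_SMILES_LENGTH:
        return StandardizationFailure(smiles, "smiles_too_long")
    return canonical


# ---------------------------------------------------------------------------
# p-activity transform and deduplication
# ---------------------------------------------------------------------------

def to_p_activity(value_nm):
    """pIC50 = 9 − log10(v) for v in nM (−log10 of the molar value).

    Accepts scalars or arrays; values must be strictly positive.
    """
    arr = np.asarray(value_nm, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("p-activity requires strictly positive values (nM)")
    out = 9.0 - np.log10(arr)
    return float(out) if np.isscalar(value_nm) or arr.ndim == 0 else out


def aggregate_duplicates(curated: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse repeated (canonical_smiles, target_id) pairs to the most
    active measurement (maximum pIC50); ties keep the first occurrence.

    Returns the collapsed table (original relative order) and the number of
    rows removed.
    """
    if curated.empty:
        return curated.copy(), 0
    idx = (
        curated.reset_index(drop=True)
        .groupby(["canonical_smiles", "target_id"], sort=False)["p_activity"]
        .idxmax()  # first occurrence of the group maximum
    )
    keep = sorted(idx.tolist())
    out = curated.reset_index(drop=True).loc[keep].reset_index(drop=True)
    return out, len(curated) - len(out)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def build_dataset(
    table: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, CurationReport]:
    """Filter → standardize → transform → deduplicate a raw activity table.

    Returns a curated dataset with columns ``canonical_smiles, p_activity,
    relation, target_id`` and a report accounting for every input row.
    An empty survivor set is a warning, not an error.
    """
    survivors, report = filter_records(table, config)

    canonical = []
    ok = np.ones(len(survivors), dtype=bool)
    cache: dict[str, str | StandardizationFailure] = {}
    for i, smi in enumerate(survivors["smiles"].astype(str)):
        res = cache.get(smi)
        if res is None:
            res = cache[smi] = standardize_structure(smi)
        if isinstance(res, StandardizationFailure):
            ok[i] = False
            canonical.append(None)
        else:
            canonical.append(res)
    report.n_standardization_failures = int((~ok).sum())

    curated = pd.DataFrame(
        {
            "canonical_smiles": np.asarray(canonical, dtype=object)[ok],
            "p_activity": to_p_activity(
                pd.to_numeric(survivors["standard_value"]).to_numpy()[ok]
            )
            if ok.any()
            else np.empty(0),
            "relation": survivors["standard_relation"].to_numpy()[ok],
            "target_id": survivors["target_id"].to_numpy()[ok],
        }
    )
    curated, n_collapsed = aggregate_duplicates(curated)
    report.n_collapsed = n_collapsed
    report.n_survivors = len(curated)
    report.check()
    if curated.empty:
        warnings.warn("curation produced an empty dataset", stacklevel=2)
    return curated, report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_activity_table(
    path, column_map: Mapping[str, str] | None = None, sep: str | None = None
) -> pd.DataFrame:
    """Read a raw activity table from CSV/TSV, renaming columns if needed.

    ``column_map`` maps file column names to the canonical schema names.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    table = pd.read_csv(path, sep=sep)
    if column_map:
        table = table.rename(columns=dict(column_map))
    _validate_schema(table)
    return table


def write_curated(curated: pd.DataFrame, path) -> None:
    curated.to_csv(path, index=False, columns=list(CURATED_COLUMNS))


def read_curated(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in CURATED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"curated dataset missing columns: {missing}")
    return table


def records_to_table(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    """Convert a sequence of :class:`ActivityRecord` to the tabular form."""
    return pd.DataFrame([asdict(r) for r in records], columns=list(REQUIRED_COLUMNS))
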