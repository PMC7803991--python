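"""Virtual screening: rank a candidate library by predicted activity under
lipophilicity, selectivity, and prior-assay exclusion filters.

The filter set mirrors a selectivity-driven transporter screen: keep
compounds with logP above a floor (central-nervous-system permeability
proxy), predicted pIC50 on the target at or above a potency threshold,
predicted pIC50 on the anti-target at or below a selectivity ceiling, and
no prior assay record against the excluded target panel.  Hits are ranked
by descending target prediction (stable on ties) and carry their
per-criterion values for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen


@dataclass
class ScreenCriteria:
    """Thresholds of the screen; the potency floor must exceed the
    anti-target ceiling for the selectivity window to make sense."""

    logp_min: float = 2.0
    target_pic50_min: float = 7.5
    antitarget_pic50_max: float = 6.0
    excluded_assay_compounds: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        import math

        # infinite bounds mean "filter disabled" and skip the window check
        if (
            math.isfinite(self.target_pic50_min)
            and math.isfinite(self.antitarget_pic50_max)
            and not self.target_pic50_min > self.antitarget_pic50_max
        ):
            raise ValueError("target potency floor must exceed the anti-target ceiling")


def compute_logp(smiles: str) -> float:
    """Atomic-contribution (Crippen) octanol/water logP estimate."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES for logP: {smiles!r}")
    return float(Crippen.MolLogP(mol))


def screen(
    candidates,
    target_preds,
    antitarget_preds,
    criteria: ScreenCriteria | None = None,
    return_all: bool = False,
) -> pd.DataFrame:
    """Filter and rank candidates; returns the audited hit table.

    ``candidates`` is an iterable of (id, smiles); ``target_preds`` and
    ``antitarget_preds`` map id → predicted pIC50.  Candidates missing a
    prediction are skipped with a warning.  With ``return_all`` the full
    audit table (pass flags per criterion) is returned instead of the hits.
    """
    criteria = criteria or ScreenCriteria()
    rows = []
    for ident, smiles in candidates:
        if ident not in target_preds or ident not in antitarget_preds:
            warnings.warn(f"no prediction for candidate {ident!r}; skipped")
            continue
        logp = compute_logp(smiles)
        t = float(target_preds[ident])
        a = float(antitarget_preds[ident])
        rows.append(
            {
                "id": ident,
                "smiles": smiles,
                "logp": logp,
                "target_pred": t,
                "antitarget_pred": a,
                "pass_logp": logp > criteria.logp_min,
                "pass_target": t >= criteria.target_pic50_min,
                "pass_antitarget": a <= criteria.antitarget_pic50_max,
                "pass_exclusion": ident not in criteria.excluded_assay_compounds,
            }
        )
    audit = pd.DataFrame(
        rows,
        columns=[
            "id", "smiles", "logp", "target_pred", "antitarget_pred",
            "pass_logp", "pass_target", "pass_antitarget", "pass_exclusion",
        ],
    )
    audit["is_hit"] = (
        audit[["pass_logp", "pass_target", "pass_antitarget", "pass_exclusion"]].all(axis=1)
        if len(audit)
        else pd.Series([], dtype=bool)
    )
    audit = audit.sort_values("target_pred", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    if return_all:
        return audit
    return audit.loc[audit["is_hit"]].reset_index(drop=True)
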