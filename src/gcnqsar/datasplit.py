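"""Seeded two-stage random split of a curated dataset.

The dataset is first divided into a training-validation pool (90%) and a
test set (10%); the pool is then divided into a training set (88.8%) and a
validation set (11.2%), giving overall shares of approximately 80:10:10.

The assignment is a uniformly random permutation determined entirely by the
seed: the input table is order-normalized (sorted by compound and target)
before permuting, so the split is a pure function of the set of records,
the seed, and the two fractions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SplitResult:
    """Three pairwise-disjoint subsets whose union is the input dataset."""

    train: pd.DataFrame
    valid: pd.DataFrame
    test: pd.DataFrame
    seed: int
    fractions: tuple[float, float]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.valid), len(self.test)

    def manifest(self) -> dict:
        key = lambda df: (df["canonical_smiles"] + "\x1f" + df["target_id"].astype(str)).tolist()
        return {
            "seed": self.seed,
            "fractions": list(self.fractions),
            "sizes": {"train": len(self.train), "valid": len(self.valid), "test": len(self.test)},
            "members": {"train": key(self.train), "valid": key(self.valid), "test": key(self.test)},
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def split_dataset(
    dataset: pd.DataFrame, seed: int, f1: float = 0.90, f2: float = 0.888
) -> SplitResult:
    """Split a curated dataset into train/valid/test at the given fractions.

    ``f1`` is the first-stage training-validation share, ``f2`` the
    second-stage training share.  Subset sizes are fixed by rounding
    (half away from zero) the test count first, then the validation count;
    the remainder goes to training.
    """
    n = len(dataset)
    if n < 3:
        raise ValueError(f"cannot split {n} records into three subsets")
    if not (0 < f1 < 1 and 0 < f2 < 1):
        raise ValueError("fractions must lie strictly between 0 and 1")

    n_test = _round_half_away((1.0 - f1) * n)
    n_pool = n - n_test
    n_valid = _round_half_away((1.0 - f2) * n_pool)
    n_train = n_pool - n_valid
    if min(n_train, n_valid, n_test) < 1:
        raise ValueError("fractions leave an empty subset")

    normalized = dataset.sort_values(
        ["canonical_smiles", "target_id"], kind="mergesort"
    ).reset_index(drop=True)
    order = np.random.default_rng(seed).permutation(n)
    test = normalized.iloc[order[:n_test]].reset_index(drop=True)
    valid = normalized.iloc[order[n_test : n_test + n_valid]].reset_index(drop=True)
    train = normalized.iloc[order[n_test + n_valid :]].reset_index(drop=True)
    return SplitResult(train=train, valid=valid, test=test, seed=seed, fractions=(f1, f2))
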