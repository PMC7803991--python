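"""Regression metrics, hyperparameter search, retention rules, ensembling.

Model quality is summarised by the usual regression statistics

    MAE  = (1/n) Σ |f_i − y_i|
    RMSE = sqrt((1/n) Σ (f_i − y_i)²)           (MAE ≤ RMSE ≤ √n·MAE)
    R²   = 1 − RSS/TSS

and by the composite selection score

    2R2_MAE = (R² − MAE) + R²

which prefers, among settings of similar MAE, the one with the better R².

Hyperparameters are searched per network-depth tier (one conv layer, two,
or three-to-four), each tier repeated with several random initialisations;
each repeat keeps the trial with the maximal validation 2R2_MAE.  Tiered
retention then applies:

* tier 1: if every repeat's R² is below 0.45, the tier is flagged for an
  extended re-search (its candidates are kept either way);
* tier 2: candidates need R² ≥ 0.40;
* tier 3–4: candidates must beat every shallower retained candidate's R².

Retained candidates are retrained with a fixed seed; a model whose
retraining R² falls more than ``delta`` below its search-time R² is deemed
non-reproducing and excluded.  Surviving models form an ensemble whose
prediction is the unweighted mean of the member predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .gcn import GCNConfig, GCNModel, GraphBatch, TrainingDiverged, train_fixed_epochs

# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_pair(y, f):
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.ndim != 1:
        raise ValueError(f"prediction set shape mismatch: {y.shape} vs {f.shape}")
    if y.size < 1:
        raise ValueError("empty prediction set")
    return y, f


def compute_mae(y, f) -> float:
    """Mean absolute error between observed y and predicted f."""
    y, f = _check_pair(y, f)
    return float(np.mean(np.abs(f - y)))


def compute_rmse(y, f) -> float:
    """Root-mean-square error between observed y and predicted f."""
    y, f = _check_pair(y, f)
    return float(np.sqrt(np.mean((f - y) ** 2)))


def compute_r2(y, f) -> float:
    """Coefficient of determination 1 − RSS/TSS; undefined for constant y."""
    y, f = _check_pair(y, f)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0.0:
        raise ValueError("R² undefined: observed values are constant (TSS = 0)")
    return 1.0 - float(np.sum((y - f) ** 2)) / tss


def compute_2r2_mae(r2: float, mae: float) -> float:
    """Composite selection score (R² − MAE) + R²; higher is better."""
    return (r2 - mae) + r2


# ---------------------------------------------------------------------------
# Search space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter ranges (inclusive) explored during model selection."""

    conv_size: tuple = (32, 2048)
    dense_size: tuple = (16, 2048)
    learning_rate: tuple = (1e-4, 2e-3)
    dropout: tuple = (0.0, 0.5)
    epoch: tuple = (20, 200)
    batch_size: tuple = (10, 100)

    def __post_init__(self):
        for name in ("conv_size", "dense_size", "learning_rate", "dropout", "epoch", "batch_size"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"search range for {name} has lower bound above upper")

    @classmethod
    def small(cls) -> "SearchSpace":
        """Reduced ranges used for smaller datasets."""
        return cls(conv_size=(16, 512), dense_size=(16, 512))

    @classmethod
    def desk(cls) -> "SearchSpace":
        """Desk-scale ranges for synthetic-benchmark runs on one CPU.

        The planted-SAR datasets are small and learnable by narrow
        networks, so the size and epoch ranges are cut further than the
        small-dataset variant; the learning-rate, dropout and batch ranges
        are unchanged.
        """
        return cls(conv_size=(16, 128), dense_size=(16, 128), epoch=(20, 60))


#: Tier labels: 1 and 2 conv layers, and the grouped 3–4 layer tier.
TIERS = (1, 2, 3)


@dataclass
class CandidateResult:
    """Best trial of one (tier, repeat) search, scored on the validation set."""

    config: GCNConfig
    tier: int
    epochs: int
    valid_mae: float
    valid_r2: float
    valid_trmae: float
    search_seed: int
    retained: bool = True


# ---------------------------------------------------------------------------
# Trial sampling and Bayesian optimization
# ---------------------------------------------------------------------------

def _decode(x: np.ndarray, space: SearchSpace, tier: int) -> tuple[GCNConfig, int]:
    """Map a point of the unit cube to a configuration.

    Sizes and learning rate are sampled log-uniformly, dropout / epoch /
    batch size uniformly; for the 3–4 layer tier the last coordinate picks
    the layer count.
    """
    def log_int(u, lo, hi):
        return int(round(math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))))

    def lin_int(u, lo, hi):
        return int(round(lo + u * (hi - lo)))

    n_layers = tier if tier < 3 else (3 if x[6] < 0.5 else 4)
    cfg = GCNConfig(
        n_conv_layers=n_layers,
        conv_size=log_int(x[0], *space.conv_size),
        dense_size=log_int(x[1], *space.dense_size),
        learning_rate=float(
            math.exp(
                math.log(space.learning_rate[0])
                + x[2] * (math.log(space.learning_rate[1]) - math.log(space.learning_rate[0]))
            )
        ),
        dropout=float(space.dropout[0] + x[3] * (space.dropout[1] - space.dropout[0])),
        batch_size=lin_int(x[5], *space.batch_size),
    )
    return cfg, lin_int(x[4], *space.epoch)


def _expected_improvement(gp, X, best):
    from scipy.stats import norm

    mu, sd = gp.predict(X, return_std=True)
    sd = np.maximum(sd, 1e-9)
    z = (best - mu) / sd
    return (best - mu) * norm.cdf(z) + sd * norm.pdf(z)


def _bo_minimize(objective, n_dim, n_iter, rng, backend):
    """Minimize a noisy black-box over [0,1]^n_dim; returns all evaluations.

    ``gp_ei`` fits a Matérn-5/2 Gaussian process and maximizes expected
    improvement over a random candidate pool; ``random`` samples uniformly.
    """
    xs, fs = [], []
    n_init = n_iter if backend == "random" else max(3, n_iter // 3)
    for _ in range(min(n_init, n_iter)):
        x = rng.random(n_dim)
        xs.append(x)
        fs.append(objective(x))
    if backend == "gp_ei":
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

        while len(xs) < n_iter:
            finite = np.isfinite(fs)
            if finite.sum() >= 2:
                kernel = ConstantKernel(1.0) * Matern(nu=2.5, length_scale=np.ones(n_dim)) \
                    + WhiteKernel(1e-4)
                gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                              random_state=int(rng.integers(2**31)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gp.fit(np.asarray(xs)[finite], np.asarray(fs)[finite])
                pool = rng.random((256, n_dim))
                x = pool[int(np.argmax(_expected_improvement(gp, pool, np.min(np.asarray(fs)[finite]))))]
            else:
                x = rng.random(n_dim)
            xs.append(x)
            fs.append(objective(x))
    return xs, fs


def search_hyperparameters(
    train_data,
    valid_data,
    space: SearchSpace | None = None,
    tiers=TIERS,
    n_iter: int = 100,
    n_repeats: int = 4,
    backend: str = "gp_ei",
    seed: int = 0,
) -> list[CandidateResult]:
    """Tiered, repeated hyperparameter search minimizing validation MAE.

    For every tier and repeat, ``n_iter`` trials are run (each trial trains
    a fresh network for its sampled epoch count); the trial with maximal
    validation 2R2_MAE becomes that repeat's candidate.  Diverged trials
    are recorded as failures; a (tier, repeat) whose every trial diverged
    contributes no candidate.
    """
    if backend not in ("gp_ei", "random"):
        raise ValueError(f"unknown search backend: {backend}")
    space = space or SearchSpace()
    y_valid = np.asarray(valid_data[1], dtype=float)
    candidates: list[CandidateResult] = []
    master = np.random.default_rng(seed)
    for tier in tiers:
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier}; expected one of {TIERS}")
        for repeat in range(n_repeats):
            repeat_seed = int(master.integers(2**31))
            rng = np.random.default_rng(repeat_seed)
            n_dim = 7 if tier == 3 else 6
            trials = []

            def objective(x):
                cfg, epochs = _decode(x, space, tier)
                cfg = replace(cfg, seed=int(rng.integers(2**31)))
                try:
                    model, trace = train_fixed_epochs(train_data, valid_data, cfg, epochs)
                except TrainingDiverged:
                    return float("inf")
                mae = trace.valid_mae[-1]
                r2 = trace.valid_r2[-1]
                trials.append((cfg, epochs, mae, r2, compute_2r2_mae(r2, mae)))
                return mae

            _bo_minimize(objective, n_dim, n_iter, rng, backend)
            if not trials:
                warnings.warn(f"all trials diverged for tier {tier}, repeat {repeat}")
                continue
            cfg, epochs, mae, r2, trmae = max(trials, key=lambda t: t[4])
            candidates.append(
                CandidateResult(
                    config=cfg, tier=tier, epochs=epochs, valid_mae=mae,
                    valid_r2=r2, valid_trmae=trmae, search_seed=repeat_seed,
                )
            )
    return candidates


# ---------------------------------------------------------------------------
# Tiered retention and reproducibility
# ---------------------------------------------------------------------------

def best_candidate(candidates: list[CandidateResult]) -> CandidateResult:
    """Candidate with the maximal validation 2R2_MAE (earliest on ties)."""
    if not candidates:
        raise ValueError("empty candidate list")
    return max(candidates, key=lambda c: c.valid_trmae)


@dataclass
class TierDecision:
    """Outcome of the retention rules: kept candidates and re-search flags."""

    retained: list = field(default_factory=list)
    research_tiers: list = field(default_factory=list)


def apply_tier_rules(
    candidates: list[CandidateResult],
    tier1_research_threshold: float = 0.45,
    tier2_min_r2: float = 0.40,
) -> TierDecision:
    """Apply the per-tier retention rules to per-repeat best candidates."""
    decision = TierDecision()
    tier1 = [c for c in candidates if c.tier == 1]
    tier2 = [c for c in candidates if c.tier == 2]
    deeper = [c for c in candidates if c.tier == 3]

    if tier1 and all(c.valid_r2 < tier1_research_threshold for c in tier1):
        decision.research_tiers.append(1)
    for c in tier1:
        c.retained = True
    for c in tier2:
        c.retained = c.valid_r2 >= tier2_min_r2
    kept2 = [c for c in tier2 if c.retained]
    shallow_best = max(
        (c.valid_r2 for c in tier1 + kept2), default=-np.inf
    )
    for c in deeper:
        c.retained = c.valid_r2 > shallow_best
    decision.retained = [c for c in candidates if c.retained]
    return decision


def filter_reproducible(
    candidates_with_retrain: list[tuple[CandidateResult, float]],
    delta: float = 0.15,
) -> list[CandidateResult]:
    """Drop candidates whose retraining validation R² fell more than
    ``delta`` below the search-time value (non-reproducing models)."""
    kept = []
    for cand, retrain_r2 in candidates_with_retrain:
        if retrain_r2 >= cand.valid_r2 - delta:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Ensembling
# ---------------------------------------------------------------------------

def ensemble_predict(models: list[GCNModel], graphs) -> np.ndarray:
    """Unweighted average of member predictions per molecule."""
    if not models:
        raise ValueError("ensemble requires at least one model")
    if isinstance(graphs, GraphBatch):
        preds = [m.predict_batch(graphs) for m in models]
    else:
        preds = [m.predict(graphs) for m in models]
    return np.mean(preds, axis=0)
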