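"""End-to-end orchestration: curate → split → search → train → ensemble →
evaluate → scaffold-diversity diagnostics, from one configuration.

Every stage is seeded and the report contains only deterministic content,
so a rerun with the same configuration reproduces the report exactly.
Individual-model metrics are reported as mean ± sd across ensemble
members; ensemble metrics are computed from the same prediction sets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import curation, datasplit, diversity, synthetic
from .featurize import featurize_many
from .gcn import GCNConfig, train
from .modelsel import (
    CandidateResult,
    SearchSpace,
    apply_tier_rules,
    compute_mae,
    compute_r2,
    compute_rmse,
    ensemble_predict,
    filter_reproducible,
    search_hyperparameters,
)

log = logging.getLogger("gcnqsar.pipeline")


@dataclass
class RunConfig:
    """One pipeline run: data source, split, search budget, retention and
    diversity settings.

    The default search budget (10 iterations × 2 repeats × tiers {1, 2},
    reduced hyperparameter ranges) is a desk-scale regime; the full-scale
    regime of the original protocol corresponds to ``n_iter=100``,
    ``n_repeats=4``, ``tiers=(1, 2, 3)`` and the default ranges.
    """

    sar: synthetic.SARSpec | None = None
    input_csv: str | None = None
    split_seed: int = 0
    f1: float = 0.90
    f2: float = 0.888
    space: str = "desk"            # "desk", "small" or "default" ranges
    tiers: tuple = (1, 2)
    n_iter: int = 10
    n_repeats: int = 2
    backend: str = "gp_ei"
    search_seed: int = 0
    research_budget: int | None = None   # extra tier-1 iterations when flagged
    tier1_research_threshold: float = 0.45
    tier2_min_r2: float = 0.40
    reproducibility_delta: float = 0.15
    retrain_seed: int = 2020
    max_blocks: int | None = None
    bin_capacity: int | None = None      # None: capacity giving ~15 bins
    fixed_config: GCNConfig | None = None  # skip the search, train this one

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sar" in raw and raw["sar"] is not None:
            raw["sar"] = synthetic.SARSpec(**{
                k: tuple(tuple(x) for x in v) if k.endswith("_library") else v
                for k, v in raw["sar"].items()
            })
        if "fixed_config" in raw and raw["fixed_config"] is not None:
            raw["fixed_config"] = GCNConfig(**raw["fixed_config"])
        if "tiers" in raw:
            raw["tiers"] = tuple(raw["tiers"])
        return cls(**raw)


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    config: dict
    curation: dict
    sizes: dict
    candidates: list
    members: list
    metrics: dict
    diversity: dict
    versions: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _subset_metrics(y, f) -> dict:
    return {
        "mae": compute_mae(y, f),
        "rmse": compute_rmse(y, f),
        "r2": compute_r2(y, f),
    }


def _candidate_dict(c: CandidateResult) -> dict:
    d = asdict(c.config)
    d.update(
        tier=c.tier, epochs=c.epochs, valid_mae=c.valid_mae, valid_r2=c.valid_r2,
        valid_trmae=c.valid_trmae, search_seed=c.search_seed, retained=c.retained,
    )
    return d


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the full pipeline and return (and optionally persist) the report."""
    from pathlib import Path

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # -- data --------------------------------------------------------------
    if config.sar is not None:
        log.info("stage=simulate seed=%d n=%d", config.sar.seed, config.sar.n)
        raw = synthetic.generate_activity_table(config.sar)
    elif config.input_csv is not None:
        raw = curation.read_activity_table(config.input_csv)
    else:
        raise ValueError("run config needs either a SARSpec or an input table")

    log.info("stage=curate rows=%d", len(raw))
    curated, report = curation.build_dataset(raw)
    if curated.empty:
        raise RuntimeError("stage curate: no rows survived curation")
    if out is not None:
        curation.write_curated(curated, out / "curated.csv")
        report.to_json(out / "curation_report.json")

    log.info("stage=split seed=%d n=%d", config.split_seed, len(curated))
    split = datasplit.split_dataset(curated, config.split_seed, config.f1, config.f2)
    if out is not None:
        for name in ("train", "valid", "test"):
            curation.write_curated(getattr(split, name), out / f"{name}.csv")
        split.write_manifest(out / "split_manifest.json")

    subsets = {}
    for name in ("train", "valid", "test"):
        df = getattr(split, name)
        subsets[name] = (
            featurize_many(df["canonical_smiles"]),
            df["p_activity"].to_numpy(dtype=float),
        )

    # -- model selection ---------------------------------------------------
    spaces = {"desk": SearchSpace.desk, "small": SearchSpace.small, "default": SearchSpace}
    space = spaces[config.space]()
    if config.fixed_config is not None:
        log.info("stage=search skipped (fixed config)")
        candidates, retained = [], None
    else:
        log.info(
            "stage=search tiers=%s n_iter=%d n_repeats=%d backend=%s seed=%d",
            config.tiers, config.n_iter, config.n_repeats, config.backend,
            config.search_seed,
        )
        candidates = search_hyperparameters(
            subsets["train"], subsets["valid"], space, config.tiers,
            config.n_iter, config.n_repeats, config.backend, config.search_seed,
        )
        decision = apply_tier_rules(
            candidates, config.tier1_research_threshold, config.tier2_min_r2
        )
        if 1 in decision.research_tiers:
            budget = config.research_budget if config.research_budget is not None else config.n_iter
            if budget > 0:
                log.info("stage=research tier=1 budget=%d", budget)
                extra = search_hyperparameters(
                    subsets["train"], subsets["valid"], space, (1,), budget,
                    config.n_repeats, config.backend, config.search_seed + 1,
                )
                candidates = candidates + extra  # augment the pool
                decision = apply_tier_rules(
                    candidates, config.tier1_research_threshold, config.tier2_min_r2
                )
        retained = decision.retained

    # -- final training with the block rule and reproducibility check ------
    members = []
    if config.fixed_config is not None:
        cfg = replace(config.fixed_config, seed=config.retrain_seed)
        model, trace = train(subsets["train"], subsets["valid"], cfg, config.max_blocks)
        idx = trace.epochs.index(trace.selected_epoch)
        cand = CandidateResult(
            config=cfg, tier=cfg.n_conv_layers if cfg.n_conv_layers < 3 else 3,
            epochs=trace.selected_epoch, valid_mae=trace.valid_mae[idx],
            valid_r2=trace.valid_r2[idx], valid_trmae=trace.valid_trmae[idx],
            search_seed=config.retrain_seed,
        )
        members = [(cand, model, trace, cand.valid_r2)]
    else:
        retrained = []
        for cand in retained:
            cfg = replace(cand.config, seed=config.retrain_seed)
            log.info("stage=retrain tier=%d config=%s", cand.tier, cfg)
            model, trace = train(subsets["train"], subsets["valid"], cfg, config.max_blocks)
            idx = trace.epochs.index(trace.selected_epoch)
            retrained.append((cand, model, trace, trace.valid_r2[idx]))
        kept = filter_reproducible(
            [(c, r2) for c, _, _, r2 in retrained], config.reproducibility_delta
        )
        kept_ids = {id(c) for c in kept}
        members = [m for m in retrained if id(m[0]) in kept_ids]
        if not members and retrained:
            log.warning("no model reproduced its search performance; keeping the best")
            members = [max(retrained, key=lambda m: m[3])]
    if not members:
        raise RuntimeError("stage train: no ensemble members available")

    if out is not None:
        for i, (_, model, trace, _) in enumerate(members):
            model.save(out / f"member{i}.npz")
            trace.to_csv(out / f"member{i}_trace.csv")

    # -- evaluation --------------------------------------------------------
    models = [m for _, m, _, _ in members]
    metrics: dict = {}
    for name, (graphs, y) in subsets.items():
        member_preds = [m.predict(graphs) for m in models]
        member_metrics = [_subset_metrics(y, f) for f in member_preds]
        ens = np.mean(member_preds, axis=0)
        metrics[name] = {
            "ensemble": _subset_metrics(y, ens),
            "member_mean": {
                k: float(np.mean([mm[k] for mm in member_metrics]))
                for k in ("mae", "rmse", "r2")
            },
            "member_sd": {
                k: float(np.std([mm[k] for mm in member_metrics]))
                for k in ("mae", "rmse", "r2")
            },
            "members": member_metrics,
        }

    # -- scaffold-diversity diagnostics -------------------------------------
    skeletons = sorted(
        {diversity.carbon_skeleton(s) for s in curated["canonical_smiles"]}
    )
    capacity = config.bin_capacity or max(1, math.ceil(len(skeletons) / 15))
    scheme = diversity.build_binning(skeletons, capacity)
    full_hist = diversity.dataset_histogram(curated, scheme)
    div = {
        "capacity": capacity,
        "n_bins": scheme.n_bins,
        "n_scaffolds": len(skeletons),
        "H": {"full": diversity.shannon_H(full_hist)},
        "KLD_vs_full": {},
    }
    for name in ("train", "valid", "test"):
        hist = diversity.dataset_histogram(getattr(split, name), scheme)
        div["H"][name] = diversity.shannon_H(hist)
        div["KLD_vs_full"][name] = diversity.kld(hist, full_hist)

    run_report = RunReport(
        config=_config_dict(config),
        curation=dataclasses.asdict(report),
        sizes={
            "input": len(raw), "curated": len(curated),
            "train": len(split.train), "valid": len(split.valid), "test": len(split.test),
        },
        candidates=[_candidate_dict(c) for c in candidates],
        members=[
            {
                **_candidate_dict(c),
                "stopping_epoch": t.stopping_epoch,
                "selected_epoch": t.selected_epoch,
                "retrain_valid_r2": r2,
            }
            for c, _, t, r2 in members
        ],
        metrics=metrics,
        diversity=div,
        versions=_versions(),
    )
    if out is not None:
        run_report.to_json(out / "report.json")
        rows = []
        for subset, block in metrics.items():
            rows.append({"subset": subset, "model": "ensemble", **block["ensemble"]})
            for i, mm in enumerate(block["members"]):
                rows.append({"subset": subset, "model": f"member{i}", **mm})
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    return run_report


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    for key, value in list(d.items()):
        if isinstance(value, tuple):
            d[key] = list(value)
    if d.get("sar") is not None:
        d["sar"] = {
            k: [list(x) for x in v] if k.endswith("_library") else v
            for k, v in d["sar"].items()
        }
    return d


def _versions() -> dict:
    import rdkit
    import sklearn

    from . import __version__

    return {
        "gcnqsar": __version__,
        "numpy": np.__version__,
        "rdkit": rdkit.__version__,
        "sklearn": sklearn.__version__,
    }
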