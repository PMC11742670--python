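"""End-to-end screening orchestration.

One run corresponds to one assay context (one cancer cell line in the
motivating use case): load a reference decision table with measured IC50s
(optionally anchored by a lead compound), select descriptors by fuzzy-rough
dependency, train the 1-D CNN on the selected columns, predict IC50 for a
candidate table, rank candidates by ascending predicted potency and explain
the top hits.  Every artifact is written to the output directory together
with a manifest (config echo + content hashes) so identical configs yield
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem_io, cnn_model, explain, fuzzy_rough
from .chem_io import CompoundRecord, DescriptorTable
from .cnn_model import RegressorConfig, TrainedRegressor
from .fuzzy_rough import ReductResult

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RankedCandidates",
    "PipelineResult",
    "assemble_training_set",
    "rank_candidates",
    "compare_reducts",
    "run_pipeline",
]


@dataclass(frozen=True)
class RunConfig:
    """Machine form of one screening run (data collection through XAI)."""

    reference_csv: str
    candidate_csv: str
    out_dir: str
    target_column: str = "IC50"
    name_column: str | None = None
    lead_name: str | None = None
    lead_handling: str = "include"  # or "exclude"
    bins: int = 3
    fuzzify_method: str = "crisp"
    # screening-scale stopping tolerance on γ: with min-t-norm similarity on
    # continuous descriptors, γ(full) is approached only as nearly every
    # feature is added, so a looser stop than quickreduct's 1e-6 default
    # yields a proper-subset reduct without losing the relevant descriptors
    tolerance: float = 0.01
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    select_features: bool = True
    explainer_samples: int = 1000
    kernel_width: float | None = None
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.lead_handling not in ("include", "exclude"):
            raise ValueError("lead_handling must be 'include' or 'exclude'")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw.update(overrides)
        if "regressor" in raw and isinstance(raw["regressor"], dict):
            reg = dict(raw["regressor"])
            if "conv_filters" in reg:
                reg["conv_filters"] = tuple(reg["conv_filters"])
            raw["regressor"] = RegressorConfig(**reg)
        return cls(**raw)

    def validate_paths(self) -> None:
        for p in (self.reference_csv, self.candidate_csv):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class RankedCandidates:
    """Candidates ordered by ascending predicted IC50 (most potent first)."""

    entries: list[tuple[str, float]]  # (name, predicted IC50 µg/mL)
    model_id: str = ""
    reduct_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        ic50s = [v for _, v in self.entries]
        if any(b < a for a, b in zip(ic50s, ic50s[1:])):
            raise ValueError("predicted IC50 must be non-decreasing down the list")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.entries, columns=["Drug_name", "IC50"]).to_csv(path, index=False)
        return path


def assemble_training_set(
    table: DescriptorTable,
    targets: np.ndarray,
    names: Sequence[str],
    lead: CompoundRecord | None = None,
    lead_descriptors: np.ndarray | None = None,
) -> tuple[DescriptorTable, np.ndarray, list[str]]:
    """Append a measured lead compound to the reference set as a labeled row."""
    if lead is None:
        return table, np.asarray(targets, dtype=float), list(names)
    if lead.ic50 is None:
        raise ValueError(f"lead compound {lead.name!r} has no measured IC50")
    if lead.name in set(names):
        raise ValueError(f"duplicate compound name: {lead.name!r}")
    if lead_descriptors is None:
        raise ValueError("lead_descriptors required when a lead is supplied")
    row = np.asarray(lead_descriptors, dtype=float)
    if row.shape != (table.n_features,):
        raise ValueError(
            f"lead descriptor vector has {row.shape} values, table expects {table.n_features}"
        )
    new = DescriptorTable(
        list(table.compound_ids) + [lead.id],
        list(table.feature_names),
        np.vstack([table.values, row]),
    )
    return new, np.append(np.asarray(targets, dtype=float), lead.ic50), list(names) + [lead.name]


def rank_candidates(
    predictions: Sequence[tuple[str, float]], top_k: int
) -> RankedCandidates:
    """Sort ascending by predicted IC50 (ties by name) and truncate to top_k."""
    if not predictions:
        raise ValueError("empty prediction list")
    if any(not np.isfinite(v) for _, v in predictions):
        raise ValueError("predictions must be finite")
    ordered = sorted(predictions, key=lambda e: (e[1], e[0]))
    return RankedCandidates(entries=[(n, float(v)) for n, v in ordered[:top_k]])


def compare_reducts(
    with_lead: ReductResult,
    without_lead: ReductResult,
    path: str | Path | None = None,
) -> dict[str, list[str]]:
    """Diff two reducts from the same feature universe.

    Returns shared / only-with-lead / only-without-lead lists; when ``path``
    is given, writes a comparison CSV whose two leading columns mirror the
    with/without-lead selected-descriptor layout.
    """
    if set(with_lead.universe) != set(without_lead.universe):
        raise ValueError("reducts come from different feature universes")
    a, b = set(with_lead.selected), set(without_lead.selected)
    diff = {
        "shared": sorted(a & b),
        "only_with_lead": sorted(a - b),
        "only_without_lead": sorted(b - a),
    }
    if path is not None:
        cols = {
            "selected_without_lead": list(without_lead.selected),
            "selected_with_lead": list(with_lead.selected),
            "shared": diff["shared"],
            "only_without_lead": diff["only_without_lead"],
            "only_with_lead": diff["only_with_lead"],
        }
        depth = max((len(v) for v in cols.values()), default=0)
        padded = {k: v + [""] * (depth - len(v)) for k, v in cols.items()}
        pd.DataFrame(padded).to_csv(path, index=False)
    return diff


@dataclass
class PipelineResult:
    reduct: ReductResult
    reduct_without_lead: ReductResult | None
    trained: TrainedRegressor
    metrics: dict[str, float]
    ranked: RankedCandidates
    explanations: list[explain.Explanation]
    manifest_path: Path
    manifest_hash: str


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the screening stages end to end; deterministic given the seed.

    Stage errors abort with the stage name.  Artifacts written to
    ``config.out_dir``: reduct JSON(s), reduct comparison CSV (when a lead
    is named), model checkpoint, metrics CSV, ranked-candidates CSV,
    explanation JSONs and ``manifest.json``.
    """
    stage = "configure"
    try:
        config.validate_paths()
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        artifacts: dict[str, Path] = {}

        stage = "load_reference"
        table, targets, names = chem_io.load_dataset(
            config.reference_csv, target_column=config.target_column,
            id_column=config.name_column,
        )
        if targets is None:
            raise ValueError("reference table must carry measured targets")
        logger.info("reference: %d compounds x %d descriptors", table.n_compounds,
                    table.n_features)

        stage = "lead_handling"
        lead_mask = np.ones(table.n_compounds, dtype=bool)
        if config.lead_name is not None:
            hits = [i for i, n in enumerate(names) if n == config.lead_name]
            if not hits:
                raise ValueError(f"lead compound {config.lead_name!r} not in reference")
            lead_mask[hits] = False

        def restricted(mask: np.ndarray) -> tuple[DescriptorTable, np.ndarray]:
            sub = DescriptorTable(
                [cid for cid, k in zip(table.compound_ids, mask) if k],
                list(table.feature_names),
                table.values[mask],
            )
            return sub, targets[mask]

        stage = "normalize"
        full_norm = chem_io.normalize_table(table)

        stage = "feature_selection"
        decision = fuzzy_rough.fuzzify_decision(
            targets, bins=config.bins, method=config.fuzzify_method
        )
        reduct_with = fuzzy_rough.quickreduct(full_norm, decision, config.tolerance)
        reduct_without = None
        if config.lead_name is not None:
            sub, sub_targets = restricted(lead_mask)
            sub_norm = chem_io.normalize_table(sub)
            sub_decision = fuzzy_rough.fuzzify_decision(
                sub_targets, bins=config.bins, method=config.fuzzify_method
            )
            reduct_without = fuzzy_rough.quickreduct(sub_norm, sub_decision, config.tolerance)
            reduct_with.to_json(out / "reduct_with_lead.json")
            reduct_without.to_json(out / "reduct_without_lead.json")
            artifacts["reduct_with_lead"] = out / "reduct_with_lead.json"
            artifacts["reduct_without_lead"] = out / "reduct_without_lead.json"
            compare_reducts(reduct_with, reduct_without, out / "reduct_comparison.csv")
            artifacts["reduct_comparison"] = out / "reduct_comparison.csv"
        else:
            reduct_with.to_json(out / "reduct.json")
            artifacts["reduct"] = out / "reduct.json"
        logger.info("selected %d/%d descriptors", len(reduct_with.selected),
                    table.n_features)

        stage = "assemble_training_set"
        if config.lead_name is not None and config.lead_handling == "exclude":
            train_table_raw, train_targets = restricted(lead_mask)
        else:
            train_table_raw, train_targets = table, targets
        selected = (
            list(reduct_with.selected) if config.select_features and reduct_with.selected
            else list(table.feature_names)
        )
        train_norm = chem_io.normalize_table(train_table_raw.subset(selected))

        stage = "train"
        reg_cfg = config.regressor
        if reg_cfg.seed != config.seed:
            reg_cfg = RegressorConfig(**{**asdict(reg_cfg), "seed": config.seed})
        n_feat = len(selected)
        if n_feat < cnn_model.minimum_features(reg_cfg.kernel_size, reg_cfg.pool_size):
            raise ValueError(
                f"{n_feat} selected descriptor(s) below the architecture minimum "
                f"{cnn_model.minimum_features(reg_cfg.kernel_size, reg_cfg.pool_size)}"
            )
        model = cnn_model.build_regressor(n_feat, reg_cfg)
        trained = cnn_model.train(model, train_norm, train_targets, reg_cfg)
        cnn_model.save_checkpoint(trained, out / "model_checkpoint.json")
        artifacts["model_checkpoint"] = out / "model_checkpoint.json"

        stage = "evaluate"
        metrics = cnn_model.evaluate(trained, train_norm, train_targets)
        cnn_model.metrics_report_to_csv({"run": metrics}, out / "metrics.csv")
        artifacts["metrics"] = out / "metrics.csv"

        stage = "load_candidates"
        cand_table, _, cand_names = chem_io.load_dataset(
            config.candidate_csv, target_column=None, id_column=config.name_column
        )
        cand_sel = cand_table.subset(selected)
        cand_norm = chem_io.apply_normalization(cand_sel, train_norm.norm_params)
        train_ids = set(train_norm.compound_ids)
        cand_ids = set(cand_norm.compound_ids)
        overlap = sorted(train_ids & cand_ids)
        if overlap:
            raise ValueError(f"candidate ids overlap the training set: {overlap[:5]}")

        stage = "predict_rank"
        preds = cnn_model.predict(trained, cand_norm)
        ranked = rank_candidates(list(zip(cand_names, preds)), config.top_k)
        ranked.seed = config.seed
        ranked.model_id = _sha256(artifacts["model_checkpoint"])[:16]
        reduct_key = "reduct_with_lead" if config.lead_name is not None else "reduct"
        ranked.reduct_id = _sha256(artifacts[reduct_key])[:16]
        ranked.to_csv(out / "ranked_candidates.csv")
        artifacts["ranked_candidates"] = out / "ranked_candidates.csv"

        stage = "explain"
        bins = explain.discretize_features(train_norm)

        def predict_matrix(x: np.ndarray) -> np.ndarray:
            t = DescriptorTable(
                [f"s{i}" for i in range(x.shape[0])], list(train_norm.feature_names), x
            )
            return trained.predict(t)

        explanations = []
        name_to_row = {n: i for i, n in enumerate(cand_names)}
        for rank_pos, (name, _pred) in enumerate(ranked.entries[: min(3, len(ranked.entries))]):
            inst = cand_norm.values[name_to_row[name]]
            e = explain.fit_local_surrogate(
                predict_matrix, inst, bins,
                n=config.explainer_samples, seed=config.seed + rank_pos,
                kernel_width=config.kernel_width, instance_id=name,
            )
            fname = out / f"explanation_{rank_pos:02d}.json"
            e.to_json(fname)
            artifacts[f"explanation_{rank_pos:02d}"] = fname
            explanations.append(e)

        stage = "manifest"
        manifest = {
            "config": _config_echo(config),
            "train_ids": sorted(train_ids),
            "candidate_ids": sorted(cand_ids),
            "selected_features": selected,
            "artifacts": {k: _sha256(p) for k, p in sorted(artifacts.items())},
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        manifest_hash = hashlib.sha256(manifest_path.read_bytes()).hexdigest()
    except PipelineStageError:
        raise
    except Exception as exc:
        logger.exception("pipeline failed at stage %r", stage)
        raise PipelineStageError(stage, exc) from exc
    return PipelineResult(
        reduct=reduct_with,
        reduct_without_lead=reduct_without,
        trained=trained,
        metrics=metrics,
        ranked=ranked,
        explanations=explanations,
        manifest_path=manifest_path,
        manifest_hash=manifest_hash,
    )


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name for CLI reporting."""

    def __init__(self, stage: str, cause: BaseException | None = None):
        super().__init__(f"pipeline stage {stage!r} failed" + (f": {cause}" if cause else ""))
        self.stage = stage


def _config_echo(config: RunConfig) -> dict:
    d = asdict(config)
    d["regressor"]["conv_filters"] = list(d["regressor"]["conv_filters"])
    return d
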