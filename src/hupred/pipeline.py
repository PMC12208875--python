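"""End-to-end pipeline: simulate -> select -> label -> train -> synergy -> report.

Each stage reads and writes plain-text artifacts under one output directory so
stages can be run independently (and are what the command-line interface
wraps):

    cohort/patients.csv, cohort/events.csv, cohort/truth.csv
    funnel.tsv            inclusion-funnel attrition counts
    features.csv          label + survival + pre-index features per patient
    ranking.tsv           cross-validated feature ranking (rank score)
    eval.json             composite / per-fold / validation ROC-AUC
    pairs.tsv             pair synergy table (thresholds, p-values, enrichment)
    associations.tsv      pair association table (sorted by combined p)
    summary.json          run summary (seeds, versions, funnel, AUC, top pairs)
    figures/*.svg         quadrant scatter and KM curves by risk class

Given identical configuration and seed the text outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .forest import ModelConfig, cross_validated_importance, evaluate_model, ranking_table
from .reporting import RiskRule, classify_quadrant, km_curve
from .selection import (
    FEATURE_COLUMNS,
    InclusionCriteria,
    apply_inclusion_funnel,
    derive_features,
    label_cohort,
    survival_from_labels,
)
from .simulate import GeneratorConfig, generate_cohort, read_cohort, write_cohort
from .synergy import GridRule, SurvivalData, quadrant_enrichment, rank_pairs

__all__ = [
    "SynergyConfig",
    "PipelineConfig",
    "PipelineConfigError",
    "load_pipeline_config",
    "run_pipeline",
    "stage_simulate",
    "stage_select",
    "stage_label",
    "stage_train",
    "stage_synergy",
    "stage_report",
]

logger = logging.getLogger("hupred")


class PipelineConfigError(ValueError):
    """Raised when a pipeline configuration is invalid or incomplete."""


@dataclass(frozen=True)
class SynergyConfig:
    """Synergy-stage settings: how many top features, grid granularity."""

    top_k: int = 10
    min_group_size: int = 10
    single_max_candidates: int | None = None
    pair_max_candidates: int = 20

    def grid_rules(self) -> tuple[GridRule, GridRule]:
        single = GridRule(
            min_group_size=self.min_group_size, max_candidates=self.single_max_candidates
        )
        pair = GridRule(
            min_group_size=self.min_group_size, max_candidates=self.pair_max_candidates
        )
        return single, pair


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end run.

    Exactly one cohort source must be set: ``simulate`` (a GeneratorConfig)
    or ``input_dir`` (a directory with patients.csv/events.csv).
    """

    outdir: Path
    simulate: GeneratorConfig | None = None
    input_dir: Path | None = None
    criteria: InclusionCriteria = field(default_factory=InclusionCriteria)
    model: ModelConfig = field(default_factory=ModelConfig)
    synergy: SynergyConfig = field(default_factory=SynergyConfig)
    risk_rule: RiskRule = field(default_factory=RiskRule)
    labeling_window: tuple[int, int] = (183, 274)
    labeling_tolerance_days: int = 14
    followup_days: int = 365
    seed: int = 0
    make_plots: bool = True

    def validate(self) -> None:
        if self.simulate is None and self.input_dir is None:
            raise PipelineConfigError(
                "cohort source missing: set 'simulate' or 'input_dir' in the config"
            )
        if self.simulate is not None:
            self.simulate.validate()
        self.criteria.validate()
        self.model.validate()
        self.risk_rule.validate()


def _build_dataclass(cls, data: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise PipelineConfigError(f"{context}: unknown field(s) {sorted(unknown)}")
    return cls(**data)


def load_pipeline_config(
    path: str | Path, seed: int | None = None, outdir: str | Path | None = None
) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PipelineConfigError(f"{path}: config must be a mapping")
    cfg_kwargs: dict = {}
    if "simulate" in raw and raw["simulate"] is not None:
        sim = dict(raw["simulate"])
        if "event_window_days" in sim:
            sim["event_window_days"] = tuple(sim["event_window_days"])
        cfg_kwargs["simulate"] = _build_dataclass(GeneratorConfig, sim, "simulate")
    if raw.get("input_dir"):
        cfg_kwargs["input_dir"] = Path(raw["input_dir"])
    for key, cls in (
        ("criteria", InclusionCriteria),
        ("model", ModelConfig),
        ("synergy", SynergyConfig),
        ("risk_rule", RiskRule),
    ):
        if key in raw and raw[key] is not None:
            cfg_kwargs[key] = _build_dataclass(cls, dict(raw[key]), key)
    for key in ("labeling_tolerance_days", "followup_days", "seed", "make_plots"):
        if key in raw:
            cfg_kwargs[key] = raw[key]
    if "labeling_window" in raw:
        cfg_kwargs["labeling_window"] = tuple(raw["labeling_window"])
    out = raw.get("outdir", "hupred_out")
    cfg = PipelineConfig(outdir=Path(out), **cfg_kwargs)
    if seed is not None:
        cfg.seed = seed
        if cfg.simulate is not None:
            cfg.simulate = replace(cfg.simulate, seed=seed)
        cfg.model = replace(cfg.model, seed=seed)
    if outdir is not None:
        cfg.outdir = Path(outdir)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: PipelineConfig) -> Path:
    """Generate (or copy in) the cohort CSVs under <outdir>/cohort."""
    cfg.validate()
    cohort_dir = cfg.outdir / "cohort"
    if cfg.simulate is not None:
        logger.info("simulate: generating %d patients (seed %d)", cfg.simulate.n_patients, cfg.simulate.seed)
        patients, events, truth = generate_cohort(cfg.simulate)
        write_cohort(cohort_dir, patients, events, truth)
    else:
        patients, events, truth = read_cohort(cfg.input_dir)
        write_cohort(cohort_dir, patients, events, truth)
    return cohort_dir


def stage_select(cfg: PipelineConfig) -> pd.DataFrame:
    """Apply the inclusion funnel; writes funnel.tsv, returns retained patients."""
    patients, events, _ = read_cohort(cfg.outdir / "cohort")
    retained, report = apply_inclusion_funnel(patients, events, cfg.criteria)
    report.to_frame().to_csv(cfg.outdir / "funnel.tsv", sep="\t", index=False)
    logger.info("select: %d -> %d patients", len(patients), len(retained))
    return retained


def stage_label(cfg: PipelineConfig) -> pd.DataFrame:
    """Label retained patients and derive features; writes features.csv."""
    patients, events, _ = read_cohort(cfg.outdir / "cohort")
    retained, _ = apply_inclusion_funnel(patients, events, cfg.criteria)
    labels = label_cohort(
        retained,
        events,
        window=cfg.labeling_window,
        tolerance_days=cfg.labeling_tolerance_days,
        followup_days=cfg.followup_days,
    )
    features = derive_features(retained, events, cfg.criteria.pre_index_history_days)
    table = labels.set_index("patient_id").join(features)
    table.to_csv(cfg.outdir / "features.csv")
    logger.info(
        "label: %d resistant / %d non-resistant", int(table["resistant"].sum()),
        int((~table["resistant"]).sum()),
    )
    return table


def _read_features(cfg: PipelineConfig) -> pd.DataFrame:
    path = cfg.outdir / "features.csv"
    if not path.exists():
        raise PipelineConfigError("features.csv not found; run the label stage first")
    return pd.read_csv(path, dtype={"patient_id": str}).set_index("patient_id")


def stage_train(cfg: PipelineConfig) -> pd.DataFrame:
    """Train/evaluate the forest; writes ranking.tsv and eval.json."""
    table = _read_features(cfg)
    x = table[list(FEATURE_COLUMNS)]
    y = table["resistant"].to_numpy(dtype=bool)
    from .forest import split_train_validate

    x_tr, _, y_tr, _ = split_train_validate(x, y, cfg.model)
    ranked = cross_validated_importance(x_tr, y_tr, cfg.model)
    ranking = ranking_table(ranked)
    ranking.to_csv(cfg.outdir / "ranking.tsv", sep="\t", index=False)
    result = evaluate_model(x, y, cfg.model)
    payload = {
        "composite_auc": result.composite_auc,
        "per_fold_auc": list(result.per_fold_auc),
        "validation_auc": result.validation_auc,
        "model": dataclasses.asdict(cfg.model),
    }
    with open(cfg.outdir / "eval.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    logger.info("train: composite AUC %.3f", result.composite_auc)
    return ranking


def stage_synergy(cfg: PipelineConfig) -> pd.DataFrame:
    """Pairwise synergy scan over the top-ranked features; writes pairs.tsv."""
    table = _read_features(cfg)
    ranking_path = cfg.outdir / "ranking.tsv"
    if not ranking_path.exists():
        raise PipelineConfigError("ranking.tsv not found; run the train stage first")
    ranking = pd.read_csv(ranking_path, sep="\t")
    top = list(ranking["variable"].head(cfg.synergy.top_k))
    survival = SurvivalData(
        time=table["event_day"].to_numpy(dtype=float),
        event=table["resistant"].to_numpy(dtype=bool),
    )
    single_rule, pair_rule = cfg.synergy.grid_rules()
    pairs, associations = rank_pairs(
        table, survival, feature_names=top, grid_rule=single_rule, pair_grid_rule=pair_rule
    )
    pairs.to_csv(cfg.outdir / "pairs.tsv", sep="\t", index=False)
    associations.to_csv(cfg.outdir / "associations.tsv", sep="\t", index=False)
    logger.info(
        "synergy: top pair %s-%s (S=%.1f)",
        pairs.loc[0, "var1"], pairs.loc[0, "var2"], pairs.loc[0, "synergy"],
    )
    return pairs


def stage_report(cfg: PipelineConfig) -> dict:
    """Assemble summary.json and figures from the stage artifacts."""
    table = _read_features(cfg)
    funnel = pd.read_csv(cfg.outdir / "funnel.tsv", sep="\t")
    with open(cfg.outdir / "eval.json") as fh:
        eval_payload = json.load(fh)
    pairs = pd.read_csv(cfg.outdir / "pairs.tsv", sep="\t")

    resistant = table["resistant"].to_numpy(dtype=bool)
    rdw = table["RDW"].to_numpy(dtype=float)
    hgb = table["HGB"].to_numpy(dtype=float)
    ok = ~(np.isnan(rdw) | np.isnan(hgb))
    enrich, counts = quadrant_enrichment(
        rdw[ok], hgb[ok], cfg.risk_rule.rdw_threshold, cfg.risk_rule.hgb_threshold, resistant[ok]
    )
    quadrants = {
        q: {
            "n": counts[q][0],
            "n_resistant": counts[q][1],
            "enrichment": None if np.isnan(enrich[q]) else enrich[q],
            "risk_class": classify_quadrant(
                cfg.risk_rule.rdw_threshold + (0.1 if q in ("Q1", "Q2") else -0.1),
                cfg.risk_rule.hgb_threshold + (0.1 if q in ("Q2", "Q4") else -0.1),
                cfg.risk_rule,
            )[1],
        }
        for q in ("Q1", "Q2", "Q3", "Q4")
    }
    summary = {
        "package_version": __version__,
        "seed": cfg.seed,
        "funnel": funnel.to_dict(orient="records"),
        "n_patients": int(len(table)),
        "n_resistant": int(resistant.sum()),
        "n_non_resistant": int((~resistant).sum()),
        "composite_auc": eval_payload["composite_auc"],
        "validation_auc": eval_payload["validation_auc"],
        "top_pairs": pairs.head(3)[
            ["var1", "var2", "synergy", "t1", "t2", "p12", "quadrant"]
        ].to_dict(orient="records"),
        "risk_rule": {
            "rdw_threshold": cfg.risk_rule.rdw_threshold,
            "hgb_threshold": cfg.risk_rule.hgb_threshold,
            "quadrants": quadrants,
        },
    }
    with open(cfg.outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    if cfg.make_plots:
        _make_figures(cfg, table)
    return summary


def _make_figures(cfg: PipelineConfig, table: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "hupred"
    figdir = cfg.outdir / "figures"
    figdir.mkdir(exist_ok=True)
    resistant = table["resistant"].to_numpy(dtype=bool)
    rdw = table["RDW"].to_numpy(dtype=float)
    hgb = table["HGB"].to_numpy(dtype=float)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(hgb[~resistant], rdw[~resistant], s=8, alpha=0.5, label="non-resistant")
    ax.scatter(hgb[resistant], rdw[resistant], s=8, alpha=0.5, label="resistant")
    ax.axhline(cfg.risk_rule.rdw_threshold, color="k", lw=1)
    ax.axvline(cfg.risk_rule.hgb_threshold, color="k", lw=1)
    ax.set_xlabel("HGB (g/dL)")
    ax.set_ylabel("RDW (%)")
    ax.legend(frameon=False)
    fig.savefig(figdir / "rdw_hgb_scatter.svg", metadata={"Date": None})
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, mask in (
        ("high RDW / low HGB (Q1)", (rdw >= cfg.risk_rule.rdw_threshold) & (hgb < cfg.risk_rule.hgb_threshold)),
        ("low RDW / low HGB (Q3)", (rdw < cfg.risk_rule.rdw_threshold) & (hgb < cfg.risk_rule.hgb_threshold)),
        ("other", (hgb >= cfg.risk_rule.hgb_threshold)),
    ):
        mask = mask & ~np.isnan(rdw) & ~np.isnan(hgb)
        if mask.sum() == 0:
            continue
        curve = km_curve(
            SurvivalData(
                time=table["event_day"].to_numpy(dtype=float)[mask], event=resistant[mask]
            )
        )
        ax.step(curve.times, curve.survival, where="post", label=f"{label} (n={int(mask.sum())})")
    ax.set_xlabel("days since index")
    ax.set_ylabel("resistance-free probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    fig.savefig(figdir / "km_risk_groups.svg", metadata={"Date": None})
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order; returns the summary dict.

    Any stage failure is re-raised as ``RuntimeError`` naming the stage.
    """
    cfg.validate()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    stages = (
        ("simulate", stage_simulate),
        ("select", stage_select),
        ("label", stage_label),
        ("train", stage_train),
        ("synergy", stage_synergy),
        ("report", stage_report),
    )
    result = None
    for name, fn in stages:
        try:
            result = fn(cfg)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return result
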