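"""End-to-end study runner.

Reproduces the full design — {unfiltered, distance-filtered,
riverscape-filtered} presence datasets x {default beta=1,
AICc-selected beta} = six final models — from a single seeded config:
data generation (or loading), covariate screening, both bias filters,
per-dataset complexity selection over the beta grid, cross-validated
evaluation of the final models, contribution/importance tables,
pairwise niche-similarity matrices, per-model MTP binary maps and the
0..6 ensemble agreement map.  Every artifact is written as delimited
text and listed with its SHA-256 hash in a run manifest, so a rerun
under the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, evaluation, filters, maxent, selection, swd_io, synthetic
from .synthetic import RiverscapeParams, stage_seed

__all__ = ["RunConfig", "StudyResult", "run_study"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything a study run needs; seed is mandatory."""

    seed: int
    outdir: str = "study_out"
    # input data: either paths ...
    segments_path: str | None = None
    presences_path: str | None = None
    # ... or synthetic-riverscape parameters (dict of RiverscapeParams overrides)
    synthetic: dict = field(default_factory=dict)
    covariates: list[str] | None = None     # None = auto-select by screen
    correlation_threshold: float = 0.70
    distance_min_km: float = 20.0
    distance_reps: int = 100
    beta_lo: float = 1.0
    beta_hi: float = 5.0
    beta_step: float = 0.5
    folds: int = 5
    n_knots: int = 50
    tol: float = 1e-5
    latlon: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class StudyResult:
    config: RunConfig
    segments: swd_io.SegmentTable
    datasets: dict
    selections: dict
    final_models: dict          # label -> MaxentModel
    evaluations: pd.DataFrame   # Table-3 analogue
    importance: pd.DataFrame    # Table-2 analogue
    similarity: comparison.SimilarityMatrix
    ensemble_map: comparison.EnsembleMap
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_or_generate(cfg: RunConfig):
    if cfg.segments_path is not None:
        seg = swd_io.read_segments(cfg.segments_path, latlon=cfg.latlon)
        pres = swd_io.read_presences(cfg.presences_path, segments=seg)
        return seg, pres
    params = RiverscapeParams(**{"seed": stage_seed(cfg.seed, "riverscape"),
                                 **cfg.synthetic})
    seg, pres, _ = synthetic.generate_riverscape(params)
    return seg, pres


def run_study(cfg: RunConfig) -> StudyResult:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, index=False) -> None:
        p = out / name
        df.to_csv(p, index=index, float_format=FLOAT_FMT)
        artifacts.append(p)

    segments, presences = _load_or_generate(cfg)
    save_df(segments.data, "segments.csv")
    presences = swd_io.dedupe_presences(presences, segments)
    logger.info("presences after segment-level dedup: %d", len(presences))

    report = swd_io.correlation_screen(segments, cfg.correlation_threshold)
    save_df(report.matrix, "correlation_matrix.csv", index=True)
    if cfg.covariates is None:
        chosen = swd_io.auto_select_covariates(report)
        logger.info("auto-selected covariates: %s", chosen)
    else:
        chosen = list(cfg.covariates)
        check = swd_io.validate_subset(report, chosen)
        if not check.passed:
            logger.warning("chosen covariates violate |r| <= %.2f: %s",
                           cfg.correlation_threshold, check.offending)

    # --- three presence datasets -----------------------------------------
    datasets = {"unfiltered": presences}
    dres = filters.distance_filter(presences, cfg.distance_min_km,
                                   cfg.distance_reps,
                                   seed=stage_seed(cfg.seed, "distance"),
                                   latlon=cfg.latlon)
    datasets["distance"] = dres.retained
    rres = filters.riverscape_filter(presences, seed=stage_seed(cfg.seed, "riverscape_filter"))
    datasets["riverscape"] = rres.retained
    for name, d in datasets.items():
        logger.info("dataset %-10s: %d records", name, len(d))
        p = out / f"presences_{name}.csv"
        swd_io.write_presences(d, p)
        artifacts.append(p)

    grid = selection.beta_grid(cfg.beta_lo, cfg.beta_hi, cfg.beta_step)
    selections, final_models = {}, {}
    eval_rows = []
    imp_rows = []
    for name, d in datasets.items():
        sel = selection.select_model(
            segments, d, grid=grid, covariates=chosen, n_knots=cfg.n_knots,
            tol=cfg.tol, folds=cfg.folds, seed=stage_seed(cfg.seed, f"cv:{name}"))
        selections[name] = sel
        save_df(sel.table, f"selection_{name}.csv")
        for kind, b in (("default", float(grid[0])), ("aicc", sel.chosen_beta)):
            label = f"{name}/{kind}"
            model = sel.models[b]
            final_models[label] = model
            mp = out / f"model_{name}_{kind}.json"
            maxent.save_model(model, mp)
            artifacts.append(mp)
            row = sel.table.loc[sel.table["beta"] == b].iloc[0]
            eval_rows.append({
                "dataset": name, "model": kind, "beta": b,
                "n": len(d), "auc_test": row["auc_test"], "or_mtp": row["or_mtp"],
                "k": int(row["k"]), "logL": row["logL"],
                "aicc": row["aicc"] if row["aicc_defined"] else np.nan,
                "aicc_defined": bool(row["aicc_defined"]),
            })
            pc = maxent.percent_contribution(model)
            pi = maxent.permutation_importance(
                model, d.segment_ids, segments,
                seed=stage_seed(cfg.seed, f"perm:{label}"))
            for cov in pc.index:
                imp_rows.append({"model": label, "covariate": cov,
                                 "percent_contribution": pc[cov],
                                 "permutation_importance": pi[cov]})

    evaluations = pd.DataFrame(eval_rows)
    save_df(evaluations, "evaluation_table.csv")
    importance = pd.DataFrame(imp_rows)
    save_df(importance, "importance_table.csv")

    # --- comparison -------------------------------------------------------
    preds = {label: maxent.predict(m, segments) for label, m in final_models.items()}
    sim = comparison.pairwise_similarity(preds)
    save_df(sim.d, "schoeners_d.csv", index=True)
    save_df(sim.i, "warrens_i.csv", index=True)

    maps = []
    pos = {sid: i for i, sid in enumerate(segments.data["segment_id"])}
    for label, model in final_models.items():
        d = datasets[label.split("/")[0]]
        pred = preds[label]
        idx = [pos[s] for s in d.segment_ids]
        mtp = evaluation.mtp_threshold(pred.cloglog[idx])
        maps.append(comparison.binary_map(pred, mtp, label))
    binmap_df = pd.DataFrame({"segment_id": segments.data["segment_id"]})
    for m in maps:
        binmap_df[m.label] = m.suitable.astype(int)
    save_df(binmap_df, "binary_maps.csv")
    ens = comparison.ensemble(maps)
    save_df(pd.DataFrame({"segment_id": ens.segment_ids, "count": ens.counts}),
            "ensemble_map.csv")

    manifest = {
        "config": asdict(cfg),
        "n_segments": len(segments),
        "covariates_used": chosen,
        "dataset_sizes": {k: len(v) for k, v in datasets.items()},
        "chosen_beta": {k: v.chosen_beta for k, v in selections.items()},
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    return StudyResult(cfg, segments, datasets, selections, final_models,
                       evaluations, importance, sim, ens, manifest)
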