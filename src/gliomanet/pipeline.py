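"""End-to-end orchestration: simulate -> connectome -> topology -> select -> classify.

A single :class:`PipelineConfig` (loadable from YAML) carries every
hyperparameter of the analysis — cohort spec when simulating, cleaning
band, sparsity grid, selection CI / top-percent / repetitions, outer CV
folds, ridge — plus one master seed from which each stage derives its own
seed as a stable hash of (master seed, stage name), so stages rerun in
isolation reproduce their in-pipeline behavior.  Artifacts are plain text
(TSV time series and matrices, CSV feature tables, JSON reports) and every
run emits a RunRecord with config snapshot, stage wall times and SHA-256
digests of the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import CVEvaluation, cross_hemisphere_validate, outer_cv_evaluate
from .connectome import (
    CleaningConfig,
    cohort_fc_matrices,
    edge_feature_ids,
    write_edge_feature_csv,
)
from .feature_selection import (
    FeatureTable,
    SelectionConfig,
    build_feature_table,
    demographic_screen,
    pick_predictive,
    repeated_selection,
    write_ranked_tsv,
    write_selection_report,
)
from .network_topology import (
    TopologyConfig,
    compute_topology_profile,
    topology_feature_table,
)
from .synth_cohort import CohortSpec, generate_cohort, read_cohort_manifest, write_cohort

STAGES = ("simulate", "connectome", "topology", "select", "classify")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (master seed, stage name), < 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortSpec | None = None
    manifest: str | None = None
    feature_sets: tuple[str, ...] = ("fc",)
    cleaning: CleaningConfig = CleaningConfig()
    topology: TopologyConfig = TopologyConfig()
    selection: SelectionConfig = SelectionConfig()
    cv_folds: int = 10
    ridge: float = 1e-4
    smote_k: int = 5
    include_age: bool = True
    write_matrices: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort is None and self.manifest is None:
            raise ValueError("config needs either a cohort spec (simulate) or a manifest path")
        bad = set(self.feature_sets) - {"fc", "tf"}
        if bad:
            raise ValueError(f"unknown feature sets: {sorted(bad)}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.ridge <= 0:
            raise ValueError("ridge must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("cohort"):
            c = dict(d["cohort"])
            for key in ("age_lgg", "age_hgg"):
                if key in c and c[key] is not None:
                    c[key] = tuple(c[key])
            if c.get("planted_edges"):
                c["planted_edges"] = tuple(tuple(e) for e in c["planted_edges"])
            if c.get("planted_signs"):
                c["planted_signs"] = tuple(c["planted_signs"])
            d["cohort"] = CohortSpec(**c)
        if d.get("cleaning"):
            cl = dict(d["cleaning"])
            if cl.get("band"):
                cl["band"] = tuple(cl["band"])
            d["cleaning"] = CleaningConfig(**cl)
        if d.get("topology"):
            t = dict(d["topology"])
            if t.get("sparsities"):
                t["sparsities"] = tuple(t["sparsities"])
            d["topology"] = TopologyConfig(**t)
        if d.get("selection"):
            d["selection"] = SelectionConfig(**d["selection"])
        if d.get("feature_sets"):
            d["feature_sets"] = tuple(d["feature_sets"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunRecord:
    config: dict
    version: str
    stage_seconds: dict[str, float]
    output_digests: dict[str, str]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_subjects(config: PipelineConfig, out: Path):
    if config.manifest is not None:
        return read_cohort_manifest(config.manifest)
    manifest = out / "cohort" / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(
            f"no simulated cohort at {manifest}; run the simulate stage first"
        )
    return read_cohort_manifest(manifest)


def _tables_from_csv(path: Path, subjects) -> FeatureTable:
    df = pd.read_csv(path, index_col="subject_id")
    by_id = {s.id: s for s in subjects}
    labels = {s.id: s.label for s in subjects}
    ages = {s.id: s.age for s in subjects}
    sexes = {s.id: 1 if s.sex == "M" else 0 for s in subjects}
    df = df.loc[[s.id for s in subjects if s.id in by_id]]
    return build_feature_table(df, labels, ages, sexes)


def fc_feature_table(
    subjects,
    tr: float = 2.0,
    cleaning: CleaningConfig = CleaningConfig(),
) -> FeatureTable:
    """Clean, correlate and vectorize a subject list into an FC FeatureTable."""
    from .connectome import vectorize_edges

    fcs = cohort_fc_matrices(subjects, tr=tr, config=cleaning)
    X = np.vstack([vectorize_edges(fc).values for fc in fcs])
    return FeatureTable(
        X=X,
        feature_ids=edge_feature_ids(fcs[0].n_nodes),
        labels=np.array([s.label for s in subjects]),
        subject_ids=[s.id for s in subjects],
        age=np.array([s.age for s in subjects]),
        sex=np.array([1 if s.sex == "M" else 0 for s in subjects]),
    )


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> RunRecord:
    """Execute the requested stages, writing all artifacts under ``out_dir``."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    times: dict[str, float] = {}
    outputs: list[Path] = []
    subjects = None
    tr = config.cohort.tr_seconds if config.cohort is not None else 2.0

    if "simulate" in stages and config.cohort is not None:
        t0 = time.perf_counter()
        spec = dataclasses.replace(config.cohort, seed=stage_seed(config.master_seed, "simulate"))
        cohort = generate_cohort(spec)
        write_cohort(cohort, out / "cohort")
        subjects = cohort.subjects
        times["simulate"] = time.perf_counter() - t0
        outputs.append(out / "cohort" / "manifest.csv")
        outputs.append(out / "cohort" / "ground_truth.json")

    if subjects is None and set(stages) & {"connectome", "topology", "select", "classify"}:
        subjects = _load_subjects(config, out)

    fcs = None
    if "connectome" in stages:
        t0 = time.perf_counter()
        fcs = cohort_fc_matrices(subjects, tr=tr, config=config.cleaning)
        fc_path = out / "fc_features.csv"
        write_edge_feature_csv(fcs, fc_path)
        if config.write_matrices:
            from .connectome import write_fc_matrix

            mat_dir = out / "fc_matrices"
            mat_dir.mkdir(exist_ok=True)
            for fc in fcs:
                write_fc_matrix(fc, mat_dir / f"{fc.subject_id}.tsv")
        times["connectome"] = time.perf_counter() - t0
        outputs.append(fc_path)

    if "topology" in stages and "tf" in config.feature_sets:
        t0 = time.perf_counter()
        if fcs is None:
            fcs = cohort_fc_matrices(subjects, tr=tr, config=config.cleaning)
        tcfg = dataclasses.replace(config.topology, seed=stage_seed(config.master_seed, "topology"))
        profiles = [compute_topology_profile(fc, tcfg) for fc in fcs]
        tf_path = out / "tf_features.csv"
        topology_feature_table(profiles).to_csv(tf_path)
        times["topology"] = time.perf_counter() - t0
        outputs.append(tf_path)

    tables: dict[str, FeatureTable] = {}
    for fs in config.feature_sets:
        path = out / ("fc_features.csv" if fs == "fc" else "tf_features.csv")
        if path.exists() and set(stages) & {"select", "classify"}:
            tables[fs] = _tables_from_csv(path, subjects)

    if "select" in stages:
        t0 = time.perf_counter()
        sel_seed = stage_seed(config.master_seed, "select")
        for fs, table in tables.items():
            cfg = dataclasses.replace(config.selection, seed=sel_seed)
            freq = repeated_selection(table, cfg)
            predictive = pick_predictive(freq, cfg.top_pct)
            report = out / f"selection_{fs}.json"
            write_selection_report(report, cfg, freq, predictive, demographic_screen(table))
            ranked = out / f"selection_{fs}_ranked.tsv"
            write_ranked_tsv(ranked, freq)
            outputs.extend([report, ranked])
        times["select"] = time.perf_counter() - t0

    if "classify" in stages:
        t0 = time.perf_counter()
        cls_seed = stage_seed(config.master_seed, "classify")
        for fs, table in tables.items():
            cfg = dataclasses.replace(config.selection, seed=cls_seed)
            ev = outer_cv_evaluate(
                table,
                cfg,
                cv_folds=config.cv_folds,
                seed=cls_seed,
                ridge=config.ridge,
                smote_k=config.smote_k,
                include_age=config.include_age,
            )
            payload = {
                ctx.context: dict(
                    aucs=ctx.aucs.tolist(), mean=ctx.mean, sd=ctx.sd
                )
                for ctx in (ev.train, ev.validation)
            }
            payload["selected_features"] = ev.selected_features
            eval_path = out / f"evaluation_{fs}.json"
            with open(eval_path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
            roc_rows = []
            for fold, roc in enumerate(ev.validation.roc_points):
                for fpr, tpr in roc:
                    roc_rows.append(dict(fold=fold, fpr=fpr, tpr=tpr))
            roc_path = out / f"roc_validation_{fs}.csv"
            pd.DataFrame(roc_rows).to_csv(roc_path, index=False)
            outputs.extend([eval_path, roc_path])
        times["classify"] = time.perf_counter() - t0

    record = RunRecord(
        config=config.to_dict(),
        version=__version__,
        stage_seconds=times,
        output_digests={str(p.relative_to(out)): _sha256(p) for p in outputs if p.exists()},
    )
    record.write(out / "run_record.json")
    return record


def sweep_hyperparams(
    table: FeatureTable,
    base_cfg: SelectionConfig,
    ci_levels: list[float],
    top_pcts: list[float],
    cv_folds: int = 10,
    seed: int = 0,
    ridge: float = 1e-4,
) -> pd.DataFrame:
    """Grid of (ci_level, top_pct): mean +/- sd validation AUC per cell."""
    if not ci_levels or not top_pcts:
        raise ValueError("both grids must be non-empty")
    rows = []
    for ci in ci_levels:
        for top in top_pcts:
            cfg = dataclasses.replace(base_cfg, ci_level=ci, top_pct=top)
            ev = outer_cv_evaluate(table, cfg, cv_folds=cv_folds, seed=seed, ridge=ridge)
            rows.append(
                dict(
                    ci_level=ci,
                    top_pct=top,
                    validation_auc_mean=ev.validation.mean,
                    validation_auc_sd=ev.validation.sd,
                    train_auc_mean=ev.train.mean,
                )
            )
    df = pd.DataFrame(rows)
    df["best"] = df["validation_auc_mean"] == df["validation_auc_mean"].max()
    return df
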