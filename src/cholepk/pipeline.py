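"""End-to-end pipeline binding curation, LLMs, QIVIVE and evaluation.

Stage order follows the metamodel workflow: curate -> train the
per-transporter LLMs -> predict the activity matrix (with experimental
overrides) -> QIVIVE reverse dosimetry -> fit the decision rule ->
evaluate under the requested CV regimes. Every artifact directory gets a
resolved-config snapshot with a digest and the global seed, and a rerun
with the same config reproduces deterministic outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import curation, evaluation, metamodel, qivive, qsar, synthetic
from .utils import derive_seed

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    ``bundle_dir`` points at a CSV bundle (as written by
    :func:`cholepk.synthetic.export`); alternatively ``synthetic`` holds
    an inline generator configuration. Unknown keys in a config file are
    rejected.
    """

    bundle_dir: str | None = None
    synthetic: dict | None = None
    out_dir: str = "cholepk_run"
    seed: int = 0
    physiology: dict = field(default_factory=dict)
    llm_families: tuple = ("XGB", "RF", "KNN", "SVM")
    llm_grids: dict | None = None
    qsar_families: tuple = ("XGB", "RF", "NB", "SVM")
    cv_schemes: tuple = ("repeated_random", "similarity_cluster", "atc_group")
    cv_repeats: int = 20
    cv_k: int = 5
    metamodel_mode: str = "or"          # "or" | "highest"
    metamodel_objective: str = "balanced_accuracy"
    score_mode: str = "margin"          # "margin" | "binary"
    dose_filter_threshold: float = 10000.0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("llm_families", "qsar_families", "cv_schemes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_provenance(out: Path, config: PipelineConfig, stage: str) -> None:
    prov = {"config_digest": config.digest(), "seed": config.seed,
            "stage": stage}
    with open(out / f"{stage}.provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns a dict of key artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config) | {"digest": config.digest()},
                  fh, indent=2, default=str)

    # -- stage: load ---------------------------------------------------
    if config.bundle_dir is not None:
        bundle = Path(config.bundle_dir)
        required = ["compounds.csv", "fingerprints.csv", "activities.csv",
                    "tk.csv"]
        missing = [f for f in required if not (bundle / f).exists()]
        if missing:
            raise PipelineError("load", f"missing input files: {missing}")
        dataset = synthetic.load_bundle(bundle)
    elif config.synthetic is not None:
        syn_cfg = dict(config.synthetic)
        syn_cfg.setdefault("seed", config.seed)
        if "physiology" in syn_cfg and isinstance(syn_cfg["physiology"], dict):
            syn_cfg["physiology"] = qivive.PhysiologyConfig(
                **syn_cfg["physiology"])
        dataset = synthetic.generate(synthetic.SyntheticConfig(**syn_cfg))
    else:
        raise PipelineError("load", "either bundle_dir or synthetic required")

    # -- stage: curate (route filter; structures are pre-standardized) --
    report = curation.FilterReport()
    keep = [i for i, r in enumerate(dataset.routes)
            if r in ("oral", "intravenous")]
    report.add_stage("route", len(dataset.routes) - len(keep))
    ids = [dataset.compound_ids[i] for i in keep]

    # -- stage: train-llm ----------------------------------------------
    try:
        fp_lookup = dataset.fingerprint_lookup()
        training, exp_lookup = curation.aggregate_duplicate_activities(
            dataset.activity)
        models = qsar.train_transporter_models(
            training, fp_lookup, families=config.llm_families,
            grids=config.llm_grids, seed=derive_seed(config.seed, "llm"))
    except Exception as exc:
        raise PipelineError("train-llm", str(exc)) from exc

    # -- stage: predict-matrix -------------------------------------------
    activity = qsar.build_activity_matrix(ids, fp_lookup, models, exp_lookup)
    activity.to_frame().rename_axis("compound_id") \
        .to_csv(out / "activity_matrix.csv")

    # -- stage: qivive ----------------------------------------------------
    phys = qivive.PhysiologyConfig(
        **({"seed": derive_seed(config.seed, "qivive")} | config.physiology))
    with_tk, no_tk = qivive.filter_missing_tk(activity.compound_ids,
                                              dataset.tk)
    report.add_stage("missing_tk", len(no_tk))
    mask = [cid in set(with_tk) for cid in activity.compound_ids]
    dose = qivive.build_dose_matrix(
        activity.values[mask], with_tk, activity.transporters,
        dataset.tk, phys)
    dose, removed = qivive.filter_implausible_doses(
        dose, config.dose_filter_threshold)
    report.add_stage("implausible_dose", len(removed))
    dose.write_csv(out / "dose_matrix.csv", out / "dose_matrix.meta.json")
    with open(out / "filter_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    # -- stage: metamodel -------------------------------------------------
    idx = {cid: i for i, cid in enumerate(dataset.compound_ids)}
    rows = [idx[cid] for cid in dose.compound_ids]
    td = dataset.td[rows]
    y = dataset.labels[rows]
    X_pk = metamodel.dose_rule_features(dose, td)
    pk = metamodel.PkRuleMetamodel(
        mode=config.metamodel_mode,
        objective=config.metamodel_objective).fit(X_pk, y)
    (out / "metamodel_pk.json").write_text(pk.to_json())
    act_rows = np.array([activity.compound_ids.index(c)
                         for c in dose.compound_ids])
    X_nopk = metamodel.activity_to_ic50_um(activity.values[act_rows])
    nopk = metamodel.NoPkRuleMetamodel().fit()
    (out / "metamodel_not_pk.json").write_text(nopk.to_json())

    # -- stage: evaluate --------------------------------------------------
    fps = np.vstack([fp_lookup[c] for c in dose.compound_ids])
    atc = [dataset.atc_codes[idx[c]] for c in dose.compound_ids]
    schemes = {}
    for kind in config.cv_schemes:
        if kind == "repeated_random":
            schemes[kind] = evaluation.repeated_kfold_scheme(
                len(y), k=config.cv_k, repeats=config.cv_repeats,
                seed=derive_seed(config.seed, "cv", kind))
        elif kind == "similarity_cluster":
            schemes[kind] = evaluation.similarity_cluster_scheme(fps)
        elif kind == "atc_group":
            schemes[kind] = evaluation.atc_group_scheme(atc)
        else:
            raise PipelineError("evaluate", f"unknown CV scheme {kind!r}")
    reports = {}
    tidy = []
    for kind, scheme in schemes.items():
        rep = evaluation.run_cv(
            lambda: metamodel.PkRuleMetamodel(
                mode=config.metamodel_mode,
                objective=config.metamodel_objective),
            scheme, X_pk, y, score_mode=config.score_mode)
        reports[kind] = rep
        for f, row in rep.per_fold.iterrows():
            for m in evaluation.METRIC_NAMES:
                tidy.append({"model": "metamodel_pk", "scheme": kind,
                             "fold": f, "metric": m, "value": row[m]})
    pd.DataFrame(tidy).to_csv(out / "metrics.csv", index=False)
    summary = {kind: rep.summary["mean"].to_dict()
               for kind, rep in reports.items()}
    with open(out / "metrics_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _write_provenance(out, config, "run")

    return {
        "dataset": dataset,
        "filter_report": report,
        "models": models,
        "activity_matrix": activity,
        "dose_matrix": dose,
        "metamodel_pk": pk,
        "metamodel_not_pk": nopk,
        "X_pk": X_pk,
        "X_nopk": X_nopk,
        "labels": y,
        "reports": reports,
        "out_dir": out,
    }
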