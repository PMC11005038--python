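"""Seeded synthetic datasets with the structure the pipeline assumes.

The generator emulates, at desk scale, the kind of data the cholestasis
metamodel consumes:

* **chemical series** — binary fingerprints drawn from per-cluster bit
  templates with bit-flip noise, so hierarchical clustering under
  Jaccard distance can recover the series;
* **transporter bioactivity** — per-transporter pIC50 that is a linear
  function of a designated set of *activity bits* plus Gaussian assay
  noise, measured for a random subset of (compound, transporter) pairs
  with occasional replicates. The activity bits are sampled
  independently of cluster membership, so the structure-activity signal
  generalizes across clusters while cluster identity does not;
* **toxicokinetics** — lognormal unbound fractions and intrinsic
  clearances, lognormal molecular weights;
* **therapeutic doses and labels** — doses are placed around
  ``true_n_factor`` times each compound's minimum ground-truth IEOD50
  with a controlled log-margin, so that labels equal the PK decision
  rule exactly (before optional label noise) and the positive prevalence
  is an exact Bernoulli draw at the configured rate.

``label_mode="structure"`` instead ties labels to cluster membership,
which is the regime where a direct QSAR model shines under random CV and
collapses under similarity-cluster CV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .qivive import (DoseMatrix, PhysiologyConfig, TKParameters, compute_css,
                     ic50_from_pic50)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "PrevalenceWarning",
    "TRANSPORTER_PANEL",
    "generate",
    "export",
    "load_bundle",
]

#: Hepatic transporter panel the activity columns mimic.
TRANSPORTER_PANEL = ("BSEP", "P-gp", "BCRP", "MRP2", "MRP3", "MRP4",
                     "OATP1B1", "OATP1B3")

ATC_POOL = ("J01", "N05", "L01", "C01", "N02")


class PrevalenceWarning(UserWarning):
    """Achieved label prevalence deviates from the configured target."""


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults describe the study conditions.

    420 compounds in 5 fingerprint-clusterable series mirror the scale of
    a curated cholestasis dataset; 8 transporters mirror the hepatic
    panel; assay noise of 0.3 pIC50 units and a ~27% positive prevalence
    are typical of curated bioactivity/label collections.
    """

    n_compounds: int = 420
    n_clusters: int = 5
    n_bits: int = 2048
    template_bits: int = 60
    bit_noise: float = 0.02
    n_activity_bits: int = 32
    activity_bit_rate: float = 0.5
    n_transporters: int = 8
    activity_weight_sd: float = 0.4
    activity_bits_per_transporter: int = 8
    activity_intercept_mean: float = 5.0
    activity_intercept_sd: float = 0.5
    noise_sd: float = 0.3
    measured_rate: float = 0.4
    replicate_rate: float = 0.3
    fub_median: float = 0.1
    fub_sigma: float = 1.0
    clint_median: float = 10.0
    clint_sigma: float = 1.0
    molwt_median: float = 350.0
    molwt_sigma: float = 0.3
    td_log_sd: float = 1.0
    td_log_margin: float = 0.1
    prevalence: float = 0.27
    true_n_factor: float = 3.0
    label_noise: float = 0.0
    label_mode: str = "pk_rule"     # "pk_rule" | "structure"
    positive_clusters: tuple = (0, 1)
    frac_intravenous: float = 0.1
    frac_other_route: float = 0.0
    atc_cluster_assoc: float = 0.7
    physiology: PhysiologyConfig = field(default_factory=PhysiologyConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bit_noise", "activity_bit_rate", "measured_rate",
                     "replicate_rate", "prevalence", "label_noise",
                     "frac_intravenous", "frac_other_route",
                     "atc_cluster_assoc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.true_n_factor <= 0:
            raise ValueError("true_n_factor must be > 0")
        if self.label_mode not in ("pk_rule", "structure"):
            raise ValueError("label_mode must be 'pk_rule' or 'structure'")


@dataclass
class SyntheticDataset:
    """Generated compounds, features, activities, TK, doses and labels."""

    config: SyntheticConfig
    compound_ids: list[str]
    fingerprints: np.ndarray          # (n, n_bits) uint8
    clusters: np.ndarray              # (n,)
    routes: list[str]
    atc_codes: list[list[str]]
    molwt: np.ndarray
    tk: dict[str, TKParameters]
    transporters: list[str]
    true_pic50: np.ndarray            # (n, T) noise-free ground truth
    activity: pd.DataFrame            # measured replicate rows
    true_dose_matrix: DoseMatrix
    td: np.ndarray                    # mg/kg/day
    labels: np.ndarray                # 1 = cholestatic

    def fingerprint_lookup(self) -> dict[str, np.ndarray]:
        return {cid: self.fingerprints[i]
                for i, cid in enumerate(self.compound_ids)}

    def td_lookup(self) -> dict[str, float]:
        return {cid: float(t) for cid, t in zip(self.compound_ids, self.td)}


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; bit-identical for a fixed config (incl. seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, t = cfg.n_compounds, cfg.n_transporters
    ids = [f"SYN{i:05d}" for i in range(n)]
    transporters = [TRANSPORTER_PANEL[i % len(TRANSPORTER_PANEL)]
                    + ("" if i < len(TRANSPORTER_PANEL) else f"_{i}")
                    for i in range(t)]

    # --- bit layout: disjoint cluster templates + shared activity bits
    perm = rng.permutation(cfg.n_bits)
    templates = [perm[c * cfg.template_bits:(c + 1) * cfg.template_bits]
                 for c in range(cfg.n_clusters)]
    a0 = cfg.n_clusters * cfg.template_bits
    activity_bits = perm[a0:a0 + cfg.n_activity_bits]

    clusters = rng.integers(0, cfg.n_clusters, size=n)
    fp = (rng.random((n, cfg.n_bits)) < cfg.bit_noise).astype(np.uint8)
    for i in range(n):
        keep = rng.random(cfg.template_bits) > cfg.bit_noise
        fp[i, templates[clusters[i]][keep]] = 1
    act = (rng.random((n, cfg.n_activity_bits))
           < cfg.activity_bit_rate).astype(np.uint8)
    fp[:, activity_bits] = act

    # --- transporter structure-activity model on the activity bits
    intercepts = rng.normal(cfg.activity_intercept_mean,
                            cfg.activity_intercept_sd, size=t)
    weights = np.zeros((t, cfg.n_activity_bits))
    for j in range(t):
        sel = rng.choice(cfg.n_activity_bits,
                         size=min(cfg.activity_bits_per_transporter,
                                  cfg.n_activity_bits), replace=False)
        weights[j, sel] = rng.normal(0.0, cfg.activity_weight_sd, len(sel))
    true_pic50 = intercepts[None, :] + act.astype(float) @ weights.T

    # --- measured replicate rows
    measured = rng.random((n, t)) < cfg.measured_rate
    rows = []
    for i in range(n):
        for j in range(t):
            if not measured[i, j]:
                continue
            n_rep = 1 + int(rng.random() < cfg.replicate_rate)
            for _ in range(n_rep):
                rows.append({
                    "compound_id": ids[i],
                    "transporter": transporters[j],
                    "pic50": true_pic50[i, j] + rng.normal(0, cfg.noise_sd),
                })
    activity = pd.DataFrame(rows,
                            columns=["compound_id", "transporter", "pic50"])

    # --- toxicokinetics
    molwt = rng.lognormal(np.log(cfg.molwt_median), cfg.molwt_sigma, size=n)
    fub = np.clip(rng.lognormal(np.log(cfg.fub_median), cfg.fub_sigma,
                                size=n), 1e-4, 1.0)
    clint = rng.lognormal(np.log(cfg.clint_median), cfg.clint_sigma, size=n)
    tk = {ids[i]: TKParameters(fub=float(fub[i]), clint=float(clint[i]),
                               molwt=float(molwt[i]), source="synthetic")
          for i in range(n)}

    # --- ground-truth dose matrix (deterministic point Css)
    ieod = np.zeros((n, t))
    for i in range(n):
        css = compute_css(tk[ids[i]], cfg.physiology)
        _, ic50_mg_l = ic50_from_pic50(true_pic50[i], molwt[i])
        ieod[i] = np.asarray(ic50_mg_l) / css.css_per_unit_dose
    true_doses = DoseMatrix(ids, transporters, ieod,
                            {"source": "synthetic_ground_truth",
                             "seed": cfg.seed})

    # --- therapeutic doses with controlled margin around n* x min IEOD50
    min_ieod = true_doses.min_per_compound()
    pos = rng.random(n) < cfg.prevalence
    u = (cfg.td_log_margin + np.abs(rng.normal(0, cfg.td_log_sd, size=n)))
    u = np.where(pos, u, -u)
    td = cfg.true_n_factor * min_ieod * 10.0 ** u

    # --- labels
    if cfg.label_mode == "pk_rule":
        labels = (td > cfg.true_n_factor * min_ieod).astype(int)
    else:
        labels = np.isin(clusters, cfg.positive_clusters).astype(int)
    flip = rng.random(n) < cfg.label_noise
    labels = np.where(flip, 1 - labels, labels)

    achieved = labels.mean()
    se = np.sqrt(cfg.prevalence * (1 - cfg.prevalence) / n)
    if cfg.label_mode == "pk_rule" and abs(achieved - cfg.prevalence) > 3 * se \
            and cfg.label_noise == 0:
        warnings.warn(
            f"achieved prevalence {achieved:.3f} deviates from target "
            f"{cfg.prevalence:.3f}", PrevalenceWarning)

    # --- routes and ATC-like therapeutic classes
    routes = list(rng.choice(
        ["oral", "intravenous", "other"], size=n,
        p=[1 - cfg.frac_intravenous - cfg.frac_other_route,
           cfg.frac_intravenous, cfg.frac_other_route]))
    atc = []
    for i in range(n):
        if rng.random() < cfg.atc_cluster_assoc:
            code = ATC_POOL[clusters[i] % len(ATC_POOL)]
        else:
            code = ATC_POOL[rng.integers(len(ATC_POOL))]
        atc.append([code])

    return SyntheticDataset(
        config=cfg, compound_ids=ids, fingerprints=fp, clusters=clusters,
        routes=routes, atc_codes=atc, molwt=molwt, tk=tk,
        transporters=transporters, true_pic50=true_pic50, activity=activity,
        true_dose_matrix=true_doses, td=td, labels=labels,
    )


def _fp_to_string(row: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in row)


def export(dataset: SyntheticDataset, directory) -> Path:
    """Write the CSV bundle the pipeline consumes; returns the directory."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        probe = d / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write synthetic bundle to {d}: {exc}") from exc
    ds = dataset
    pd.DataFrame({
        "id": ds.compound_ids,
        "route": ds.routes,
        "td": ds.td,
        "atc": [";".join(a) for a in ds.atc_codes],
        "label": np.where(ds.labels == 1, "cholestatic", "noncholestatic"),
        "cluster": ds.clusters,
        "molwt": ds.molwt,
    }).to_csv(d / "compounds.csv", index=False)
    pd.DataFrame({
        "id": ds.compound_ids,
        "bits": [_fp_to_string(r) for r in ds.fingerprints],
    }).to_csv(d / "fingerprints.csv", index=False)
    ds.activity.to_csv(d / "activities.csv", index=False)
    pd.DataFrame({
        "id": ds.compound_ids,
        "fub": [ds.tk[c].fub for c in ds.compound_ids],
        "clint": [ds.tk[c].clint for c in ds.compound_ids],
        "molwt": [ds.tk[c].molwt for c in ds.compound_ids],
        "source": [ds.tk[c].source for c in ds.compound_ids],
    }).to_csv(d / "tk.csv", index=False)
    ds.true_dose_matrix.to_frame().rename_axis("compound_id") \
        .to_csv(d / "true_doses.csv")
    pd.DataFrame(ds.true_pic50, index=ds.compound_ids,
                 columns=ds.transporters).rename_axis("compound_id") \
        .to_csv(d / "true_pic50.csv")
    cfg = asdict(ds.config)
    cfg["physiology"] = asdict(ds.config.physiology)
    with open(d / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=list)
    return d


def load_bundle(directory) -> SyntheticDataset:
    """Reload a bundle written by :func:`export` (roundtrip inverse)."""
    d = Path(directory)
    with open(d / "config.json") as fh:
        cfg_d = json.load(fh)
    cfg_d["physiology"] = PhysiologyConfig(**cfg_d["physiology"])
    cfg_d["positive_clusters"] = tuple(cfg_d["positive_clusters"])
    cfg = SyntheticConfig(**cfg_d)
    comp = pd.read_csv(d / "compounds.csv", dtype={"id": str, "atc": str})
    fps = pd.read_csv(d / "fingerprints.csv", dtype={"id": str, "bits": str})
    fp = np.array([[int(ch) for ch in s] for s in fps["bits"]], dtype=np.uint8)
    activity = pd.read_csv(d / "activities.csv",
                           dtype={"compound_id": str, "transporter": str})
    tk_df = pd.read_csv(d / "tk.csv", dtype={"id": str})
    tk = {str(r.id): TKParameters(fub=float(r.fub), clint=float(r.clint),
                                  molwt=float(r.molwt), source=str(r.source))
          for r in tk_df.itertuples(index=False)}
    doses = pd.read_csv(d / "true_doses.csv", index_col="compound_id")
    pic50 = pd.read_csv(d / "true_pic50.csv", index_col="compound_id")
    ids = list(comp["id"])
    return SyntheticDataset(
        config=cfg,
        compound_ids=ids,
        fingerprints=fp,
        clusters=comp["cluster"].to_numpy(dtype=int),
        routes=list(comp["route"]),
        atc_codes=[[c for c in str(a).split(";") if c]
                   for a in comp["atc"].fillna("")],
        molwt=comp["molwt"].to_numpy(dtype=float),
        tk=tk,
        transporters=list(doses.columns),
        true_pic50=pic50.to_numpy(dtype=float),
        activity=activity,
        true_dose_matrix=DoseMatrix(ids, list(doses.columns),
                                    doses.to_numpy(dtype=float),
                                    {"source": "synthetic_ground_truth",
                                     "seed": cfg.seed}),
        td=comp["td"].to_numpy(dtype=float),
        labels=(comp["label"] == "cholestatic").to_numpy(dtype=int),
    )
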