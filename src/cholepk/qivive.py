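"""Quantitative in vitro to in vivo extrapolation (QIVIVE).

Converts transporter inhibition potencies (pIC50, -log10 molar) into
in vivo equivalent oral doses (IEOD50, mg/kg/day) by reverse dosimetry
through an analytic one-compartment steady-state toxicokinetic model:

* whole-liver intrinsic clearance is scaled up from the per-hepatocyte
  value via hepatocellularity and liver mass;
* hepatic clearance follows the well-stirred contract
  ``CLh = Q * fub * CLint / (Q + fub * CLint)``;
* renal clearance is glomerular filtration of unbound drug,
  ``CLr = fub * GFR``;
* the steady-state plasma concentration for a constant oral input of
  1 mg/kg/day is ``Css = F * BW / (24 * (CLh + CLr))`` in mg/L.

The IEOD50 is the external dose rate whose steady-state concentration
equals the in vitro IC50: ``IEOD50 = IC50[mg/L] / Css[per unit dose]``.
Population conservatism is obtained by Monte-Carlo sampling of fub and
Clint and taking an upper Css percentile (default the 90th), which
lowers the IEOD50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TKParameters",
    "PhysiologyConfig",
    "SteadyStateResult",
    "DoseMatrix",
    "InfiniteCssError",
    "ic50_from_pic50",
    "pic50_from_ic50_micromolar",
    "compute_css",
    "css_percentile_mc",
    "compute_ieod50",
    "build_dose_matrix",
    "filter_implausible_doses",
    "filter_missing_tk",
    "load_tk_csv",
]


class InfiniteCssError(ValueError):
    """Total clearance is zero, so the steady state does not exist."""


@dataclass(frozen=True)
class TKParameters:
    """Per-compound toxicokinetic inputs.

    Parameters
    ----------
    fub:
        Unbound plasma fraction, dimensionless, in (0, 1].
    clint:
        Intrinsic clearance, μL/min/10^6 hepatocytes, >= 0.
    molwt:
        Molecular weight, g/mol.
    source:
        Provenance of the values: "experimental", "predicted" or
        "synthetic".
    """

    fub: float
    clint: float
    molwt: float
    source: str = "experimental"

    def __post_init__(self) -> None:
        if not (0.0 < self.fub <= 1.0):
            raise ValueError(f"fub must be in (0, 1], got {self.fub}")
        if self.clint < 0.0:
            raise ValueError(f"clint must be >= 0, got {self.clint}")
        if self.molwt <= 0.0:
            raise ValueError(f"molwt must be > 0, got {self.molwt}")
        if self.source not in ("experimental", "predicted", "synthetic"):
            raise ValueError(f"unknown TK source {self.source!r}")


@dataclass(frozen=True)
class PhysiologyConfig:
    """Population physiology and sampling settings for the steady state.

    Defaults describe a reference 70 kg human: hepatic blood flow 90 L/h,
    glomerular filtration 6.7 L/h, hepatocellularity 110e6 cells per gram
    of liver and 1820 g liver mass. ``css_percentile`` selects the upper
    population percentile of Css used for reverse dosimetry (0.90 is the
    conservative default); ``variability_cv`` is the lognormal coefficient
    of variation applied to fub and Clint in the Monte-Carlo step.
    ``bioavailability`` scales the absorbed fraction of the oral dose.
    """

    body_weight: float = 70.0          # kg
    liver_blood_flow: float = 90.0     # L/h
    gfr: float = 6.7                   # L/h
    hepatocellularity: float = 110.0   # 10^6 cells / g liver
    liver_mass: float = 1820.0         # g
    css_percentile: float = 0.90
    mc_draws: int = 1000
    variability_cv: float = 0.3
    bioavailability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("body_weight", "liver_blood_flow", "gfr",
                     "hepatocellularity", "liver_mass", "bioavailability"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.css_percentile < 1.0):
            raise ValueError("css_percentile must be in (0, 1)")
        if self.mc_draws < 1:
            raise ValueError("mc_draws must be >= 1")
        if self.variability_cv < 0:
            raise ValueError("variability_cv must be >= 0")


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady-state concentration per unit dose rate.

    ``css_per_unit_dose`` is in mg/L per (mg/kg/day); ``clearance_total``
    is the point-estimate total clearance in L/h; ``percentile_used`` is
    the population percentile the Css corresponds to (0.5 denotes the
    deterministic point estimate).
    """

    css_per_unit_dose: float
    clearance_total: float
    percentile_used: float


def ic50_from_pic50(pic50, molwt):
    """Convert pIC50 (-log10 molar) to IC50 in μM and mg/L.

    ``IC50[μM] = 10**(6 - pIC50)``; mass units follow from the molecular
    weight: ``IC50[mg/L] = IC50[μM] * molwt / 1000``.
    """
    pic50 = np.asarray(pic50, dtype=float)
    molwt = np.asarray(molwt, dtype=float)
    if np.any(molwt <= 0):
        raise ValueError("molwt must be > 0")
    ic50_um = 10.0 ** (6.0 - pic50)
    ic50_mg_l = ic50_um * molwt / 1000.0
    if pic50.ndim == 0:
        return float(ic50_um), float(ic50_mg_l)
    return ic50_um, ic50_mg_l


def pic50_from_ic50_micromolar(ic50_um):
    """Inverse of :func:`ic50_from_pic50` for the micromolar branch."""
    ic50_um = np.asarray(ic50_um, dtype=float)
    out = 6.0 - np.log10(ic50_um)
    return float(out) if out.ndim == 0 else out


def _total_clearance(fub, clint, phys: PhysiologyConfig):
    """Well-stirred hepatic plus glomerular renal clearance, L/h."""
    # μL/min/1e6 cells -> L/h for the whole liver
    clint_whole = (
        np.asarray(clint, dtype=float)
        * phys.hepatocellularity
        * phys.liver_mass
        * 60.0
        / 1.0e6
    )
    q = phys.liver_blood_flow
    fu = np.asarray(fub, dtype=float)
    num = q * fu * clint_whole
    den = q + fu * clint_whole
    clh = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    clr = fu * phys.gfr
    return clh + clr


def compute_css(tk: TKParameters, phys: PhysiologyConfig) -> SteadyStateResult:
    """Analytic steady state for a constant oral input of 1 mg/kg/day."""
    cl = float(_total_clearance(tk.fub, tk.clint, phys))
    if cl <= 0.0 or not math.isfinite(cl):
        raise InfiniteCssError(
            "total clearance is zero or non-finite; steady state undefined"
        )
    dose_rate = phys.bioavailability * 1.0 * phys.body_weight / 24.0  # mg/h
    return SteadyStateResult(
        css_per_unit_dose=dose_rate / cl,
        clearance_total=cl,
        percentile_used=0.5,
    )


def _lognormal_draws(rng: np.random.Generator, point: float, cv: float,
                     n: int) -> np.ndarray:
    """Mean-preserving lognormal sample around ``point`` with CV ``cv``."""
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = math.log(point) - 0.5 * sigma * sigma
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def css_percentile_mc(tk: TKParameters, phys: PhysiologyConfig,
                      rng: np.random.Generator | None = None) -> SteadyStateResult:
    """Upper population percentile of Css via Monte-Carlo on fub and Clint.

    fub and Clint are drawn from mean-preserving lognormals with
    coefficient of variation ``phys.variability_cv`` (fub truncated at 1);
    the requested percentile is read off the sorted draws as the order
    statistic with index ``ceil(p * n)`` (1-based). With zero variability
    the result degenerates to :func:`compute_css`.
    """
    point = compute_css(tk, phys)
    if phys.variability_cv == 0.0:
        return replace(point, percentile_used=phys.css_percentile)
    if rng is None:
        rng = np.random.default_rng(phys.seed)
    n = phys.mc_draws
    fub = np.minimum(_lognormal_draws(rng, tk.fub, phys.variability_cv, n), 1.0)
    clint = _lognormal_draws(rng, max(tk.clint, 0.0), phys.variability_cv, n) \
        if tk.clint > 0 else np.zeros(n)
    cl = _total_clearance(fub, clint, phys)
    dose_rate = phys.bioavailability * phys.body_weight / 24.0
    css = dose_rate / cl
    css_sorted = np.sort(css)
    k = min(max(math.ceil(phys.css_percentile * n), 1), n) - 1
    return SteadyStateResult(
        css_per_unit_dose=float(css_sorted[k]),
        clearance_total=point.clearance_total,
        percentile_used=phys.css_percentile,
    )


def compute_ieod50(ic50_mg_per_l, css: SteadyStateResult):
    """Reverse dosimetry: the dose rate whose Css equals the IC50.

    ``IEOD50 [mg/kg/day] = IC50 [mg/L] / Css-per-unit-dose``; directly
    proportional to IC50 and inversely proportional to Css.
    """
    ic50 = np.asarray(ic50_mg_per_l, dtype=float)
    if np.any(ic50 <= 0) or css.css_per_unit_dose <= 0:
        raise ValueError("IC50 and Css must be positive")
    out = ic50 / css.css_per_unit_dose
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseMatrix:
    """Compounds x transporters matrix of IEOD50 (mg/kg/day).

    ``pieod50`` is the elementwise negative decadic log of the dose.
    ``metadata`` carries physiology, percentile and seed provenance.
    """

    compound_ids: list[str]
    transporters: list[str]
    ieod50: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ieod50 = np.asarray(self.ieod50, dtype=float)
        if self.ieod50.shape != (len(self.compound_ids), len(self.transporters)):
            raise ValueError("ieod50 shape does not match ids/transporters")
        if np.any(self.ieod50[np.isfinite(self.ieod50)] <= 0):
            raise ValueError("IEOD50 values must be > 0 where defined")

    @property
    def pieod50(self) -> np.ndarray:
        return -np.log10(self.ieod50)

    def min_per_compound(self) -> np.ndarray:
        return np.nanmin(self.ieod50, axis=1)

    def max_per_compound(self) -> np.ndarray:
        return np.nanmax(self.ieod50, axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ieod50, index=self.compound_ids,
                            columns=self.transporters)

    def write_csv(self, path, metadata_path=None) -> None:
        self.to_frame().rename_axis("compound_id").to_csv(path)
        if metadata_path is not None:
            import json
            with open(metadata_path, "w") as fh:
                json.dump(self.metadata, fh, indent=2, default=str)


def build_dose_matrix(activity_values: np.ndarray,
                      compound_ids: Sequence[str],
                      transporters: Sequence[str],
                      tk: dict[str, TKParameters],
                      phys: PhysiologyConfig,
                      use_percentile: bool = True) -> DoseMatrix:
    """Map a pIC50 activity matrix to an IEOD50 dose matrix.

    Each compound uses its own TK parameters; the Css is the Monte-Carlo
    percentile when ``use_percentile`` (and variability is nonzero), else
    the deterministic point estimate.
    """
    values = np.asarray(activity_values, dtype=float)
    n, t = values.shape
    if n != len(compound_ids) or t != len(transporters):
        raise ValueError("activity matrix shape mismatch")
    missing = [cid for cid in compound_ids if cid not in tk]
    if missing:
        raise KeyError(f"missing TK parameters for compounds: {missing[:5]}")
    rng = np.random.default_rng(phys.seed)
    ieod = np.empty_like(values)
    for i, cid in enumerate(compound_ids):
        tki = tk[cid]
        css = (css_percentile_mc(tki, phys, rng=rng) if use_percentile
               else compute_css(tki, phys))
        _, ic50_mg_l = ic50_from_pic50(values[i], tki.molwt)
        ieod[i] = np.asarray(ic50_mg_l) / css.css_per_unit_dose
    meta = {
        "physiology": phys.__dict__ | {},
        "percentile": phys.css_percentile if use_percentile else None,
        "seed": phys.seed,
    }
    return DoseMatrix(list(compound_ids), list(transporters), ieod, meta)


def filter_implausible_doses(matrix: DoseMatrix,
                             threshold: float = 10000.0
                             ) -> tuple[DoseMatrix, list[str]]:
    """Drop compounds whose minimum IEOD50 exceeds ``threshold`` mg/kg/day.

    The minimum over transporters is the quantity the OR decision rule
    consumes; a compound whose most potent transporter-equivalent dose is
    beyond the threshold is physiologically implausible. The boundary
    value itself is kept (strictly-greater removal).
    """
    mins = matrix.min_per_compound()
    keep = mins <= threshold
    removed = [cid for cid, k in zip(matrix.compound_ids, keep) if not k]
    filtered = DoseMatrix(
        [cid for cid, k in zip(matrix.compound_ids, keep) if k],
        list(matrix.transporters),
        matrix.ieod50[keep],
        dict(matrix.metadata),
    )
    return filtered, removed


def filter_missing_tk(compound_ids: Sequence[str],
                      tk: dict[str, TKParameters]
                      ) -> tuple[list[str], list[str]]:
    """Split compounds into (with TK, without TK) preserving order."""
    kept = [cid for cid in compound_ids if cid in tk]
    dropped = [cid for cid in compound_ids if cid not in tk]
    return kept, dropped


def load_tk_csv(path) -> dict[str, TKParameters]:
    """Read the TK parameter table: columns id, fub, clint, molwt, source."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "fub", "clint", "molwt"}
    if not required.issubset(df.columns):
        raise ValueError(f"TK CSV must have columns {sorted(required)}")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.id)] = TKParameters(
            fub=float(row.fub), clint=float(row.clint),
            molwt=float(row.molwt),
            source=getattr(row, "source", "experimental"),
        )
    return out
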