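"""Structure standardization, dataset filters and descriptor blocks.

Curation mirrors common bioactivity-database practice: salts are stripped
to the largest organic fragment, charges are neutralized where chemically
valid, and compounds that are inorganic (no carbon) or contain metallic
elements are rejected. Features are Morgan fingerprints (radius 2,
2048 bits, feature invariants) and a small physicochemical descriptor
block (the Lipinski rule-of-five variables plus a few companions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "Rejection",
    "FilterReport",
    "DescriptorError",
    "ALLOWED_ELEMENTS",
    "LIPINSKI_DESCRIPTORS",
    "standardize_structure",
    "apply_dataset_filters",
    "compute_fingerprint",
    "fingerprint_matrix",
    "compute_descriptors",
    "descriptor_matrix",
    "aggregate_duplicate_activities",
    "dose_to_mg_per_kg_day",
    "load_compounds_csv",
    "write_compounds_csv",
]

#: Elements permitted in an organic parent structure. Anything outside
#: this set triggers the "metallic" rejection rule.
ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

VALID_ROUTES = ("oral", "intravenous", "other")
VALID_LABELS = ("cholestatic", "noncholestatic", "unknown")

#: Descriptors entering the Lipinski rule-of-five comparison.
LIPINSKI_DESCRIPTORS = ("ExactMolWt", "MolLogP", "NumHDonors", "NumHAcceptors")


class DescriptorError(ValueError):
    """A descriptor could not be computed; carries the descriptor name."""


@dataclass(frozen=True)
class Rejection:
    """Typed curation rejection: unparseable | inorganic | metallic."""

    reason: str
    raw_smiles: str

    def __post_init__(self) -> None:
        if self.reason not in ("unparseable", "inorganic", "metallic"):
            raise ValueError(f"unknown rejection reason {self.reason!r}")


@dataclass
class CompoundRecord:
    """One curated compound.

    ``therapeutic_dose`` is in mg/kg/day; ``atc_codes`` are level-2 ATC
    strings such as "J01". ``compound_id`` is caller-supplied and opaque.
    """

    compound_id: str
    smiles: str
    route: str = "oral"
    therapeutic_dose: float | None = None
    atc_codes: list[str] = field(default_factory=list)
    label: str = "unknown"
    molwt: float = 0.0
    logp: float = 0.0

    def __post_init__(self) -> None:
        if self.route not in VALID_ROUTES:
            raise ValueError(f"route must be one of {VALID_ROUTES}")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}")
        if self.therapeutic_dose is not None and not self.therapeutic_dose > 0:
            raise ValueError("therapeutic_dose must be > 0 when present")


@dataclass
class FilterReport:
    """Counts of records removed per curation stage, in application order."""

    stages: dict[str, int] = field(default_factory=dict)

    def add_stage(self, name: str, removed: int) -> None:
        self.stages[name] = self.stages.get(name, 0) + int(removed)

    @property
    def total_removed(self) -> int:
        return sum(self.stages.values())

    def to_dict(self) -> dict:
        return {"stages": dict(self.stages), "total_removed": self.total_removed}


_UNCHARGER = rdMolStandardize.Uncharger()


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags
               if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    if not organic:
        return None
    return max(organic,
               key=lambda f: (f.GetNumHeavyAtoms(), f.GetNumAtoms(),
                              Chem.MolToSmiles(f)))


def standardize_structure(raw_smiles: str, compound_id: str = "",
                          **record_kwargs) -> CompoundRecord | Rejection:
    """Canonicalize a parent structure or return a typed rejection.

    Steps: parse; keep the largest carbon-containing fragment (salt
    stripping); neutralize charges; reject "metallic" when a disallowed
    element survives (or when no organic fragment exists but a disallowed
    element is present anywhere), "inorganic" when no carbon-containing
    fragment exists. Stereochemistry is preserved as given.
    """
    if not raw_smiles:
        raise ValueError("raw_smiles must be nonempty")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return Rejection("unparseable", raw_smiles)
    parent = _largest_organic_fragment(mol)
    if parent is None:
        symbols = {a.GetSymbol() for a in mol.GetAtoms()}
        reason = "metallic" if symbols - ALLOWED_ELEMENTS else "inorganic"
        return Rejection(reason, raw_smiles)
    symbols = {a.GetSymbol() for a in parent.GetAtoms()}
    if symbols - ALLOWED_ELEMENTS:
        return Rejection("metallic", raw_smiles)
    try:
        Chem.SanitizeMol(parent)
        parent = _UNCHARGER.uncharge(parent)
    except Exception:
        return Rejection("unparseable", raw_smiles)
    smiles = Chem.MolToSmiles(parent)
    return CompoundRecord(
        compound_id=compound_id or smiles,
        smiles=smiles,
        molwt=float(Descriptors.MolWt(parent)),
        logp=float(Descriptors.MolLogP(parent)),
        **record_kwargs,
    )


def apply_dataset_filters(records: Sequence[CompoundRecord],
                          report: FilterReport | None = None
                          ) -> tuple[list[CompoundRecord], FilterReport]:
    """Keep only compounds administered orally or intravenously.

    The later stages of the curation chain (missing TK inputs,
    implausible doses) live in :mod:`cholepk.qivive`; pass the returned
    report on so their counts accumulate in application order.
    """
    if report is None:
        report = FilterReport()
    kept = [r for r in records if r.route in ("oral", "intravenous")]
    report.add_stage("route", len(records) - len(kept))
    return kept, report


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=2,
    fpSize=2048,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
)


def compute_fingerprint(record_or_smiles) -> np.ndarray:
    """Feature-invariant Morgan fingerprint, radius 2, 2048 bits.

    Returns a uint8 0/1 vector. Deterministic and invariant to the atom
    ordering of equivalent SMILES.
    """
    smiles = getattr(record_or_smiles, "smiles", record_or_smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid structure for fingerprint: {smiles!r}")
    fp = _FP_GEN.GetFingerprint(mol)
    arr = np.zeros(2048, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(records: Iterable) -> np.ndarray:
    """Stack fingerprints into an (n, 2048) uint8 matrix."""
    return np.vstack([compute_fingerprint(r) for r in records])


_EXTRA_DESCRIPTORS = {
    "TPSA": Descriptors.TPSA,
    "NumRotatableBonds": Descriptors.NumRotatableBonds,
    "RingCount": Descriptors.RingCount,
    "FractionCSP3": Descriptors.FractionCSP3,
}


def _lipinski_donors(mol: Chem.Mol) -> int:
    """Classic rule-of-five donor count: N/O atoms bearing >= 1 H."""
    return sum(1 for a in mol.GetAtoms()
               if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() > 0)


def _lipinski_acceptors(mol: Chem.Mol) -> int:
    """Classic rule-of-five acceptor count: number of N and O atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))


def compute_descriptors(record_or_smiles) -> dict[str, float]:
    """Physicochemical block: Lipinski variables plus companions.

    Used both for the cholestatic-vs-noncholestatic property comparison
    and as the PC feature block of the direct QSAR baseline. Donor and
    acceptor counts follow the original rule-of-five definitions
    (heteroatom counts), which count e.g. water as one donor and one
    acceptor.
    """
    smiles = getattr(record_or_smiles, "smiles", record_or_smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid structure for descriptors: {smiles!r}")
    funcs = {
        "ExactMolWt": Descriptors.ExactMolWt,
        "MolLogP": Descriptors.MolLogP,
        "NumHDonors": _lipinski_donors,
        "NumHAcceptors": _lipinski_acceptors,
        **_EXTRA_DESCRIPTORS,
    }
    out: dict[str, float] = {}
    for name, fn in funcs.items():
        try:
            val = float(fn(mol))
        except Exception as exc:  # pragma: no cover - rdkit edge cases
            raise DescriptorError(f"descriptor {name} failed: {exc}") from exc
        if not np.isfinite(val):
            raise DescriptorError(f"descriptor {name} is not finite")
        out[name] = val
    return out


def descriptor_matrix(records: Iterable) -> pd.DataFrame:
    rows = [compute_descriptors(r) for r in records]
    index = [getattr(r, "compound_id", i) for i, r in enumerate(records)] \
        if hasattr(records, "__len__") else None
    return pd.DataFrame(rows, index=index)


def aggregate_duplicate_activities(activity: pd.DataFrame
                                   ) -> tuple[pd.DataFrame, dict]:
    """Replicate handling for bioactivity tables.

    Training keeps every replicate row (replicates weight the compound in
    the regression), while the returned lookup maps
    ``(compound_id, transporter) -> mean pIC50`` and is used downstream to
    override model predictions with experimental means.
    """
    required = {"compound_id", "transporter", "pic50"}
    if not required.issubset(activity.columns):
        raise ValueError(f"activity table needs columns {sorted(required)}")
    if not np.all(np.isfinite(activity["pic50"].to_numpy(dtype=float))):
        raise ValueError("pIC50 values must be finite")
    means = activity.groupby(["compound_id", "transporter"])["pic50"].mean()
    lookup = {(cid, tr): float(v) for (cid, tr), v in means.items()}
    return activity.copy(), lookup


def dose_to_mg_per_kg_day(dose_mg_per_day: float,
                          body_weight: float = 70.0) -> float:
    """Convert a clinical dose in mg/day to mg/kg/day (default 70 kg)."""
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    return dose_mg_per_day / body_weight


def load_compounds_csv(path) -> list[CompoundRecord]:
    """Read the compound table: columns smiles,id,route,td,atc,label.

    ``td`` is the therapeutic dose in mg/kg/day (blank allowed); ``atc``
    is a ;-separated list of level-2 codes. Unparseable or rejected
    structures are skipped (they surface in the curation report of the
    pipeline, which calls :func:`standardize_structure` itself).
    """
    df = pd.read_csv(path, dtype={"id": str})
    required = {"smiles", "id", "route", "td", "atc", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"compound CSV must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        td = None if pd.isna(row.td) else float(row.td)
        atc = [] if pd.isna(row.atc) or not str(row.atc) else \
            [c.strip() for c in str(row.atc).split(";") if c.strip()]
        label = row.label if isinstance(row.label, str) else "unknown"
        rec = standardize_structure(
            str(row.smiles), compound_id=str(row.id), route=str(row.route),
            therapeutic_dose=td, atc_codes=atc, label=label,
        )
        if isinstance(rec, CompoundRecord):
            records.append(rec)
    return records


def write_compounds_csv(records: Sequence[CompoundRecord], path) -> None:
    df = pd.DataFrame({
        "smiles": [r.smiles for r in records],
        "id": [r.compound_id for r in records],
        "route": [r.route for r in records],
        "td": [r.therapeutic_dose for r in records],
        "atc": [";".join(r.atc_codes) for r in records],
        "label": [r.label for r in records],
        "molwt": [r.molwt for r in records],
        "logp": [r.logp for r in records],
    })
    df.to_csv(path, index=False)
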