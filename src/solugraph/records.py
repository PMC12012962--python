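"""Core chemical record types, structure standardization and eligibility filters.

Aqueous solubility is modelled as log Sw, the base-10 logarithm of the molar
solubility (mol/L) of the neutral organic compound.  This module parses raw
tabular data into :class:`MoleculeRecord` objects, standardizes structures to
a canonical SMILES / InChIKey, and applies the structural eligibility rules
used to assemble a modelling dataset:

* salts and mixtures are detected as multi-fragment structures and removed
  (no desalting is attempted),
* inorganic chemicals are operationalized as carbon-free structures,
* very large chemicals (molar mass > 900 g/mol) are removed,
* fully miscible chemicals (log Sw > 0.50) are removed.

Both cutoffs are strict inequalities: a compound with molar mass exactly
900 g/mol or log Sw exactly 0.50 is eligible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, inchi, rdMolDescriptors

# RDKit is chatty on malformed input; failures are surfaced as StructureError.
RDLogger.DisableLog("rdApp.*")

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class StructureError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{detail}: {smiles!r}")


class FilterReason(str, Enum):
    invalid_structure = "invalid_structure"
    multi_fragment = "multi_fragment"
    inorganic = "inorganic"
    too_large = "too_large"
    miscible = "miscible"


@dataclass
class MoleculeRecord:
    """One raw dataset row: an identifier, a SMILES and its measured values."""

    record_id: str
    input_smiles: str
    logsw_values: list[tuple[float, str]] = field(default_factory=list)
    notes: str = ""


@dataclass(frozen=True)
class StandardizedMolecule:
    """A structure resolved to canonical identifiers and gross composition."""

    canonical_smiles: str
    inchikey: str
    molecular_formula: str
    molar_mass: float
    heavy_atom_count: int
    fragment_count: int
    has_carbon: bool

    def __post_init__(self) -> None:
        if not _INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"malformed InChIKey: {self.inchikey!r}")


@dataclass(frozen=True)
class FilterDecision:
    eligible: bool
    reasons: tuple[FilterReason, ...]

    def __post_init__(self) -> None:
        if self.eligible != (len(self.reasons) == 0):
            raise ValueError("eligible must hold exactly when reasons is empty")


@dataclass
class FilterConfig:
    """Eligibility cutoffs; both comparisons are strict (>)."""

    max_molar_mass: float = 900.0
    max_logsw: float = 0.50


@dataclass
class ParseIssue:
    row_index: int
    record_id: str
    reason: str


@dataclass
class ParseReport:
    issues: list[ParseIssue] = field(default_factory=list)

    def add(self, row_index: int, record_id: str, reason: str) -> None:
        self.issues.append(ParseIssue(row_index, record_id, reason))

    def __len__(self) -> int:
        return len(self.issues)


DEFAULT_COLUMN_MAP = {"id": "id", "smiles": "smiles", "logsw": "logS", "source": "source"}


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`StructureError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureError(str(smiles), "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    return mol


def read_dataset(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> tuple[list[MoleculeRecord], ParseReport]:
    """Read a CSV of (id, smiles, log Sw, source) rows into MoleculeRecords.

    Rows are *not* merged by identifier here; duplicate structures are merged
    later during curation.  Rows with an empty SMILES or an unparseable label
    are skipped and listed in the returned :class:`ParseReport`.

    If the mapped log-Sw column is absent from ``column_map`` (set to None),
    records are returned without labels (prediction-only input).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={cmap["id"]: str})
    for key in ("id", "smiles"):
        if cmap[key] not in df.columns:
            raise KeyError(f"mapped column {cmap[key]!r} (for {key!r}) not in {path}")
    want_label = cmap.get("logsw") is not None
    if want_label and cmap["logsw"] not in df.columns:
        raise KeyError(f"mapped column {cmap['logsw']!r} (for 'logsw') not in {path}")
    has_source = cmap.get("source") in df.columns

    records: list[MoleculeRecord] = []
    report = ParseReport()
    for i, row in df.iterrows():
        rid = str(row[cmap["id"]])
        smiles = row[cmap["smiles"]]
        if not isinstance(smiles, str) or not smiles.strip():
            report.add(int(i), rid, "empty_smiles")
            continue
        values: list[tuple[float, str]] = []
        if want_label:
            raw = row[cmap["logsw"]]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                report.add(int(i), rid, "unparseable_label")
                continue
            if pd.isna(value):
                report.add(int(i), rid, "missing_label")
                continue
            source = str(row[cmap["source"]]) if has_source else ""
            values.append((value, source))
        records.append(MoleculeRecord(rid, smiles.strip(), values))
    return records, report


def read_smiles_file(path: str | Path) -> list[str]:
    """Read a plain SMILES list, one structure per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip().split()[0] for ln in lines if ln.strip()]


def read_sdf(path: str | Path) -> list[MoleculeRecord]:
    """Read structures from an SDF file (labels, if any, stay in ``notes``)."""
    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_{i}"
        records.append(MoleculeRecord(rid, Chem.MolToSmiles(mol)))
    return records


def standardize_structure(smiles: str) -> StandardizedMolecule:
    """Resolve a SMILES to canonical form and gross composition.

    Idempotent: standardizing the returned canonical SMILES yields the same
    canonical SMILES and InChIKey.  Molar mass is the average molecular weight
    of the neutral structure including implicit hydrogens.
    """
    mol = mol_from_smiles(smiles)
    canonical = Chem.MolToSmiles(mol)
    key = inchi.MolToInchiKey(mol)
    if not key:
        raise StructureError(smiles, "no InChIKey could be derived")
    return StandardizedMolecule(
        canonical_smiles=canonical,
        inchikey=key,
        molecular_formula=rdMolDescriptors.CalcMolFormula(mol),
        molar_mass=Descriptors.MolWt(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        fragment_count=len(Chem.GetMolFrags(mol)),
        has_carbon=any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()),
    )


def apply_eligibility_filters(
    mol: StandardizedMolecule,
    logsw: float | None = None,
    cfg: FilterConfig | None = None,
) -> FilterDecision:
    """Decide whether a standardized structure enters the modelling dataset."""
    cfg = cfg or FilterConfig()
    reasons: list[FilterReason] = []
    if mol.fragment_count > 1:
        reasons.append(FilterReason.multi_fragment)
    if not mol.has_carbon:
        reasons.append(FilterReason.inorganic)
    if mol.molar_mass > cfg.max_molar_mass:
        reasons.append(FilterReason.too_large)
    if logsw is not None and logsw > cfg.max_logsw:
        reasons.append(FilterReason.miscible)
    return FilterDecision(eligible=not reasons, reasons=tuple(reasons))


def write_standardized_csv(
    rows: Iterable[tuple[MoleculeRecord, StandardizedMolecule]],
    path: str | Path,
) -> None:
    """Write a curation-ready CSV of standardized columns."""
    df = pd.DataFrame(
        [
            {
                "record_id": rec.record_id,
                "canonical_smiles": std.canonical_smiles,
                "inchikey": std.inchikey,
                "molecular_formula": std.molecular_formula,
                "molar_mass": std.molar_mass,
                "heavy_atom_count": std.heavy_atom_count,
                "fragment_count": std.fragment_count,
            }
            for rec, std in rows
        ]
    )
    df.to_csv(path, index=False)


def write_filter_report(
    decisions: Sequence[tuple[str, FilterDecision]], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {"record_id": rid, "eligible": d.eligible,
             "reasons": ";".join(r.value for r in d.reasons)}
            for rid, d in decisions
        ]
    )
    df.to_csv(path, index=False)
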