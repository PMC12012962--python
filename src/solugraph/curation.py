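"""Dataset curation: duplicate merging, multi-value resolution, outlier flagging.

The curation pipeline turns raw measurement rows into one record per unique
structure (keyed by full InChIKey) with a single resolved log Sw label:

1. optional manual-review annotations (remove / replace / keep) are applied,
2. structures are standardized; unparseable rows are removed,
3. rows are merged by InChIKey, pooling all measured values,
4. a single label is resolved per structure:
   one value -> that value; exactly two distinct values -> the one nearer an
   independent reference prediction; three or more -> the value nearest the
   mean of all values (ties broken toward the more negative, less soluble,
   value),
5. structural and miscibility eligibility filters are applied,
6. optionally, records whose label deviates from a model prediction by more
   than 1 log unit are flagged for manual review (advisory only; the dataset
   is not modified).

The log accounts for every input row exactly once:
``n_input == n_output + sum(removals.values())``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .records import (
    FilterConfig,
    FilterReason,
    MoleculeRecord,
    StandardizedMolecule,
    StructureError,
    apply_eligibility_filters,
    standardize_structure,
)


class ResolutionRule(str, Enum):
    single_value = "single_value"
    mean_sd_selection = "mean_sd_selection"
    reference_prediction_selection = "reference_prediction_selection"


class CurationFlag(str, Enum):
    outlier_gt_1log = "outlier_gt_1log"
    manually_reviewed = "manually_reviewed"


class NeedsReferenceModelError(ValueError):
    """Two conflicting values need a reference prediction to arbitrate."""


@dataclass
class CuratedRecord:
    """One unique chemical with its resolved log Sw label."""

    canonical_smiles: str
    inchikey: str
    logsw: float
    resolution_rule: ResolutionRule
    curation_flags: list[CurationFlag] = field(default_factory=list)
    heavy_atom_count: int = 0
    molar_mass: float = 0.0
    molecular_formula: str = ""
    source_ids: list[str] = field(default_factory=list)
    value_sd: float | None = None  # SD across pooled values, recorded only


@dataclass
class CuratedDataset:
    records: list[CuratedRecord]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.inchikey for r in self.records]

    def get(self, inchikey: str) -> CuratedRecord:
        for r in self.records:
            if r.inchikey == inchikey:
                return r
        raise KeyError(inchikey)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "inchikey": r.inchikey,
                    "canonical_smiles": r.canonical_smiles,
                    "logsw": r.logsw,
                    "resolution_rule": r.resolution_rule.value,
                    "curation_flags": ";".join(f.value for f in r.curation_flags),
                    "heavy_atom_count": r.heavy_atom_count,
                    "molar_mass": r.molar_mass,
                    "molecular_formula": r.molecular_formula,
                    "source_ids": ";".join(r.source_ids),
                }
                for r in self.records
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CuratedDataset":
        df = pd.read_csv(path)
        records = []
        def _split(value):
            if value is None or (isinstance(value, float) and pd.isna(value)):
                return []
            return [tok for tok in str(value).split(";") if tok]

        for _, row in df.iterrows():
            flags = [CurationFlag(f) for f in _split(row.get("curation_flags"))]
            sources = _split(row.get("source_ids"))
            records.append(
                CuratedRecord(
                    canonical_smiles=row["canonical_smiles"],
                    inchikey=row["inchikey"],
                    logsw=float(row["logsw"]),
                    resolution_rule=ResolutionRule(row.get("resolution_rule", "single_value")),
                    curation_flags=flags,
                    heavy_atom_count=int(row.get("heavy_atom_count", 0)),
                    molar_mass=float(row.get("molar_mass", 0.0)),
                    molecular_formula=str(row.get("molecular_formula", "")),
                    source_ids=sources,
                )
            )
        return cls(records)

    def to_molecule_records(self) -> list[MoleculeRecord]:
        return [
            MoleculeRecord(r.inchikey, r.canonical_smiles, [(r.logsw, "curated")])
            for r in self.records
        ]


@dataclass
class OutlierEntry:
    inchikey: str
    experimental: float
    predicted: float
    deviation: float  # absolute, log units


@dataclass
class OutlierReport:
    threshold: float
    entries: list[OutlierEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "inchikey": e.inchikey,
                    "experimental_logsw": e.experimental,
                    "predicted_logsw": e.predicted,
                    "abs_deviation": e.deviation,
                }
                for e in self.entries
            ]
        ).to_csv(path, index=False)


@dataclass
class CurationLog:
    n_input: int = 0
    n_output: int = 0
    removals: dict[str, int] = field(default_factory=dict)
    filter_reason_counts: dict[str, int] = field(default_factory=dict)
    resolutions: dict[str, int] = field(default_factory=dict)
    n_flagged_outliers: int = 0

    def count_removal(self, reason: str, n: int = 1) -> None:
        if n:
            self.removals[reason] = self.removals.get(reason, 0) + n

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


@dataclass
class CurationConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    outlier_threshold: float = 1.0
    outlier_iterations: int = 3
    # record_id -> ("remove"|"keep", None) or ("replace", value)
    annotations: dict[str, tuple[str, float | None]] = field(default_factory=dict)
    exclusion_ids: frozenset[str] = frozenset()
    # behaviour when exactly two values conflict and no reference model exists:
    # "error" (default) or "mean" (fall back to the nearest-to-mean rule)
    two_value_fallback: str = "error"


def resolve_multivalue(
    values: Sequence[float],
    reference_prediction: float | None = None,
) -> tuple[float, ResolutionRule]:
    """Pick one log Sw from several measurements of the same chemical.

    Exact duplicate values are pooled first.  Ties are broken toward the more
    negative (less soluble) value.
    """
    if not values:
        raise ValueError("values must be non-empty")
    unique = sorted(set(float(v) for v in values))
    if len(unique) == 1:
        return unique[0], ResolutionRule.single_value
    if len(unique) == 2:
        if reference_prediction is None:
            raise NeedsReferenceModelError(
                "two conflicting values need a reference model prediction"
            )
        lo, hi = unique
        # sorted ascending: on a tie the more negative value wins
        pick = lo if abs(lo - reference_prediction) <= abs(hi - reference_prediction) else hi
        return pick, ResolutionRule.reference_prediction_selection
    mean = sum(unique) / len(unique)
    pick = min(unique, key=lambda v: (abs(v - mean), v))
    return pick, ResolutionRule.mean_sd_selection


def flag_outliers(
    dataset: CuratedDataset | Sequence[CuratedRecord],
    predictions: dict[str, float],
    threshold: float = 1.0,
) -> OutlierReport:
    """List records whose prediction deviates from experiment by > threshold.

    Advisory only: the dataset is left untouched, matching a manual-review
    step rather than automatic removal.
    """
    records = dataset.records if isinstance(dataset, CuratedDataset) else list(dataset)
    report = OutlierReport(threshold=threshold)
    for rec in records:
        if rec.inchikey not in predictions:
            raise KeyError(f"no prediction for record {rec.inchikey}")
        dev = abs(predictions[rec.inchikey] - rec.logsw)
        if dev > threshold:
            report.entries.append(
                OutlierEntry(rec.inchikey, rec.logsw, predictions[rec.inchikey], dev)
            )
    return report


_FILTER_ORDER = [
    FilterReason.multi_fragment,
    FilterReason.inorganic,
    FilterReason.too_large,
    FilterReason.miscible,
]


def run_curation(
    records: Sequence[MoleculeRecord],
    reference_model: Callable[[str], float] | None = None,
    cfg: CurationConfig | None = None,
) -> tuple[CuratedDataset, CurationLog, OutlierReport | None]:
    """Run the full curation pipeline on raw records.

    ``reference_model`` maps a canonical SMILES to a predicted log Sw; it is
    used both to arbitrate two-value conflicts and (if given) to flag
    outliers.  Returns the curated dataset, a log accounting for every input
    row, and the final outlier report (None when no reference model).
    """
    cfg = cfg or CurationConfig()
    log = CurationLog(n_input=len(records))

    # 1. manual-review annotations + exclusion list
    kept: list[MoleculeRecord] = []
    reviewed_ids: set[str] = set()
    for rec in records:
        if rec.record_id in cfg.exclusion_ids:
            log.count_removal("excluded_list")
            continue
        action = cfg.annotations.get(rec.record_id)
        if action is not None:
            kind, new_value = action
            if kind == "remove":
                log.count_removal("annotation_removed")
                continue
            if kind == "replace":
                rec = MoleculeRecord(
                    rec.record_id,
                    rec.input_smiles,
                    [(float(new_value), "annotation")],
                    rec.notes,
                )
            reviewed_ids.add(rec.record_id)
        kept.append(rec)

    # 2. standardize
    standardized: list[tuple[MoleculeRecord, StandardizedMolecule]] = []
    for rec in kept:
        try:
            std = standardize_structure(rec.input_smiles)
        except StructureError:
            log.count_removal(FilterReason.invalid_structure.value)
            continue
        standardized.append((rec, std))

    # 3. merge by full InChIKey
    groups: dict[str, list[tuple[MoleculeRecord, StandardizedMolecule]]] = {}
    for rec, std in standardized:
        groups.setdefault(std.inchikey, []).append((rec, std))
    log.count_removal("merged_duplicate", sum(len(g) - 1 for g in groups.values()))

    # 4. resolve one value per structure, then 5. filters
    out: list[CuratedRecord] = []
    for key, group in groups.items():
        std = group[0][1]
        values = [v for rec, _ in group for v, _src in rec.logsw_values]
        sources = [rec.record_id for rec, _ in group]
        ref_pred: float | None = None
        if reference_model is not None:
            ref_pred = float(reference_model(std.canonical_smiles))
        try:
            logsw, rule = resolve_multivalue(values, ref_pred)
        except NeedsReferenceModelError:
            if cfg.two_value_fallback == "mean":
                unique = sorted(set(values))
                mean = sum(unique) / len(unique)
                logsw = min(unique, key=lambda v: (abs(v - mean), v))
                rule = ResolutionRule.mean_sd_selection
            else:
                raise
        sd = None
        if len(values) > 1:
            m = sum(values) / len(values)
            sd = (sum((v - m) ** 2 for v in values) / len(values)) ** 0.5
        log.resolutions[rule.value] = log.resolutions.get(rule.value, 0) + 1

        decision = apply_eligibility_filters(std, logsw, cfg.filters)
        if not decision.eligible:
            primary = next(r for r in _FILTER_ORDER if r in decision.reasons)
            log.count_removal(primary.value)
            for r in decision.reasons:
                log.filter_reason_counts[r.value] = (
                    log.filter_reason_counts.get(r.value, 0) + 1
                )
            continue
        flags = []
        if reviewed_ids.intersection(sources):
            flags.append(CurationFlag.manually_reviewed)
        out.append(
            CuratedRecord(
                canonical_smiles=std.canonical_smiles,
                inchikey=key,
                logsw=logsw,
                resolution_rule=rule,
                curation_flags=flags,
                heavy_atom_count=std.heavy_atom_count,
                molar_mass=std.molar_mass,
                molecular_formula=std.molecular_formula,
                source_ids=sources,
                value_sd=sd,
            )
        )

    dataset = CuratedDataset(out)
    log.n_output = len(out)

    # 6. advisory outlier screening (repeated; flags are recomputed per pass)
    report: OutlierReport | None = None
    if reference_model is not None and cfg.outlier_iterations > 0:
        for _ in range(cfg.outlier_iterations):
            preds = {r.inchikey: float(reference_model(r.canonical_smiles)) for r in out}
            report = flag_outliers(dataset, preds, cfg.outlier_threshold)
        flagged = {e.inchikey for e in report.entries}
        for r in out:
            if r.inchikey in flagged and CurationFlag.outlier_gt_1log not in r.curation_flags:
                r.curation_flags.append(CurationFlag.outlier_gt_1log)
        log.n_flagged_outliers = len(report.entries)

    return dataset, log, report


def read_annotations(path: str | Path) -> dict[str, tuple[str, float | None]]:
    """Read a manual-review annotation CSV (record_id, action, new_value)."""
    df = pd.read_csv(path, dtype={"record_id": str})
    out: dict[str, tuple[str, float | None]] = {}
    for _, row in df.iterrows():
        action = str(row["action"]).strip()
        if action not in {"remove", "replace", "keep"}:
            raise ValueError(f"unknown annotation action {action!r}")
        value = float(row["new_value"]) if action == "replace" else None
        out[str(row["record_id"])] = (action, value)
    return out
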