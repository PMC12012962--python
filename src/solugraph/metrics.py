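"""Evaluation statistics for (experimental, predicted) log Sw vectors.

The error convention is ``e_i = pred_i - exp_i``, so a positive bias means
overprediction.  The battery comprises:

* ``r2`` — squared Pearson correlation between experiment and prediction,
* ``q2`` — predictive squared correlation for external validation,
  ``1 - Σe² / Σ(exp_i - ȳ_ref)²`` with ``ȳ_ref`` the *training-set* mean
  when available (flagged when the evaluation-set mean is the fallback),
* ``rmse`` (log units), ``bias`` (mean error),
* ``mne`` / ``mpe`` — most negative / most positive single error,
* ``p95_neg`` / ``p95_pos`` — 95th percentiles of the negative and positive
  error subsets (reported signed; linear-interpolation percentiles).

Helper views slice the battery by molecular size (non-hydrogen atom bins)
and by an ionizability predicate based on a documented SMARTS list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import CuratedRecord
from .records import mol_from_smiles

#: SMARTS patterns whose presence marks a chemical as ionizable in water.
#: Acidic: carboxylic, sulfonic, phosphonic acids, phenols, thiols,
#: sulfonamide/imide N-H.  Basic: non-amide aliphatic amines and amidine /
#: guanidine motifs.
IONIZABLE_SMARTS: dict[str, str] = {
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "sulfonic_acid": "S(=O)(=O)[OX2H1]",
    "phosphonic_acid": "P(=O)[OX2H1]",
    "phenol": "c[OX2H1]",
    "thiol": "[SX2H1]",
    "sulfonamide_nh": "S(=O)(=O)[NX3;H1,H2]",
    "imide_nh": "[CX3](=O)[NX3;H1](C=O)",
    "aliphatic_amine": "[NX3;H2,H1,H0;!$(N[C,S]=[O,S,N]);!$(N=*);!$([N+]);R0]",
    "cyclic_amine": "[NX3;H1,H0;!$(N[C,S]=[O,S,N]);!$(N=*);!$([N+]);R]",
    "amidine_guanidine": "[NX3][CX3]=[NX2]",
}
_IONIZABLE_PATTERNS = {k: Chem.MolFromSmarts(s) for k, s in IONIZABLE_SMARTS.items()}

NHA_BINS: tuple[tuple[int, int | None], ...] = (
    (0, 10),
    (11, 15),
    (16, 20),
    (21, 25),
    (26, 30),
    (31, None),
)


@dataclass
class MetricsReport:
    n: int
    r2: float | None
    q2: float | None
    rmse: float | None
    bias: float | None
    mne: float | None
    mpe: float | None
    p95_neg: float | None
    p95_pos: float | None
    q2_reference: str = "train_mean"  # or "eval_mean" fallback, or "undefined"
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compute_metrics(
    exp: Sequence[float],
    pred: Sequence[float],
    train_mean: float | None = None,
) -> MetricsReport:
    """Compute the full statistics battery for one prediction set."""
    exp = np.asarray(exp, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if exp.shape != pred.shape:
        raise ValueError("experimental and predicted vectors differ in length")
    n = exp.size
    if n < 2:
        raise ValueError("need at least 2 points")

    e = pred - exp
    rmse = float(np.sqrt(np.mean(e**2)))
    bias = float(np.mean(e))
    mne = float(np.min(e))
    mpe = float(np.max(e))
    undefined: list[str] = []

    if np.std(exp) < 1e-12 or np.std(pred) < 1e-12:
        r2 = None
        undefined.append("r2_zero_variance")
    else:
        r2 = float(np.corrcoef(exp, pred)[0, 1] ** 2)

    if train_mean is not None:
        ref, ref_name = float(train_mean), "train_mean"
    else:
        ref, ref_name = float(np.mean(exp)), "eval_mean"
    denom = float(np.sum((exp - ref) ** 2))
    if denom < 1e-12:
        q2 = None
        ref_name = "undefined"
        undefined.append("q2_zero_denominator")
    else:
        q2 = float(1.0 - np.sum(e**2) / denom)

    neg = e[e < 0]
    pos = e[e > 0]
    if neg.size:
        p95_neg = float(-np.percentile(np.abs(neg), 95))
    else:
        p95_neg = None
        undefined.append("p95_neg_no_negative_errors")
    if pos.size:
        p95_pos = float(np.percentile(pos, 95))
    else:
        p95_pos = None
        undefined.append("p95_pos_no_positive_errors")

    return MetricsReport(
        n=n, r2=r2, q2=q2, rmse=rmse, bias=bias, mne=mne, mpe=mpe,
        p95_neg=p95_neg, p95_pos=p95_pos, q2_reference=ref_name, undefined=undefined,
    )


def _empty_report() -> MetricsReport:
    return MetricsReport(
        n=0, r2=None, q2=None, rmse=None, bias=None, mne=None, mpe=None,
        p95_neg=None, p95_pos=None, q2_reference="undefined",
        undefined=["empty_subset"],
    )


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">{lo - 1}"
    if lo == 0:
        return f"<={hi}"
    return f"{lo}-{hi}"


def rmse_by_nha(
    records: Sequence[CuratedRecord],
    preds: Sequence[float],
    bins: Sequence[tuple[int, int | None]] = NHA_BINS,
) -> pd.DataFrame:
    """Per-size-bin rmse table over non-hydrogen atom (NHA) counts.

    Every record falls in exactly one bin; empty bins appear with n=0.
    """
    preds = np.asarray(preds, dtype=np.float64)
    if len(records) != preds.size:
        raise ValueError("records and predictions differ in length")
    rows = []
    for lo, hi in bins:
        errs = [
            preds[i] - r.logsw
            for i, r in enumerate(records)
            if r.heavy_atom_count >= lo and (hi is None or r.heavy_atom_count <= hi)
        ]
        rows.append(
            {
                "bin": _bin_label(lo, hi),
                "n": len(errs),
                "rmse": float(np.sqrt(np.mean(np.square(errs)))) if errs else np.nan,
            }
        )
    return pd.DataFrame(rows)


def is_ionizable(smiles: str) -> bool:
    """True when the structure matches any documented acid/base SMARTS."""
    mol = mol_from_smiles(smiles)
    return any(mol.HasSubstructMatch(p) for p in _IONIZABLE_PATTERNS.values())


def subset_metrics(
    records: Sequence[CuratedRecord],
    preds: Sequence[float],
    predicate: str | Callable[[CuratedRecord], bool],
    train_mean: float | None = None,
) -> MetricsReport:
    """Metrics restricted to a structure-defined subset.

    ``predicate`` may be ``"ionizable"``, ``"neutral"`` (its complement) or
    any callable on a record.  An empty subset yields an n=0 report with all
    statistics flagged undefined.
    """
    if predicate == "ionizable":
        fn = lambda r: is_ionizable(r.canonical_smiles)  # noqa: E731
    elif predicate == "neutral":
        fn = lambda r: not is_ionizable(r.canonical_smiles)  # noqa: E731
    elif callable(predicate):
        fn = predicate
    else:
        raise ValueError(f"unknown predicate {predicate!r}")
    preds = np.asarray(preds, dtype=np.float64)
    if len(records) != preds.size:
        raise ValueError("records and predictions differ in length")
    mask = [bool(fn(r)) for r in records]
    exp = [r.logsw for r, m in zip(records, mask) if m]
    sub_pred = preds[np.asarray(mask, dtype=bool)] if any(mask) else np.array([])
    if len(exp) == 0:
        return _empty_report()
    if len(exp) == 1:
        report = _empty_report()
        report.n = 1
        report.undefined = ["subset_of_one"]
        report.bias = float(sub_pred[0] - exp[0])
        report.rmse = abs(report.bias)
        return report
    return compute_metrics(exp, sub_pred, train_mean)
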