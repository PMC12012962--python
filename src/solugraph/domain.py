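"""Structure/reliability applicability domain via kNN Tanimoto distances.

A query is considered inside the model's applicability domain when it falls
within the similarity radius of at least one training compound.  The radii
are built in four steps:

1. for each training compound, the mean Tanimoto distance (1 - Jaccard of
   circular fingerprints, radius 2, 2048 bits) to its k nearest neighbors
   (default k = 12) is computed;
2. a global reference value fences those means at Q3 + 1.5*IQR;
3. each compound's base radius is its mean distance to all neighbors within
   the reference value (no such neighbor -> radius 0, an isolated compound);
4. the radius is shrunk by the compound's prediction reliability through
   ``f = 1 / (1 + w * (rel_sd + rel_dev))`` where ``rel_sd`` is the consensus
   SD over the ensemble relative to |mean prediction| and ``rel_dev`` the
   absolute deviation from experiment relative to the training-label spread
   (max - min).  ``f`` equals 1 for a perfectly reliable compound and
   decreases monotonically in both inputs; the weight w (default 1) and the
   functional form are this package's own concretization and are recorded in
   the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator

from .curation import CuratedDataset
from .ensemble import Ensemble, consensus_predict_many
from .records import StructureError, mol_from_smiles

FP_RADIUS = 2
FP_BITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    on_bits: frozenset[int]
    radius: int = FP_RADIUS
    n_bits: int = FP_BITS

    def __post_init__(self) -> None:
        if self.on_bits and not all(0 <= b < self.n_bits for b in self.on_bits):
            raise ValueError("bit index out of range")


def fingerprint(smiles: str) -> Fingerprint:
    """Circular (Morgan) substructure fingerprint, radius 2, 2048 bits."""
    mol = mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(frozenset(fp.GetOnBits()))


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """1 - Jaccard similarity of the on-bit sets; two empty sets -> 0."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 0.0
    return 1.0 - len(a.on_bits & b.on_bits) / union


def _distance_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Dense pairwise Tanimoto distance matrix via bit-matrix algebra."""
    n = len(fps)
    M = np.zeros((n, fps[0].n_bits), dtype=np.float32)
    for i, fp in enumerate(fps):
        if fp.on_bits:
            M[i, list(fp.on_bits)] = 1.0
    inter = M @ M.T
    counts = M.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-12), 1.0)
    return (1.0 - sim).astype(np.float64)


def mean_knn_distances(fps: Sequence[Fingerprint], k: int) -> np.ndarray:
    """Mean Tanimoto distance of each compound to its k nearest neighbors
    (self excluded; ties broken by compound index)."""
    n = len(fps)
    if k >= n:
        raise ValueError(f"k={k} must be < number of compounds ({n})")
    D = _distance_matrix(fps)
    np.fill_diagonal(D, np.inf)
    out = np.empty(n)
    for i in range(n):
        idx = np.argsort(D[i], kind="stable")[:k]  # stable: index-order ties
        out[i] = D[i, idx].mean()
    return out


@dataclass
class ADModel:
    k: int
    fingerprints: list[Fingerprint]
    mean_knn_dist: np.ndarray
    reference_value: float
    base_radius: np.ndarray
    corrected_radius: np.ndarray
    correction_inputs: pd.DataFrame  # per-compound rel_sd, rel_dev, factor
    correction_weight: float = 1.0
    fence: str = "Q3 + 1.5*IQR of mean kNN distances"
    correction_form: str = "1 / (1 + w*(rel_sd + rel_dev))"
    fp_params: dict = field(default_factory=lambda: {"radius": FP_RADIUS, "n_bits": FP_BITS})

    def save(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "reference_value": self.reference_value,
            "correction_weight": self.correction_weight,
            "fence": self.fence,
            "correction_form": self.correction_form,
            "fp_params": self.fp_params,
            "mean_knn_dist": self.mean_knn_dist.tolist(),
            "base_radius": self.base_radius.tolist(),
            "corrected_radius": self.corrected_radius.tolist(),
            "correction_inputs": self.correction_inputs.to_dict(orient="list"),
            "fingerprints": [sorted(fp.on_bits) for fp in self.fingerprints],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ADModel":
        d = json.loads(Path(path).read_text())
        fps = [
            Fingerprint(frozenset(bits), d["fp_params"]["radius"], d["fp_params"]["n_bits"])
            for bits in d["fingerprints"]
        ]
        return cls(
            k=int(d["k"]),
            fingerprints=fps,
            mean_knn_dist=np.array(d["mean_knn_dist"]),
            reference_value=float(d["reference_value"]),
            base_radius=np.array(d["base_radius"]),
            corrected_radius=np.array(d["corrected_radius"]),
            correction_inputs=pd.DataFrame(d["correction_inputs"]),
            correction_weight=float(d["correction_weight"]),
            fence=d["fence"],
            correction_form=d["correction_form"],
            fp_params=d["fp_params"],
        )


@dataclass
class ADResult:
    inside: bool
    covering_count: int
    min_distance: float

    def __post_init__(self) -> None:
        if self.inside != (self.covering_count >= 1):
            raise ValueError("inside must hold exactly when covering_count >= 1")


def build_domain(
    train: CuratedDataset,
    ensemble: Ensemble | None,
    k: int = 12,
    correction_weight: float = 1.0,
) -> ADModel:
    """Build the reliability-corrected kNN-Tanimoto domain from the training set.

    With ``ensemble=None`` the correction step is skipped (factor 1 for every
    compound), leaving the purely structural domain.
    """
    records = list(train)
    n = len(records)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be < number of training compounds ({n})")
    fps = [fingerprint(r.canonical_smiles) for r in records]
    knn = mean_knn_distances(fps, k)
    q1, q3 = np.percentile(knn, [25, 75])
    reference = float(q3 + 1.5 * (q3 - q1))

    D = _distance_matrix(fps)
    np.fill_diagonal(D, np.inf)
    base = np.empty(n)
    for i in range(n):
        near = D[i][D[i] <= reference]
        base[i] = near.mean() if near.size else 0.0  # isolated compound

    if ensemble is not None:
        preds = consensus_predict_many(ensemble, [r.canonical_smiles for r in records])
        labels = np.array([r.logsw for r in records])
        spread = float(labels.max() - labels.min()) or 1.0
        mean = preds["mean"].to_numpy()
        sd = preds["sd"].to_numpy()
        rel_sd = sd / np.maximum(np.abs(mean), 1e-6)
        rel_dev = np.abs(mean - labels) / spread
    else:
        rel_sd = np.zeros(n)
        rel_dev = np.zeros(n)
    factor = 1.0 / (1.0 + correction_weight * (rel_sd + rel_dev))
    corrected = base * factor

    inputs = pd.DataFrame(
        {
            "inchikey": [r.inchikey for r in records],
            "rel_sd": rel_sd,
            "rel_dev": rel_dev,
            "factor": factor,
        }
    )
    return ADModel(
        k=k,
        fingerprints=fps,
        mean_knn_dist=knn,
        reference_value=reference,
        base_radius=base,
        corrected_radius=corrected,
        correction_inputs=inputs,
        correction_weight=correction_weight,
    )


def classify(
    ad: ADModel, query_smiles: str, radius_scale: float = 1.0
) -> ADResult:
    """Decide domain membership for one query structure.

    Inside iff some training compound's (scaled) corrected radius covers the
    query's Tanimoto distance to it.  Deterministic and independent of
    training-compound order.
    """
    qfp = fingerprint(query_smiles)
    dists = np.array([tanimoto_distance(fp, qfp) for fp in ad.fingerprints])
    covered = dists <= ad.corrected_radius * radius_scale
    return ADResult(
        inside=bool(covered.any()),
        covering_count=int(covered.sum()),
        min_distance=float(dists.min()),
    )


def classify_many(
    ad: ADModel, smiles_list: Sequence[str], radius_scale: float = 1.0
) -> pd.DataFrame:
    rows = []
    for smi in smiles_list:
        try:
            res = classify(ad, smi, radius_scale)
            rows.append(
                {"smiles": smi, "status": "ok", "inside": res.inside,
                 "covering_count": res.covering_count, "min_distance": res.min_distance}
            )
        except (StructureError, ValueError):
            rows.append(
                {"smiles": smi, "status": "failed", "inside": False,
                 "covering_count": 0, "min_distance": np.nan}
            )
    return pd.DataFrame(rows)


def sweep_k(
    train: CuratedDataset,
    ensemble: Ensemble | None,
    test: CuratedDataset,
    ks: Sequence[int] = (1, 3, 6, 9, 12, 15, 20),
    correction_weight: float = 1.0,
) -> pd.DataFrame:
    """Report test-set coverage for a range of k values (no auto-selection)."""
    rows = []
    for k in ks:
        ad = build_domain(train, ensemble, k=k, correction_weight=correction_weight)
        res = classify_many(ad, [r.canonical_smiles for r in test])
        rows.append(
            {"k": k, "coverage": float(res["inside"].mean()),
             "reference_value": ad.reference_value}
        )
    return pd.DataFrame(rows)
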