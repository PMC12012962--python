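"""Fixed-test fivefold splitting, ensemble training and consensus prediction.

The dataset is first stripped of a common 10% test set; the remaining
chemicals are distributed five times into 70%/20% training/validation sets
such that every non-test chemical lands in at least one validation set.
Five networks are trained — each on its fold's *augmented* training parents,
validated on unaugmented parents — and combined into a consensus model: the
prediction is the mean of the five outputs and their population standard
deviation (divisor 5) serves as a reliability proxy, banded as

=================  ==========================
SD (log units)     reliability
=================  ==========================
0 <= SD <= 0.1     high
0.1 < SD <= 0.3    good
0.3 < SD <= 0.5    moderate
SD > 0.5           low
=================  ==========================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .augmentation import AugmentationConfig, augment_dataset, derive_seed
from .curation import CuratedDataset, CuratedRecord
from .featurize import FeatureSpec, batch_graphs, featurize
from .gcn import GCNConfig, TrainedModel, forward, predict_records, train
from .metrics import MetricsReport, compute_metrics
from .records import StructureError


class ReliabilityClass(str, Enum):
    high = "high"
    good = "good"
    moderate = "moderate"
    low = "low"


#: Half-open SD bins (lower exclusive, upper inclusive), in log units.
RELIABILITY_BINS: tuple[tuple[float, float, ReliabilityClass], ...] = (
    (0.0, 0.1, ReliabilityClass.high),
    (0.1, 0.3, ReliabilityClass.good),
    (0.3, 0.5, ReliabilityClass.moderate),
    (0.5, float("inf"), ReliabilityClass.low),
)


def assign_reliability(sd: float) -> ReliabilityClass:
    """Band an ensemble SD into a reliability class (bins open below,
    closed above; SD exactly 0 counts as high)."""
    if sd < 0:
        raise ValueError("standard deviation cannot be negative")
    for lo, hi, label in RELIABILITY_BINS:
        if sd <= hi and (sd > lo or lo == 0.0):
            return label
    return ReliabilityClass.low


@dataclass
class SplitPlan:
    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]]  # (train_ids, valid_ids)
    rng_seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def check_invariants(self, all_ids: Sequence[str]) -> None:
        """Raise if any structural invariant of the plan is violated."""
        all_set = set(all_ids)
        test = set(self.test_ids)
        if not test <= all_set:
            raise AssertionError("test ids outside dataset")
        non_test = all_set - test
        covered: set[str] = set()
        for train_ids, valid_ids in self.folds:
            tr, va = set(train_ids), set(valid_ids)
            if tr & test or va & test:
                raise AssertionError("fold overlaps the test set")
            if tr & va:
                raise AssertionError("train/valid overlap within a fold")
            if tr | va != non_test:
                raise AssertionError("fold does not cover all non-test ids")
            covered |= va
        if covered != non_test:
            raise AssertionError("some chemical never enters a validation set")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rng_seed": self.rng_seed,
                    "test_ids": self.test_ids,
                    "folds": [
                        {"train_ids": tr, "valid_ids": va} for tr, va in self.folds
                    ],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            test_ids=list(d["test_ids"]),
            folds=[(list(f["train_ids"]), list(f["valid_ids"])) for f in d["folds"]],
            rng_seed=int(d["rng_seed"]),
        )


def make_splits(
    dataset: CuratedDataset | Sequence[str],
    rng_seed: int = 0,
    n_folds: int = 5,
    test_fraction: float = 0.10,
    valid_fraction: float = 0.20,
) -> SplitPlan:
    """Build the fixed-test n-fold split plan.

    10% of chemicals (rounded) form a shared test set.  Each fold assigns
    20% to validation and the rest to training; a seeded round-robin pass
    guarantees every non-test chemical is validated at least once.
    Deterministic for a seed.
    """
    ids = list(dataset.ids) if isinstance(dataset, CuratedDataset) else list(dataset)
    n = len(ids)
    if n < 10:
        raise ValueError("dataset too small to split (need >= 10 chemicals)")
    n_test = int(round(test_fraction * n))
    n_valid = int(round(valid_fraction * n))
    if n_folds * n_valid < n - n_test:
        raise ValueError("validation sets too small to cover every chemical")

    rng = np.random.default_rng(rng_seed)
    order = [ids[i] for i in rng.permutation(n)]
    test_ids = sorted(order[:n_test])
    non_test = order[n_test:]

    # round-robin guarantee: chemical i must validate in fold i mod n_folds
    must: list[list[str]] = [[] for _ in range(n_folds)]
    for i, cid in enumerate(non_test):
        must[i % n_folds].append(cid)

    folds: list[tuple[list[str], list[str]]] = []
    for f in range(n_folds):
        valid = list(must[f])
        pool = [cid for cid in non_test if cid not in set(valid)]
        extra = max(0, n_valid - len(valid))
        if extra:
            pick = rng.permutation(len(pool))[:extra]
            valid.extend(pool[i] for i in sorted(pick))
        valid_set = set(valid)
        train_ids = sorted(cid for cid in non_test if cid not in valid_set)
        folds.append((train_ids, sorted(valid)))
    return SplitPlan(test_ids=test_ids, folds=folds, rng_seed=rng_seed)


def stratification_report(
    dataset: CuratedDataset, plan: SplitPlan, n_bins: int = 6
) -> pd.DataFrame:
    """Label-distribution histogram per subset (post-hoc homogeneity check)."""
    by_id = {r.inchikey: r.logsw for r in dataset}
    values = np.array(list(by_id.values()))
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf

    def hist(ids: Sequence[str]) -> np.ndarray:
        v = np.array([by_id[i] for i in ids])
        counts, _ = np.histogram(v, bins=edges)
        return counts / max(1, len(v))

    rows = {"test": hist(plan.test_ids)}
    for f, (tr, va) in enumerate(plan.folds):
        rows[f"fold{f + 1}_train"] = hist(tr)
        rows[f"fold{f + 1}_valid"] = hist(va)
    return pd.DataFrame(rows).T


@dataclass
class EnsemblePrediction:
    mean: float
    sd: float  # population SD over the member outputs (divisor = n_members)
    per_model: list[float]
    reliability: ReliabilityClass

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class Ensemble:
    models: list[TrainedModel]
    plan: SplitPlan
    validation_reports: list[MetricsReport] = field(default_factory=list)
    test_reports: list[MetricsReport] = field(default_factory=list)
    consensus_test_report: MetricsReport | None = None
    sd_convention: str = "population (divisor = number of models)"

    @property
    def n_models(self) -> int:
        return len(self.models)


def train_ensemble(
    plan: SplitPlan,
    dataset: CuratedDataset,
    gcn_cfg: GCNConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
    feature_spec: FeatureSpec | None = None,
    rng_seed: int = 0,
) -> Ensemble:
    """Train one model per fold on augmented parents; evaluate each fold.

    Only training parents are augmented; validation and test predictions use
    each parent's canonical structure.  Per-fold seeds derive from
    ``rng_seed`` so the ensemble is reproducible end to end.
    """
    gcn_cfg = gcn_cfg or GCNConfig()
    aug_cfg = aug_cfg or AugmentationConfig()
    spec = feature_spec or FeatureSpec()
    by_id = {r.inchikey: r for r in dataset}
    test_records = [by_id[i] for i in plan.test_ids]
    test_truth = np.array([r.logsw for r in test_records])

    models: list[TrainedModel] = []
    valid_reports: list[MetricsReport] = []
    test_reports: list[MetricsReport] = []
    per_model_test: list[np.ndarray] = []
    for f, (train_ids, valid_ids) in enumerate(plan.folds):
        train_parents = [by_id[i] for i in train_ids]
        valid_parents = [by_id[i] for i in valid_ids]
        fold_seed = derive_seed(rng_seed, f"fold{f}")
        examples, _log = augment_dataset(
            train_parents, aug_cfg, rng_seed=derive_seed(rng_seed, f"aug{f}")
        )
        cfg = GCNConfig.from_dict({**gcn_cfg.to_dict(), "rng_seed": fold_seed})
        model = train(examples, valid_parents, cfg, spec)
        models.append(model)
        train_mean = float(np.mean([p.logsw for p in train_parents]))
        vp = predict_records(model, valid_parents)
        valid_reports.append(
            compute_metrics([p.logsw for p in valid_parents], vp, train_mean)
        )
        tp = predict_records(model, test_records)
        per_model_test.append(tp)
        test_reports.append(compute_metrics(test_truth, tp, train_mean))

    consensus = np.mean(per_model_test, axis=0)
    overall_train_mean = float(
        np.mean([r.logsw for r in dataset if r.inchikey not in set(plan.test_ids)])
    )
    consensus_report = (
        compute_metrics(test_truth, consensus, overall_train_mean)
        if len(test_records) >= 2
        else None
    )
    return Ensemble(
        models=models,
        plan=plan,
        validation_reports=valid_reports,
        test_reports=test_reports,
        consensus_test_report=consensus_report,
    )


def consensus_predict(
    ensemble: Ensemble | Sequence[TrainedModel], smiles: str
) -> EnsemblePrediction:
    """Mean/SD consensus over the member models for one structure.

    Any member failing on the input fails the whole prediction
    (:class:`~solugraph.records.StructureError` propagates).
    """
    models = ensemble.models if isinstance(ensemble, Ensemble) else list(ensemble)
    graph = featurize(smiles, models[0].feature_spec)
    values = [float(forward(batch_graphs([graph]), m, mode="infer")[0]) for m in models]
    arr = np.array(values)
    mean = float(arr.mean())
    sd = float(arr.std())  # population SD, divisor n
    return EnsemblePrediction(mean, sd, values, assign_reliability(sd))


def consensus_predict_many(
    ensemble: Ensemble | Sequence[TrainedModel], smiles_list: Sequence[str]
) -> pd.DataFrame:
    """Vectorized consensus prediction; bad rows get status ``failed``."""
    models = ensemble.models if isinstance(ensemble, Ensemble) else list(ensemble)
    spec = models[0].feature_spec
    graphs = []
    for smi in smiles_list:
        try:
            graphs.append(featurize(smi, spec))
        except (StructureError, ValueError):
            graphs.append(None)
    good = [g for g in graphs if g is not None]
    if good:
        batch = batch_graphs(good)
        outputs = np.stack([forward(batch, m, mode="infer") for m in models])
    rows = []
    j = 0
    for smi, g in zip(smiles_list, graphs):
        if g is None:
            rows.append({"smiles": smi, "status": "failed", "mean": np.nan,
                         "sd": np.nan, "reliability": ""})
            continue
        vals = outputs[:, j]
        j += 1
        sd = float(vals.std())
        row = {
            "smiles": smi,
            "status": "ok",
            "mean": float(vals.mean()),
            "sd": sd,
            "reliability": assign_reliability(sd).value,
        }
        row.update({f"per_model_{k + 1}": float(v) for k, v in enumerate(vals)})
        rows.append(row)
    return pd.DataFrame(rows)
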