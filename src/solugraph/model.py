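"""High-level modelling interface: build, fit, inspect, predict.

:class:`ConsensusSolubilityModel` wraps the whole pipeline — splitting,
augmentation, fivefold training, consensus statistics — behind a
construct/fit interface; :meth:`fit` returns a
:class:`ConsensusSolubilityResults` carrying the trained ensemble, the
per-fold and consensus evaluation statistics, and prediction /
applicability-domain helpers.

    >>> dataset = make_synthetic_dataset(SyntheticSpec(n=1000))
    >>> model = ConsensusSolubilityModel(dataset)
    >>> results = model.fit(seed=1)
    >>> print(results.summary())
    >>> results.predict(["CCO", "c1ccccc1O"])
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augmentation import AugmentationConfig
from .curation import CuratedDataset
from .domain import ADModel, build_domain, classify_many
from .ensemble import (
    Ensemble,
    SplitPlan,
    consensus_predict_many,
    make_splits,
    train_ensemble,
)
from .featurize import FeatureSpec
from .gcn import GCNConfig
from .metrics import MetricsReport, compute_metrics


@dataclass
class ConsensusSolubilityModel:
    """A fivefold consensus graph-convolutional solubility model.

    Parameters
    ----------
    dataset
        Curated chemicals with resolved log Sw labels (mol/L, log10).
    gcn_config, augmentation, feature_spec
        Network hyperparameters, training-set augmentation settings and the
        featurization contract.  Defaults follow the package's reference
        configuration (two conv blocks of 64/128 units, lr 5e-4, dropout
        0.1, L1 loss, 130 epochs; full variant+tautomer augmentation).
    n_folds
        Number of train/validation rotations over the non-test chemicals.
    """

    dataset: CuratedDataset
    gcn_config: GCNConfig = field(default_factory=GCNConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    n_folds: int = 5

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        smiles_col: str = "smiles",
        logsw_col: str = "logS",
        **kwargs,
    ) -> "ConsensusSolubilityModel":
        """Build from a DataFrame of SMILES and labels (curates trivially:
        standardization + merge, no multi-value resolution)."""
        from .curation import run_curation
        from .records import MoleculeRecord

        records = [
            MoleculeRecord(str(i), str(row[smiles_col]), [(float(row[logsw_col]), "df")])
            for i, row in df.iterrows()
        ]
        dataset, _log, _ = run_curation(records)
        return cls(dataset, **kwargs)

    def fit(self, seed: int = 0) -> "ConsensusSolubilityResults":
        """Split, augment, train the fold models and assemble the consensus."""
        plan = make_splits(self.dataset, rng_seed=seed, n_folds=self.n_folds)
        ens = train_ensemble(
            plan,
            self.dataset,
            gcn_cfg=self.gcn_config,
            aug_cfg=self.augmentation,
            feature_spec=self.feature_spec,
            rng_seed=seed,
        )
        return ConsensusSolubilityResults(model=self, ensemble=ens, plan=plan, seed=seed)


@dataclass
class ConsensusSolubilityResults:
    """Fitted ensemble with its evaluation statistics."""

    model: ConsensusSolubilityModel
    ensemble: Ensemble
    plan: SplitPlan
    seed: int

    @property
    def fold_validation_reports(self) -> list[MetricsReport]:
        return self.ensemble.validation_reports

    @property
    def fold_test_reports(self) -> list[MetricsReport]:
        return self.ensemble.test_reports

    @property
    def consensus_test_report(self) -> MetricsReport | None:
        return self.ensemble.consensus_test_report

    def predict(self, smiles_list) -> pd.DataFrame:
        """Consensus predictions (mean, SD, reliability class, per-model)."""
        return consensus_predict_many(self.ensemble, smiles_list)

    def applicability_domain(self, k: int = 12, fold: int = 0) -> ADModel:
        """Reliability-corrected kNN-Tanimoto domain over one fold's
        training chemicals."""
        by_id = {r.inchikey: r for r in self.model.dataset}
        train_ids = self.plan.folds[fold][0]
        train_ds = CuratedDataset([by_id[i] for i in train_ids])
        return build_domain(train_ds, self.ensemble, k=k)

    def test_coverage(self, ad: ADModel) -> float:
        """Fraction of the shared test set inside the applicability domain."""
        by_id = {r.inchikey: r for r in self.model.dataset}
        smiles = [by_id[i].canonical_smiles for i in self.plan.test_ids]
        res = classify_many(ad, smiles)
        return float(res["inside"].mean())

    def summary(self) -> str:
        """Text table of per-fold and consensus statistics."""
        lines = [
            "Consensus graph-convolutional solubility model",
            "=" * 62,
            f"chemicals: {len(self.model.dataset)}   folds: {self.plan.n_folds}"
            f"   test set: {len(self.plan.test_ids)}   seed: {self.seed}",
            "",
            f"{'model':<10}{'set':<12}{'n':>6}{'r2':>8}{'q2':>8}{'rmse':>8}",
            "-" * 62,
        ]

        def fmt(x):
            return f"{x:8.3f}" if x is not None else f"{'--':>8}"

        for i, (vr, tr) in enumerate(
            zip(self.ensemble.validation_reports, self.ensemble.test_reports)
        ):
            lines.append(
                f"{'GNN' + str(i + 1):<10}{'validation':<12}{vr.n:>6}"
                f"{fmt(vr.r2)}{fmt(vr.q2)}{fmt(vr.rmse)}"
            )
            lines.append(
                f"{'':<10}{'test':<12}{tr.n:>6}{fmt(tr.r2)}{fmt(tr.q2)}{fmt(tr.rmse)}"
            )
        cr = self.consensus_test_report
        if cr is not None:
            lines.append("-" * 62)
            lines.append(
                f"{'consensus':<10}{'test':<12}{cr.n:>6}{fmt(cr.r2)}{fmt(cr.q2)}{fmt(cr.rmse)}"
            )
            lines.append(
                f"{'':<10}{'':<12}{'':>6}  bias {cr.bias:+.3f}  mne {cr.mne:+.2f}"
                f"  mpe {cr.mpe:+.2f}"
            )
        return "\n".join(lines)

    def reliability_table(self) -> pd.DataFrame:
        """Test-set error grouped by consensus-SD reliability bin."""
        from .ensemble import assign_reliability

        by_id = {r.inchikey: r for r in self.model.dataset}
        test = [by_id[i] for i in self.plan.test_ids]
        preds = consensus_predict_many(self.ensemble, [r.canonical_smiles for r in test])
        truth = np.array([r.logsw for r in test])
        err = preds["mean"].to_numpy() - truth
        sd = preds["sd"].to_numpy()
        rows = []
        for label in ("high", "good", "moderate", "low"):
            mask = np.array([assign_reliability(s).value == label for s in sd])
            rows.append(
                {
                    "reliability": label,
                    "n": int(mask.sum()),
                    "rmse": float(np.sqrt(np.mean(err[mask] ** 2))) if mask.any() else np.nan,
                    "mean_abs_error": float(np.mean(np.abs(err[mask]))) if mask.any() else np.nan,
                    "max_abs_error": float(np.max(np.abs(err[mask]))) if mask.any() else np.nan,
                }
            )
        return pd.DataFrame(rows)
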