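import numpy as np
import pytest

from solugraph.augmentation import AugmentationConfig, VariantKind
from solugraph.ensemble import (
    Ensemble,
    EnsemblePrediction,
    ReliabilityClass,
    SplitPlan,
    assign_reliability,
    consensus_predict,
    consensus_predict_many,
    make_splits,
    stratification_report,
    train_ensemble,
)
from solugraph.gcn import GCNConfig


class TestAssignReliability:
    @pytest.mark.parametrize(
        "sd,expected",
        [
            (0.0, "high"),
            (0.05, "high"),
            (0.1, "high"),  # upper edges belong to the lower band
            (0.100001, "good"),
            (0.25, "good"),
            (0.3, "good"),
            (0.45, "moderate"),
            (0.5, "moderate"),
            (0.6, "low"),
            (5.0, "low"),
        ],
    )
    def test_banding(self, sd, expected):
        assert assign_reliability(sd).value == expected

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            assign_reliability(-0.01)


class TestMakeSplits:
    @pytest.mark.parametrize("n", [10, 37, 300])
    def test_invariants_hold(self, n, rng):
        ids = [f"id{i}" for i in range(n)]
        plan = make_splits(ids, rng_seed=3)
        plan.check_invariants(ids)

    def test_proportions_at_reference_scale(self):
        ids = [f"id{i}" for i in range(9800)]
        plan = make_splits(ids, rng_seed=0)
        assert len(plan.test_ids) == 980
        for train_ids, valid_ids in plan.folds:
            assert len(train_ids) == 6860
            assert len(valid_ids) == 1960

    def test_small_dataset_rounding(self):
        plan = make_splits([f"id{i}" for i in range(10)], rng_seed=1)
        assert len(plan.test_ids) == 1
        for tr, va in plan.folds:
            assert len(tr) == 7 and len(va) == 2

    def test_validation_union_covers_everything(self):
        ids = [f"id{i}" for i in range(53)]
        plan = make_splits(ids, rng_seed=9)
        covered = set()
        for _, va in plan.folds:
            covered |= set(va)
        assert covered == set(ids) - set(plan.test_ids)

    def test_deterministic_per_seed(self):
        ids = [f"id{i}" for i in range(64)]
        a = make_splits(ids, rng_seed=4)
        b = make_splits(ids, rng_seed=4)
        assert a.test_ids == b.test_ids and a.folds == b.folds
        c = make_splits(ids, rng_seed=5)
        assert a.folds != c.folds

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_splits([f"id{i}" for i in range(9)], rng_seed=0)

    def test_json_roundtrip(self, tmp_path):
        plan = make_splits([f"id{i}" for i in range(20)], rng_seed=2)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = SplitPlan.from_json(path)
        assert back.test_ids == plan.test_ids and back.folds == plan.folds

    def test_stratification_report_rows(self, tiny_dataset):
        plan = make_splits(tiny_dataset, rng_seed=0)
        report = stratification_report(tiny_dataset, plan)
        assert report.shape[0] == 1 + 2 * plan.n_folds
        assert np.allclose(report.sum(axis=1), 1.0)


class TestConsensus:
    def test_population_sd_hand_computation(self):
        values = [-3.0, -3.1, -2.9, -3.0, -3.0]
        arr = np.array(values)
        sd = float(arr.std())  # divisor 5
        assert sd == pytest.approx(0.0632455, abs=1e-6)
        pred = EnsemblePrediction(float(arr.mean()), sd, values, assign_reliability(sd))
        assert pred.mean == pytest.approx(-3.0)
        assert pred.reliability == ReliabilityClass.high

    def test_sd_quarter_is_good(self):
        assert assign_reliability(0.25) == ReliabilityClass.good

    def test_identical_models_give_sd_zero(self, tiny_dataset, tiny_gcn_config):
        from solugraph.gcn import train as train_one
        from solugraph.augmentation import AugmentedExample

        examples = [
            AugmentedExample(r.canonical_smiles, r.inchikey, r.logsw, VariantKind.canonical)
            for r in tiny_dataset
        ]
        model = train_one(examples, [], tiny_gcn_config)
        ens = Ensemble(models=[model] * 5, plan=SplitPlan([], [], 0))
        pred = consensus_predict(ens, "CCO")
        assert pred.sd == 0.0
        assert pred.reliability == ReliabilityClass.high
        assert pred.mean == pytest.approx(pred.per_model[0])


@pytest.fixture(scope="module")
def trained_tiny_ensemble(small_dataset):
    plan = make_splits(small_dataset, rng_seed=2)
    cfg = GCNConfig(layer_widths=(8, 12), dense_width=10, epochs=8, rng_seed=0)
    aug = AugmentationConfig(include_kinds=frozenset({VariantKind.canonical,
                                                      VariantKind.kekulized,
                                                      VariantKind.explicit_h}))
    ens = train_ensemble(plan, small_dataset, cfg, aug, rng_seed=2)
    return plan, ens


class TestTrainEnsemble:
    def test_artifact_counts(self, trained_tiny_ensemble):
        plan, ens = trained_tiny_ensemble
        assert ens.n_models == 5
        assert len(ens.validation_reports) == 5
        assert len(ens.test_reports) == 5
        assert ens.consensus_test_report is not None

    def test_fold_validation_rmse_differ(self, trained_tiny_ensemble):
        _, ens = trained_tiny_ensemble
        rmses = [r.rmse for r in ens.validation_reports]
        assert len(set(np.round(rmses, 6))) > 1  # fold compositions differ

    def test_test_set_predicted_once_per_parent(self, trained_tiny_ensemble):
        plan, ens = trained_tiny_ensemble
        assert all(r.n == len(plan.test_ids) for r in ens.test_reports)

    def test_consensus_prediction_columns(self, trained_tiny_ensemble, small_dataset):
        _, ens = trained_tiny_ensemble
        df = consensus_predict_many(ens, ["CCO", "bad_smiles(", "c1ccccc1"])
        assert list(df["status"]) == ["ok", "failed", "ok"]
        ok = df[df.status == "ok"]
        assert {"mean", "sd", "reliability", "per_model_1", "per_model_5"} <= set(df.columns)
        assert (ok["sd"] >= 0).all()
        mean_check = ok[[f"per_model_{i}" for i in range(1, 6)]].mean(axis=1)
        assert np.allclose(ok["mean"], mean_check, atol=1e-6)
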