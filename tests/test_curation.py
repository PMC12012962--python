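import pytest

from solugraph.curation import (
    CurationConfig,
    NeedsReferenceModelError,
    ResolutionRule,
    flag_outliers,
    resolve_multivalue,
    run_curation,
)
from solugraph.records import MoleculeRecord


def _rec(rid, smiles, logsw):
    return MoleculeRecord(rid, smiles, [(logsw, "test")])


class TestResolveMultivalue:
    def test_single_value_identity(self):
        assert resolve_multivalue([-3.2]) == (-3.2, ResolutionRule.single_value)

    def test_two_values_use_reference(self):
        value, rule = resolve_multivalue([-3.0, -4.2], reference_prediction=-4.0)
        assert value == -4.2
        assert rule == ResolutionRule.reference_prediction_selection

    def test_two_equal_values_collapse_to_single(self):
        assert resolve_multivalue([-0.2, -0.2]) == (-0.2, ResolutionRule.single_value)

    def test_two_values_without_reference_is_explicit_error(self):
        with pytest.raises(NeedsReferenceModelError):
            resolve_multivalue([-3.0, -4.2])

    def test_two_value_tie_prefers_less_soluble(self):
        value, _ = resolve_multivalue([-3.0, -5.0], reference_prediction=-4.0)
        assert value == -5.0

    def test_three_values_nearest_mean(self):
        value, rule = resolve_multivalue([-3.0, -3.1, -5.0])
        assert value == -3.1  # mean -3.7; -3.1 is nearest
        assert rule == ResolutionRule.mean_sd_selection

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolve_multivalue([])


class TestFlagOutliers:
    def test_thresholding_is_strict(self, small_dataset):
        records = list(small_dataset)[:3]
        preds = {r.inchikey: r.logsw for r in records}
        preds[records[0].inchikey] = records[0].logsw - 1.2  # deviation 1.2
        preds[records[1].inchikey] = records[1].logsw + 0.9  # deviation 0.9
        preds[records[2].inchikey] = records[2].logsw + 1.0  # exactly threshold
        report = flag_outliers(records, preds, threshold=1.0)
        assert [e.inchikey for e in report.entries] == [records[0].inchikey]
        assert report.entries[0].deviation == pytest.approx(1.2)

    def test_empty_dataset(self):
        assert len(flag_outliers([], {})) == 0

    def test_missing_prediction_names_record(self, small_dataset):
        records = list(small_dataset)[:2]
        with pytest.raises(KeyError) as err:
            flag_outliers(records, {records[0].inchikey: -1.0})
        assert records[1].inchikey in str(err.value)


def _toy_records():
    """12 rows: 2 multi-fragment, 1 carbon-free, 1 too large, 1 miscible, 7 clean."""
    rows = [
        _rec("mix1", "CCO.CCO", -1.0),
        _rec("mix2", "c1ccccc1.CC", -2.0),
        _rec("inorg", "OS(=O)(=O)O", -0.5),  # sulfuric acid: no carbon
        _rec("big", "C" * 66, -2.0),  # alkane, molar mass > 900
        _rec("misc", "CO", 0.6),  # above the miscibility cutoff
    ]
    clean = ["CCO", "CCC", "CCCC", "c1ccccc1", "Oc1ccccc1", "CCN", "CC(=O)O"]
    rows += [_rec(f"ok{i}", smi, -1.5 - i) for i, smi in enumerate(clean)]
    return rows


class TestRunCuration:
    def test_toy_counts(self):
        dataset, log, _ = run_curation(_toy_records())
        assert len(dataset) == 7
        assert log.removals == {
            "multi_fragment": 2,
            "inorganic": 1,
            "too_large": 1,
            "miscible": 1,
        }

    def test_duplicate_merge(self):
        rows = [_rec("a", "CCO", -0.2), _rec("b", "OCC", -0.2)]
        dataset, log, _ = run_curation(rows)
        assert len(dataset) == 1
        assert dataset.records[0].logsw == -0.2
        assert log.removals == {"merged_duplicate": 1}
        assert sorted(dataset.records[0].source_ids) == ["a", "b"]

    def test_empty_input(self):
        dataset, log, _ = run_curation([])
        assert len(dataset) == 0
        assert log.n_input == 0 and log.removals == {}

    def test_row_conservation(self):
        rows = _toy_records() + [_rec("dup", "OCC", -1.5)]  # merges with ok0 (CCO)
        _, log, _ = run_curation(
            rows, reference_model=lambda s: -2.0, cfg=CurationConfig()
        )
        assert log.n_input == log.n_output + sum(log.removals.values())

    def test_idempotent_on_curated_output(self):
        dataset, _, _ = run_curation(_toy_records())
        again, log2, _ = run_curation(dataset.to_molecule_records())
        assert len(again) == len(dataset)
        assert {r.inchikey for r in again} == {r.inchikey for r in dataset}
        assert {r.inchikey: r.logsw for r in again} == {
            r.inchikey: r.logsw for r in dataset
        }
        assert sum(log2.removals.values()) == 0

    def test_invalid_structures_counted(self):
        rows = [_rec("bad", "q((", -1.0), _rec("ok", "CCO", -1.0)]
        dataset, log, _ = run_curation(rows)
        assert len(dataset) == 1
        assert log.removals == {"invalid_structure": 1}

    def test_curated_respects_cutoffs(self, small_dataset):
        dataset, _, _ = run_curation(small_dataset.to_molecule_records())
        assert all(r.logsw <= 0.50 for r in dataset)
        assert all(r.molar_mass <= 900 for r in dataset)

    def test_two_value_conflict_with_reference_model(self):
        rows = [_rec("a", "CCO", -3.0), _rec("b", "OCC", -4.2)]
        dataset, log, _ = run_curation(rows, reference_model=lambda s: -4.0)
        assert dataset.records[0].logsw == -4.2
        assert log.resolutions == {"reference_prediction_selection": 1}

    def test_two_value_conflict_without_reference_raises(self):
        rows = [_rec("a", "CCO", -3.0), _rec("b", "OCC", -4.2)]
        with pytest.raises(NeedsReferenceModelError):
            run_curation(rows)

    def test_two_value_mean_fallback_when_configured(self):
        rows = [_rec("a", "CCO", -3.0), _rec("b", "OCC", -4.2)]
        cfg = CurationConfig(two_value_fallback="mean")
        dataset, _, _ = run_curation(rows, cfg=cfg)
        assert dataset.records[0].logsw in (-3.0, -4.2)

    def test_annotations_remove_and_replace(self):
        rows = [_rec("a", "CCO", -1.0), _rec("b", "CCC", -2.0), _rec("c", "CCCC", -3.0)]
        cfg = CurationConfig(
            annotations={"a": ("remove", None), "b": ("replace", -2.5)}
        )
        dataset, log, _ = run_curation(rows, cfg=cfg)
        assert len(dataset) == 2
        assert log.removals == {"annotation_removed": 1}
        by_smiles = {r.canonical_smiles: r for r in dataset}
        assert by_smiles["CCC"].logsw == -2.5

    def test_exclusion_list_honored(self):
        rows = [_rec("keep", "CCO", -1.0), _rec("drop", "CCC", -2.0)]
        cfg = CurationConfig(exclusion_ids=frozenset({"drop"}))
        dataset, log, _ = run_curation(rows, cfg=cfg)
        assert len(dataset) == 1
        assert log.removals == {"excluded_list": 1}

    def test_outlier_flagging_is_advisory(self, small_dataset):
        records = small_dataset.to_molecule_records()[:20]
        dataset, log, report = run_curation(records, reference_model=lambda s: 0.0)
        # a constant predictor at 0.0 makes most records outliers, none removed
        assert len(dataset) == len(report.entries) or len(report.entries) <= len(dataset)
        assert log.n_output == len(dataset)
        flagged = {e.inchikey for e in report.entries}
        for rec in dataset:
            if rec.inchikey in flagged:
                assert "outlier_gt_1log" in [f.value for f in rec.curation_flags]
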