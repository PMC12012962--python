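import numpy as np
import pytest

from solugraph.curation import CuratedDataset
from solugraph.domain import (
    Fingerprint,
    build_domain,
    classify,
    fingerprint,
    mean_knn_distances,
    tanimoto_distance,
)


def _random_fingerprints(rng, n, density=0.02, n_bits=2048):
    fps = []
    for _ in range(n):
        k = max(1, rng.poisson(density * n_bits))
        bits = frozenset(int(b) for b in rng.choice(n_bits, size=k, replace=False))
        fps.append(Fingerprint(bits))
    return fps


def brute_force_mean_knn(fps, k):
    """Oracle: exhaustive pairwise distances, sorted, first k averaged."""
    n = len(fps)
    out = np.empty(n)
    for i in range(n):
        dists = sorted(
            (tanimoto_distance(fps[i], fps[j]), j) for j in range(n) if j != i
        )
        out[i] = np.mean([d for d, _ in dists[:k]])
    return out


class TestTanimoto:
    def test_identical_sets(self):
        a = Fingerprint(frozenset({1, 2, 3}))
        assert tanimoto_distance(a, a) == 0.0

    def test_disjoint_sets(self):
        a = Fingerprint(frozenset({1, 2}))
        b = Fingerprint(frozenset({3, 4}))
        assert tanimoto_distance(a, b) == 1.0

    def test_closed_form_jaccard(self):
        a = Fingerprint(frozenset({1, 2, 3}))
        b = Fingerprint(frozenset({2, 3, 4}))
        assert tanimoto_distance(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        a = Fingerprint(frozenset())
        assert tanimoto_distance(a, a) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto_distance(
                Fingerprint(frozenset({1}), n_bits=1024), Fingerprint(frozenset({1}))
            )


class TestFingerprint:
    def test_spellings_agree(self):
        assert fingerprint("CCO").on_bits == fingerprint("OCC").on_bits

    def test_different_structures_differ(self):
        assert fingerprint("C").on_bits != fingerprint("CCCCCCCCCC").on_bits

    def test_deterministic(self):
        assert fingerprint("CC(=O)Oc1ccccc1C(=O)O") == fingerprint(
            "CC(=O)Oc1ccccc1C(=O)O"
        )


class TestMeanKnn:
    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_matches_brute_force_oracle(self, rng, k):
        fps = _random_fingerprints(rng, 20)
        fast = mean_knn_distances(fps, k)
        oracle = brute_force_mean_knn(fps, k)
        assert np.allclose(fast, oracle, atol=1e-12)

    def test_k_too_large_rejected(self, rng):
        fps = _random_fingerprints(rng, 5)
        with pytest.raises(ValueError):
            mean_knn_distances(fps, 5)


@pytest.fixture(scope="module")
def domain_no_correction(small_dataset):
    train = CuratedDataset(list(small_dataset)[:60])
    return train, build_domain(train, ensemble=None, k=5)


class TestBuildDomain:
    def test_uncorrected_radii_equal_base(self, domain_no_correction):
        _, ad = domain_no_correction
        assert np.allclose(ad.corrected_radius, ad.base_radius)
        assert np.all(ad.correction_inputs["factor"] == 1.0)

    def test_radii_nonnegative_reference_positive(self, domain_no_correction):
        _, ad = domain_no_correction
        assert np.all(ad.corrected_radius >= 0)
        assert ad.reference_value > 0

    def test_reference_is_upper_fence(self, domain_no_correction):
        _, ad = domain_no_correction
        q1, q3 = np.percentile(ad.mean_knn_dist, [25, 75])
        assert ad.reference_value == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_k_bounds(self, small_dataset):
        train = CuratedDataset(list(small_dataset)[:10])
        with pytest.raises(ValueError):
            build_domain(train, None, k=10)
        with pytest.raises(ValueError):
            build_domain(train, None, k=0)

    def test_save_load_roundtrip(self, domain_no_correction, tmp_path):
        from solugraph.domain import ADModel

        _, ad = domain_no_correction
        ad.save(tmp_path / "ad.json")
        back = ADModel.load(tmp_path / "ad.json")
        assert back.k == ad.k
        assert np.allclose(back.corrected_radius, ad.corrected_radius)
        assert back.fingerprints == ad.fingerprints


def test_sweep_k_reports_each_k(small_dataset):
    from solugraph.domain import sweep_k

    train = CuratedDataset(list(small_dataset)[:40])
    test = CuratedDataset(list(small_dataset)[40:60])
    table = sweep_k(train, None, test, ks=(1, 3, 6))
    assert list(table["k"]) == [1, 3, 6]
    assert table["coverage"].between(0, 1).all()


class TestClassify:
    def test_training_compound_with_positive_radius_is_inside(self, domain_no_correction):
        train, ad = domain_no_correction
        idx = int(np.argmax(ad.corrected_radius))
        res = classify(ad, train.records[idx].canonical_smiles)
        assert res.inside and res.covering_count >= 1
        assert res.min_distance == 0.0

    def test_inside_iff_covered(self, domain_no_correction):
        train, ad = domain_no_correction
        res = classify(ad, "C#N")  # far outside the generator's chemistry
        assert res.inside == (res.covering_count >= 1)

    def test_coverage_monotone_in_radius_scale(self, domain_no_correction, small_dataset):
        _, ad = domain_no_correction
        queries = [r.canonical_smiles for r in list(small_dataset)[60:90]]
        counts = []
        for scale in (0.5, 1.0, 2.0, 5.0):
            counts.append(sum(classify(ad, q, scale).covering_count for q in queries))
        assert counts == sorted(counts)

    def test_order_independence(self, small_dataset):
        records = list(small_dataset)[:40]
        train_a = CuratedDataset(records)
        train_b = CuratedDataset(records[::-1])
        ad_a = build_domain(train_a, None, k=5)
        ad_b = build_domain(train_b, None, k=5)
        for q in [r.canonical_smiles for r in list(small_dataset)[40:55]]:
            ra, rb = classify(ad_a, q), classify(ad_b, q)
            assert ra.inside == rb.inside
            assert ra.covering_count == rb.covering_count
            assert ra.min_distance == pytest.approx(rb.min_distance)
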