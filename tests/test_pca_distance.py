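import numpy as np
import pytest

from breedgate.ibs_central import IbsMatrix, pairwise_ibs
from breedgate.pca_distance import (
    Embedding,
    distance_scores,
    embed_ibs,
    reassess_with_candidates,
)

from conftest import make_dataset, random_dataset


def random_similarity(rng, n):
    """Random valid similarity matrix: diagonal 1, symmetric, in [0, 1]."""
    x = rng.random((n, 4))
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    s = 1.0 - d2 / (d2.max() + 1e-9)
    np.fill_diagonal(s, 1.0)
    return IbsMatrix(sample_ids=[f"S{i + 1}" for i in range(n)], values=s)


class TestEmbedIbs:
    def test_identical_samples_identical_coordinates(self):
        ds = make_dataset([[0, 1, 2, 0], [0, 1, 2, 0], [2, 1, 0, 2], [1, 1, 1, 1]])
        emb = embed_ibs(pairwise_ibs(ds), k=2)
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1], atol=1e-9)

    def test_full_rank_reproduces_centered_similarity_distances(self):
        rng = np.random.default_rng(8)
        ibs = random_similarity(rng, 7)
        emb = embed_ibs(ibs, k=6)
        s = ibs.values
        for i in range(7):
            for j in range(7):
                d2_expected = s[i, i] + s[j, j] - 2 * s[i, j]
                d2 = ((emb.coordinates[i] - emb.coordinates[j]) ** 2).sum()
                assert d2 == pytest.approx(d2_expected, abs=1e-8)

    def test_close_pair_stays_close(self):
        v = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.2], [0.2, 0.2, 1.0]])
        ibs = IbsMatrix(sample_ids=["a", "b", "c"], values=v)
        emb = embed_ibs(ibs, k=2)
        d = lambda i, j: np.linalg.norm(emb.coordinates[i] - emb.coordinates[j])
        assert d(0, 1) < d(0, 2) and d(0, 1) < d(1, 2)

    def test_eigenvalues_nonincreasing(self):
        emb = embed_ibs(random_similarity(np.random.default_rng(9), 8), k=5)
        assert (np.diff(emb.eigenvalues) <= 1e-12).all()

    def test_k_out_of_range_rejected(self):
        ibs = random_similarity(np.random.default_rng(1), 4)
        with pytest.raises(ValueError, match="k must be"):
            embed_ibs(ibs, k=4)

    def test_all_equal_matrix_flagged_degenerate(self):
        ibs = IbsMatrix(sample_ids=["a", "b", "c"], values=np.ones((3, 3)))
        emb = embed_ibs(ibs, k=2)
        assert emb.degenerate
        np.testing.assert_allclose(emb.coordinates, 0.0, atol=1e-9)


class TestDistanceScores:
    def _toy_embedding(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [3.0, 3.0]])
        return Embedding(
            sample_ids=["r1", "r2", "r3", "q", "out"],
            coordinates=coords,
            eigenvalues=np.array([2.0, 1.0]),
        )

    def test_hand_euclidean_example(self):
        # RP median (0,0); query at (1,1): sqrt(2)/sqrt(18) = 1/3
        table = distance_scores(self._toy_embedding(), ["r1", "r2", "r3"], "out")
        assert table.score_of("q") == pytest.approx(1.0 / 3.0)

    def test_outgroup_anchored_at_one(self):
        table = distance_scores(self._toy_embedding(), ["r1", "r2", "r3"], "out")
        assert table.score_of("out") == 1.0

    def test_sample_at_median_scores_zero(self):
        table = distance_scores(self._toy_embedding(), ["r1", "r2", "r3"], "out")
        assert table.score_of("r1") == 0.0

    def test_degenerate_outgroup_at_median_rejected(self):
        emb = Embedding(
            sample_ids=["a", "b", "c", "out"],
            coordinates=np.array([[0.0, 1], [1, 0], [-1, -1], [0, 0]]),
            eigenvalues=np.array([1.0, 1.0]),
        )
        with pytest.raises(ValueError, match="degenerate"):
            distance_scores(emb, ["a", "b", "c"], "out")

    def test_larger_k_never_decreases_distances(self, study_fixture):
        ds = study_fixture.dataset
        focal = ds.breed_members(study_fixture.focal_breed)[:20]
        ibs = pairwise_ibs(ds, focal + [study_fixture.outgroup_id])
        prev = None
        for k in (2, 3, 5, 8):
            emb = embed_ibs(ibs, k=k)
            table = distance_scores(emb, focal[:15], study_fixture.outgroup_id)
            if prev is not None:
                assert (table.distance >= prev - 1e-9).all()
            prev = table.distance


class TestReassess:
    def test_empty_candidates_matches_direct_pipeline(self):
        rng = np.random.default_rng(31)
        ds = random_dataset(rng, 10, 60, missing_rate=0.0)
        ids = ds.sample_ids
        rp, out = ids[:9], ids[9]
        direct = distance_scores(embed_ibs(pairwise_ibs(ds, rp + [out]), 3), rp, out)
        re = reassess_with_candidates(ds, rp, out, [], k=3)
        for s in rp + [out]:
            assert re.score_of(s) == pytest.approx(direct.score_of(s), abs=1e-12)

    def test_duplicate_candidate_scores_like_its_twin(self):
        rng = np.random.default_rng(32)
        calls = rng.integers(0, 3, (9, 80)).astype(np.int8)
        calls[8] = calls[0]  # candidate duplicates an RP member
        ds = make_dataset(calls)
        ids = ds.sample_ids
        table = reassess_with_candidates(ds, ids[:7], ids[7], [ids[8]], k=3)
        assert table.score_of(ids[8]) == pytest.approx(table.score_of(ids[0]), abs=1e-9)

    def test_matches_from_scratch_pipeline(self):
        rng = np.random.default_rng(33)
        ds = random_dataset(rng, 12, 50, missing_rate=0.05)
        ids = ds.sample_ids
        rp, out, cands = ids[:8], ids[8], ids[9:]
        re = reassess_with_candidates(ds, rp, out, cands, k=3)
        scratch = distance_scores(
            embed_ibs(pairwise_ibs(ds, rp + [out] + cands), k=3), rp, out
        )
        np.testing.assert_allclose(re.score, scratch.score, atol=1e-12)

    def test_scores_invariant_to_candidate_listing_order(self):
        rng = np.random.default_rng(34)
        ds = random_dataset(rng, 10, 50, missing_rate=0.0)
        ids = ds.sample_ids
        rp, out = ids[:7], ids[7]
        a = reassess_with_candidates(ds, rp, out, [ids[8], ids[9]])
        b = reassess_with_candidates(ds, rp, out, [ids[9], ids[8]])
        for s in ids:
            assert a.score_of(s) == pytest.approx(b.score_of(s), abs=1e-9)
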