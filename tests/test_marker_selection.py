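import math

import numpy as np
import pytest

from breedgate.io_genotypes import MISSING
from breedgate.marker_selection import (
    composite_ld_r2,
    ld_prune,
    per_marker_fst,
    select_informative,
    two_group_fst,
)

from conftest import make_dataset


class TestPerMarkerFst:
    def test_half_vs_fixed_closed_form(self):
        # group a at p=0.5 (dosages 0,2), group b fixed for allele_b:
        # H_T = 2*0.75*0.25 = 0.375, H_S = (0.5 + 0)/2 = 0.25
        ds = make_dataset([[0], [2], [2], [2]])
        stats = per_marker_fst(ds, ["S1", "S2"], ["S3", "S4"])
        assert stats[0].fst == pytest.approx((0.375 - 0.25) / 0.375)

    def test_identical_frequencies_zero(self):
        ds = make_dataset([[1], [1], [1], [1]])
        stats = per_marker_fst(ds, ["S1", "S2"], ["S3", "S4"])
        assert stats[0].fst == pytest.approx(0.0)

    def test_fixed_difference_one(self):
        ds = make_dataset([[0], [0], [2], [2]])
        stats = per_marker_fst(ds, ["S1", "S2"], ["S3", "S4"])
        assert stats[0].fst == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(11)
        ds = make_dataset(rng.integers(0, 3, (8, 30)).astype(np.int8))
        g1, g2 = [f"S{i}" for i in range(1, 5)], [f"S{i}" for i in range(5, 9)]
        f12 = [s.fst for s in per_marker_fst(ds, g1, g2)]
        f21 = [s.fst for s in per_marker_fst(ds, g2, g1)]
        assert f12 == pytest.approx(f21, nan_ok=True)

    def test_monomorphic_everywhere_not_scorable(self):
        ds = make_dataset([[0], [0], [0], [0]])
        stats = per_marker_fst(ds, ["S1", "S2"], ["S3", "S4"], fst_min=0.0)
        assert math.isnan(stats[0].fst) and not stats[0].retained

    def test_overlapping_groups_rejected(self):
        ds = make_dataset([[0], [1], [2]])
        with pytest.raises(ValueError, match="overlap"):
            per_marker_fst(ds, ["S1", "S2"], ["S2", "S3"])


class TestCompositeLd:
    def test_exact_copy_r2_one(self):
        ds = make_dataset([[0, 0], [1, 1], [2, 2], [1, 1]])
        assert composite_ld_r2(ds, "m1", "m2") == pytest.approx(1.0)

    def test_flipped_coding_r2_one(self):
        ds = make_dataset([[0, 2], [1, 1], [2, 0], [1, 1]])
        assert composite_ld_r2(ds, "m1", "m2") == pytest.approx(1.0)

    def test_hand_pearson_value(self):
        # dosages (0,1,2) vs (0,2,2): cov = 2/3, var = 2/3 and 8/9
        ds = make_dataset([[0, 0], [1, 2], [2, 2]])
        assert composite_ld_r2(ds, "m1", "m2") == pytest.approx(0.75)

    def test_orthogonal_dosages_r2_zero(self):
        ds = make_dataset([[0, 0], [1, 1], [2, 0], [1, 1]])
        assert composite_ld_r2(ds, "m1", "m2") == pytest.approx(0.0)

    def test_monomorphic_pair_undefined(self):
        ds = make_dataset([[0, 0], [0, 1], [0, 2]])
        assert math.isnan(composite_ld_r2(ds, "m1", "m2"))

    def test_pairwise_complete_samples_only(self):
        ds = make_dataset([[0, 0], [1, MISSING], [2, 2], [0, 2]])
        # complete pairs are rows 1, 3, 4 -> dosages (0,2,0) vs (0,2,2)
        x, y = np.array([0, 2, 0.0]), np.array([0, 2, 2.0])
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert composite_ld_r2(ds, "m1", "m2") == pytest.approx(expected)


def _panel_fixture(rng):
    """50 markers on 7 chromosomes; exactly 7 with focal-vs-pool
    Fst >= 0.4.  The informative markers sit on different chromosomes
    (breed-informative markers are mutually correlated through the
    population structure, so only same-chromosome LD is pruned), except
    one exact duplicate pair sharing a chromosome."""
    n_focal, n_other = 20, 20
    calls = np.empty((n_focal + n_other, 50), dtype=np.int8)
    # background: shared intermediate frequency, low differentiation
    calls[:, :] = rng.binomial(2, 0.5, size=calls.shape)
    # informative markers: near-fixed difference focal vs pool, one per chrom
    informative = [1, 8, 15, 22, 29, 36]
    for j in informative:
        calls[:n_focal, j] = rng.binomial(2, 0.05, n_focal)
        calls[n_focal:, j] = rng.binomial(2, 0.95, n_other)
    calls[:, 37] = calls[:, 36]  # duplicate of an informative marker, same chrom
    chrom = [str(j // 7 + 1) for j in range(50)]
    breeds = ["FOC"] * n_focal + ["OTH"] * n_other
    return make_dataset(calls, breeds=breeds, chrom=chrom), informative + [37]


class TestSelectInformative:
    def test_brute_force_recount_of_both_filters(self):
        rng = np.random.default_rng(7)
        ds, planted = _panel_fixture(rng)
        stats = per_marker_fst(
            ds, ds.breed_members("FOC"), ds.breed_members("OTH"), fst_min=0.4
        )
        passing = [s.marker_id for s in stats if s.retained]
        assert passing == [f"m{j + 1}" for j in planted]  # 7 markers screened in
        panel = select_informative(ds, "FOC", fst_min=0.4, ld_max=0.5)
        assert panel.n_markers == 6  # the duplicate pruned

    def test_filters_disabled_keep_all_scorable(self):
        rng = np.random.default_rng(7)
        ds, _ = _panel_fixture(rng)
        stats = per_marker_fst(ds, ds.breed_members("FOC"), ds.breed_members("OTH"))
        scorable = sum(s.retained for s in stats)
        panel = select_informative(ds, "FOC", fst_min=0.0, ld_max=1.01)
        assert panel.n_markers == scorable

    def test_overstrict_threshold_is_empty_panel_error(self):
        rng = np.random.default_rng(7)
        ds, _ = _panel_fixture(rng)
        with pytest.raises(ValueError, match="no marker survives"):
            select_informative(ds, "FOC", fst_min=1.0)

    def test_raising_fst_min_never_enlarges_panel(self):
        rng = np.random.default_rng(7)
        ds, _ = _panel_fixture(rng)
        sizes = []
        for fst_min in (0.0, 0.2, 0.4, 0.6):
            try:
                sizes.append(select_informative(ds, "FOC", fst_min=fst_min).n_markers)
            except ValueError:
                sizes.append(0)
        assert sizes == sorted(sizes, reverse=True)

    def test_kept_within_chromosome_pairs_below_ld_max(self):
        # exhaustive pairwise check per chromosome on a freshly selected panel
        from breedgate.synth_breeds import BreedSpec, SimConfig, simulate_breeds

        ds = simulate_breeds(
            SimConfig(
                breeds=(BreedSpec("FOC", 25, 0.3), BreedSpec("OTH", 25, 0.3)),
                n_markers=4000,
                n_chromosomes=10,
                seed=13,
            )
        )
        panel = select_informative(ds, "FOC", fst_min=0.3, ld_max=0.5)
        by_chrom = {}
        for m in panel.markers:
            by_chrom.setdefault(m.chromosome, []).append(m.marker_id)
        checked = 0
        for kept in by_chrom.values():
            for i, mi in enumerate(kept):
                for mj in kept[i + 1 :]:
                    r2 = composite_ld_r2(panel, mi, mj)
                    assert math.isnan(r2) or r2 < 0.5
                    checked += 1
        assert checked > 0


def test_ld_prune_keeps_first_of_duplicates():
    calls = np.array([[0, 0, 2], [1, 1, 1], [2, 2, 0], [1, 1, 2]], dtype=np.int8)
    ds = make_dataset(calls)
    kept = ld_prune(ds, ds.marker_ids, ld_max=0.5)
    assert kept[0] == "m1" and "m2" not in kept


def test_two_group_fst_matches_dataset_route():
    assert two_group_fst(0.5, 1.0) == pytest.approx(1.0 / 3.0, abs=1e-12)
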