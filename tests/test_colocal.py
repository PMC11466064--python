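"""Dilation, the >50%-overlap colocalization rule, and group statistics."""

import numpy as np
import pytest

from spincolocal.colocal import (colocalize, compare_groups, dilate_puncta,
                                 percent_reduction)
from spincolocal.image import ROIMask
from spincolocal.puncta import detect_puncta, filter_by_size
from spincolocal.simulate import (PunctaChannelSpec, PunctaSimParams,
                                  generate_puncta_field)

from conftest import (brute_force_colocalize, brute_force_dilate,
                      make_punctum_set)


def _pixel_sets(puncta_set):
    return [set(zip(p.rows.tolist(), p.cols.tolist())) for p in puncta_set]


class TestDilatePuncta:
    def test_zero_dilation_is_identity(self):
        ps = make_punctum_set([{(5, 5)}, {(10, 10), (10, 11)}], (20, 20), 0.1)
        out = dilate_puncta(ps, 0.0)
        assert _pixel_sets(out) == _pixel_sets(ps)

    def test_single_pixel_grows_to_radius_one_disk(self):
        # dilation radius exactly one pixel: the 5-pixel plus-shaped disk
        ps = make_punctum_set([{(5, 5)}], (20, 20), pixel_size_um=0.1)
        out = dilate_puncta(ps, 0.1)
        expected = {(5, 5), (4, 5), (6, 5), (5, 4), (5, 6)}
        assert _pixel_sets(out)[0] == expected

    def test_subpixel_dilation_rounds_up_to_one_pixel(self):
        # 0.1 µm at 0.15 µm/px is sub-pixel; must still grow by a full pixel
        ps = make_punctum_set([{(5, 5)}], (20, 20), pixel_size_um=0.15)
        out = dilate_puncta(ps, 0.1)
        assert _pixel_sets(out)[0] == brute_force_dilate({(5, 5)}, 1.0, (20, 20))

    @pytest.mark.parametrize("radius_um", [0.1, 0.2, 0.35])
    def test_matches_brute_force_disk_rasterization(self, radius_um):
        rng = np.random.default_rng(3)
        sets = []
        for _ in range(5):
            r, c = rng.integers(5, 40, 2)
            sets.append({(r + dr, c + dc) for dr in range(3) for dc in range(2)})
        ps = make_punctum_set(sets, (48, 48), pixel_size_um=0.1)
        out = dilate_puncta(ps, radius_um)
        radius_px = max(1.0, radius_um / 0.1)
        for orig, got in zip(sets, _pixel_sets(out)):
            assert got == brute_force_dilate(orig, radius_px, (48, 48))

    def test_dilation_never_shrinks_and_ids_preserved(self):
        ps = make_punctum_set([{(5, 5)}, {(30, 30), (31, 30)}], (48, 48), 0.1)
        out = dilate_puncta(ps, 0.25)
        assert [p.id for p in out] == [p.id for p in ps]
        for before, after in zip(ps, out):
            assert after.n_pixels >= before.n_pixels

    def test_negative_dilation_rejected(self):
        ps = make_punctum_set([{(5, 5)}], (20, 20), 0.1)
        with pytest.raises(ValueError):
            dilate_puncta(ps, -0.1)


class TestColocalize:
    def test_identical_sets_fully_colocalized(self):
        sets = [{(5, c) for c in range(5, 10)}, {(15, c) for c in range(5, 9)}]
        a = make_punctum_set(sets, (30, 30), 0.1, channel="a2")
        b = make_punctum_set(sets, (30, 30), 0.1, channel="geph")
        res = colocalize(a, b)
        assert res.colocalized_fraction == 1.0

    def test_distant_sets_not_colocalized(self):
        a = make_punctum_set([{(2, 2)}], (40, 40), 0.1, channel="a2")
        b = make_punctum_set([{(30, 30)}], (40, 40), 0.1, channel="geph")
        res = colocalize(a, b, dilation_um=0.1)
        assert res.colocalized_fraction == 0.0

    def test_strict_majority_overlap_decides(self):
        # 5x5 reference; partner covering 15/25 px (0.60) vs 12/25 px (0.48)
        ref_pixels = {(r, c) for r in range(10, 15) for c in range(10, 15)}
        over_15 = {(r, c) for r in range(10, 13) for c in range(10, 15)}
        over_12 = {(r, c) for r in range(10, 13) for c in range(10, 14)}
        ref = make_punctum_set([ref_pixels], (30, 30), 0.1, channel="r")
        hit = make_punctum_set([over_15], (30, 30), 0.1, channel="o")
        miss = make_punctum_set([over_12], (30, 30), 0.1, channel="o")
        assert colocalize(ref, hit, dilation_um=0.0).n_colocalized == 1
        assert colocalize(ref, miss, dilation_um=0.0).n_colocalized == 0

    def test_exactly_half_overlap_is_not_colocalized(self):
        ref_pixels = {(10, c) for c in range(10, 14)}
        half = {(10, 10), (10, 11)}
        ref = make_punctum_set([ref_pixels], (30, 30), 0.1)
        other = make_punctum_set([half], (30, 30), 0.1)
        res = colocalize(ref, other, dilation_um=0.0)
        assert res.overlap_fractions[0] == pytest.approx(0.5)
        assert res.n_colocalized == 0

    def test_overlap_sums_over_multiple_partners(self):
        # two partners each covering 2/6 of the reference; 4/6 total > 0.5
        ref_pixels = {(10, c) for c in range(10, 16)}
        p1 = {(10, 10), (10, 11)}
        p2 = {(10, 12), (10, 13)}
        ref = make_punctum_set([ref_pixels], (30, 30), 0.1)
        other = make_punctum_set([p1, p2], (30, 30), 0.1)
        res = colocalize(ref, other, dilation_um=0.0)
        assert res.n_colocalized == 1

    def test_empty_reference_flagged_not_raised(self):
        ref = make_punctum_set([], (30, 30), 0.1)
        other = make_punctum_set([{(5, 5)}], (30, 30), 0.1)
        res = colocalize(ref, other)
        assert res.undefined
        assert np.isnan(res.colocalized_fraction)

    def test_monotone_in_dilation_and_threshold(self):
        params = PunctaSimParams(
            field_size_um=(40.0, 40.0), seed=2, true_coloc_fraction=0.4,
            channels=[PunctaChannelSpec(name="a", density_per_um2=0.08),
                      PunctaChannelSpec(name="b", density_per_um2=0.06)])
        field, _ = generate_puncta_field(params)
        a = filter_by_size(detect_puncta(field, "a"))
        b = filter_by_size(detect_puncta(field, "b"))
        n_by_dilation = [colocalize(b, a, dilation_um=d).n_colocalized
                         for d in (0.0, 0.1, 0.3, 0.6)]
        assert n_by_dilation == sorted(n_by_dilation)
        n_by_threshold = [colocalize(b, a, overlap_threshold=t).n_colocalized
                          for t in (0.2, 0.5, 0.8, 1.0)]
        assert n_by_threshold == sorted(n_by_threshold, reverse=True)

    def test_asymmetry_counterexample_matches_pixel_oracle(self):
        # small reference fully inside a large partner: A->B colocalized,
        # B->A not (the large object is mostly uncovered)
        small = {(10, 10), (10, 11)}
        large = {(r, c) for r in range(8, 14) for c in range(8, 16)}
        a = make_punctum_set([small], (30, 30), 0.1, channel="a")
        b = make_punctum_set([large], (30, 30), 0.1, channel="b")
        ab = colocalize(a, b, dilation_um=0.0)
        ba = colocalize(b, a, dilation_um=0.0)
        assert ab.n_colocalized == 1 and ba.n_colocalized == 0
        assert brute_force_colocalize([small], [large], 0.5) == [True]
        assert brute_force_colocalize([large], [small], 0.5) == [False]

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_per_pixel_oracle_on_random_fields(self, seed):
        params = PunctaSimParams(
            field_size_um=(19.2, 19.2), pixel_size_um=0.15, seed=seed,
            true_coloc_fraction=0.5,
            channels=[PunctaChannelSpec(name="a", density_per_um2=0.1),
                      PunctaChannelSpec(name="b", density_per_um2=0.08)])
        field, _ = generate_puncta_field(params)  # 128x128 px
        a = filter_by_size(detect_puncta(field, "a"))
        b = filter_by_size(detect_puncta(field, "b"))
        res = colocalize(b, a, overlap_threshold=0.5, dilation_um=0.1)
        ref_d = dilate_puncta(b, 0.1)
        oth_d = dilate_puncta(a, 0.1)
        oracle = brute_force_colocalize(_pixel_sets(ref_d), _pixel_sets(oth_d), 0.5)
        got = [p.id in set(res.colocalized_ids) for p in b]
        assert got == oracle

    def test_mismatched_fields_rejected(self):
        a = make_punctum_set([{(1, 1)}], (20, 20), 0.1)
        b = make_punctum_set([{(1, 1)}], (30, 30), 0.1)
        with pytest.raises(ValueError):
            colocalize(a, b)


class TestPercentReduction:
    @pytest.mark.parametrize("control, test, expected", [
        (0.23, 0.005, 97.8),   # deep dorsal horn α2 clusters
        (0.46, 0.18, 60.9),    # deep dorsal horn α3 clusters
        (0.64, 0.50, 21.9),    # superficial α2 clusters
        (0.40, 0.37, 7.5),     # superficial α3 clusters
        (0.34, 0.10, 70.6),    # deep gephyrin-α3 colocalized clusters
    ])
    def test_published_cluster_density_reductions(self, control, test, expected):
        assert percent_reduction(control, test) == expected

    def test_identity_gives_zero(self):
        assert percent_reduction(0.37, 0.37) == 0.0

    def test_increase_reported_negative(self):
        assert percent_reduction(0.2, 0.3) == -50.0

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 0.1)


class TestCompareGroups:
    def test_identical_degenerate_groups_flagged(self):
        res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.percent_reduction == 0.0
        assert res.p_undefined and np.isnan(res.p_value)

    def test_means_are_arithmetic_means(self):
        a, b = [0.2, 0.4, 0.6], [0.1, 0.2]
        res = compare_groups(a, b)
        assert res.control_mean == pytest.approx(np.mean(a))
        assert res.test_mean == pytest.approx(np.mean(b))

    def test_simulated_50pct_reduction_detected(self):
        """Sections at true densities 0.6 vs 0.3, sd 0.02, n=10: the recovered
        reduction is 50% ± 5% with p < 0.001 in at least 95 of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ctrl = rng.normal(0.6, 0.02, 10)
            test = rng.normal(0.3, 0.02, 10)
            res = compare_groups(ctrl, test)
            if abs(res.percent_reduction - 50.0) <= 5.0 and res.p_value < 1e-3:
                hits += 1
        assert hits >= 95

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
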