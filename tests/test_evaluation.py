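"""QA metrics (Dice, H95, field stats, MI) and the statistical machinery."""

import itertools

import numpy as np
import pytest

from mr4dctreg import (Grid, binned_improvement, compare_methods, dice,
                       evaluate_result, hausdorff95, propagate_rigid)
from mr4dctreg.evaluation import (MetricRecord, _paired_wilcoxon,
                                  significance_stars)
from mr4dctreg.grids import BinaryMask


def _mask(grid, sl):
    d = np.zeros(grid.shape, bool)
    d[sl] = True
    return BinaryMask(grid, d)


class TestDice:
    def test_identical_and_disjoint(self):
        g = Grid((8, 8, 8))
        a = _mask(g, (slice(1, 5),) * 3)
        b = _mask(g, (slice(5, 8),) * 3)
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_half_cube_counted(self):
        g = Grid((16, 16, 16))
        a = _mask(g, (slice(4, 12), slice(4, 12), slice(4, 12)))
        b = _mask(g, (slice(4, 12), slice(4, 12), slice(4, 8)))
        assert abs(dice(a, b) - 2.0 / 3.0) < 1e-6

    def test_empty_conventions(self):
        g = Grid((4, 4, 4))
        empty = BinaryMask(g, np.zeros(g.shape, bool))
        full = _mask(g, (slice(0, 2),) * 3)
        assert dice(empty, empty) == 1.0
        assert dice(empty, full) == 0.0

    def test_symmetry(self):
        g = Grid((8, 8, 8))
        a = _mask(g, (slice(1, 6),) * 3)
        b = _mask(g, (slice(3, 8),) * 3)
        assert dice(a, b) == dice(b, a)


class TestHausdorff95:
    def test_identical_zero(self):
        g = Grid((8, 8, 8))
        a = _mask(g, (slice(2, 6),) * 3)
        assert hausdorff95(a, a) == 0.0

    def test_parallel_plates(self):
        g = Grid((12, 12, 12), (1.0, 1.0, 1.0))
        a = _mask(g, (slice(None), slice(None), slice(2, 3)))
        b = _mask(g, (slice(None), slice(None), slice(7, 8)))
        got = hausdorff95(a, b)
        assert abs(got - 5.0) <= np.sqrt(3.0)

    def test_spacing_scales_distance(self):
        g1 = Grid((12, 12, 12), (1.0, 1.0, 1.0))
        g2 = Grid((12, 12, 12), (2.0, 2.0, 2.0))
        sl_a = (slice(None), slice(None), slice(2, 3))
        sl_b = (slice(None), slice(None), slice(7, 8))
        h1 = hausdorff95(_mask(g1, sl_a), _mask(g1, sl_b))
        h2 = hausdorff95(_mask(g2, sl_a), _mask(g2, sl_b))
        assert abs(h2 - 2.0 * h1) < 1e-9

    def test_h95_below_max_distance(self, rng):
        g = Grid((16, 16, 16))
        a = BinaryMask(g, rng.random(g.shape) > 0.7)
        b = BinaryMask(g, rng.random(g.shape) > 0.7)
        from scipy.ndimage import binary_erosion, distance_transform_edt
        sa = a.data & ~binary_erosion(a.data)
        sb = b.data & ~binary_erosion(b.data)
        dta = distance_transform_edt(~sa, sampling=g.spacing)
        dtb = distance_transform_edt(~sb, sampling=g.spacing)
        h100 = max(dtb[sa].max(), dta[sb].max())
        assert hausdorff95(a, b) <= h100 + 1e-12

    def test_empty_mask_undefined(self):
        g = Grid((8, 8, 8))
        empty = BinaryMask(g, np.zeros(g.shape, bool))
        full = _mask(g, (slice(0, 2),) * 3)
        assert np.isnan(hausdorff95(empty, full))


class TestEvaluateResult:
    def test_self_evaluation_fixed_point(self, phantom_study):
        res = propagate_rigid(phantom_study.record, seed=0)
        truth = dict(res.warped_labels)  # the prediction as its own truth
        recs = evaluate_result(res, truth, omega=res.omega,
                               subject="s0")
        per_organ = [r for r in recs
                     if r.organ not in ("seen", "unseen", "all")]
        assert per_organ
        for r in per_organ:
            assert r.dsc == 1.0
            assert r.h95_mm == 0.0 or np.isnan(r.h95_mm)

    def test_all_aggregate_is_unweighted_mean(self, phantom_study):
        res = propagate_rigid(phantom_study.record, seed=0)
        recs = evaluate_result(res, phantom_study.record.labels_ct,
                               omega=res.omega, subject="s0")
        for phase in (0, 50):
            organs = [r.dsc for r in recs if r.phase == phase
                      and r.organ not in ("seen", "unseen", "all")]
            agg = [r.dsc for r in recs if r.phase == phase
                   and r.organ == "all"]
            assert abs(agg[0] - np.mean(organs)) < 1e-12

    def test_masked_mi_matches_loss_module(self, phantom_study):
        from mr4dctreg import neg_mutual_information, normalize_intensity
        from mr4dctreg.grids import resample_to_grid
        from mr4dctreg.fields import warp
        rec = phantom_study.record
        res = propagate_rigid(rec, seed=0)
        recs = evaluate_result(res, rec.labels_ct, omega=res.omega,
                               study=rec, subject="s0")
        row = next(r for r in recs if r.phase == 50 and r.organ == "all")
        mr_native = resample_to_grid(normalize_intensity(rec.mr),
                                     rec.native_grid)
        warped = warp(mr_native, res.fields[50])
        expect = neg_mutual_information(normalize_intensity(rec.ct[50]),
                                        warped, mask=res.omega)
        assert abs(row.mi_overlap - expect) < 1e-9


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.zeros(6)
        assert abs(_paired_wilcoxon(x, y) - 2.0 / 64.0) < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        r = np.random.default_rng(seed)
        d = r.normal(size=8)
        d = d[d != 0]
        got = _paired_wilcoxon(d, np.zeros_like(d))
        # brute force: distribution of W+ over all sign assignments
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        stat_obs = min(w_obs, total - w_obs)
        count = 0
        n = len(d)
        for signs in itertools.product([0, 1], repeat=n):
            w = sum(rk for rk, s in zip(ranks, signs) if s)
            if min(w, total - w) <= stat_obs:
                count += 1
        assert abs(got - count / 2 ** n) < 1e-12

    def test_self_comparison_p_one(self):
        x = np.arange(6.0)
        assert _paired_wilcoxon(x, x) == 1.0


class TestComparisons:
    def _records(self):
        r = np.random.default_rng(0)
        recs = []
        for s in range(8):
            base = 0.6 + 0.02 * r.random()
            for phase in (0, 50):
                recs.append(MetricRecord(f"s{s}", phase, "rigid", "liver",
                                         dsc=base))
                recs.append(MetricRecord(f"s{s}", phase, "direct", "liver",
                                         dsc=base + 0.1))
        return recs

    def test_consistent_improvement_significant(self):
        rep = compare_methods(self._records(), "dsc", [("direct", "rigid")])
        assert rep["p_raw"].iloc[0] < 0.05
        assert rep["p_adj"].iloc[0] >= rep["p_raw"].iloc[0]

    def test_bh_hand_computed(self):
        from statsmodels.stats.multitest import multipletests
        p = [0.01, 0.02, 0.04, 0.5]
        _, adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adj, [0.04, 0.04, 0.05333333, 0.5])

    def test_star_bands(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(5e-5) == "****"

    def test_fewer_than_two_methods_rejected(self):
        recs = [MetricRecord("s0", 0, "rigid", "liver", dsc=0.5)]
        with pytest.raises(ValueError):
            compare_methods(recs, "dsc", [("rigid", "rigid")])


class TestBinnedImprovement:
    def _paired_records(self, method, offset):
        recs = []
        for s in range(6):
            for phase in (0, 33):
                d = 0.62 + 0.01 * s
                recs.append(MetricRecord(f"s{s}", phase, method, "liver",
                                         dsc=min(d + offset, 1.0)))
        return recs

    def test_single_bin_reduces_to_global_mean(self):
        rigid = self._paired_records("rigid", 0.0)
        direct = self._paired_records("direct", 0.1)
        tab = binned_improvement(direct, rigid, bin_width=1.0)
        assert len(tab) == 1
        expect = np.mean([r.dsc for r in direct])
        assert abs(tab["mean_dice"].iloc[0] - expect) < 1e-12

    def test_method_identical_to_rigid(self):
        rigid = self._paired_records("rigid", 0.0)
        same = self._paired_records("same", 0.0)
        tab = binned_improvement(same, rigid, bin_width=0.1)
        assert np.allclose(tab["mean_dice"], tab["mean_rigid_dice"])
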