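"""Drifted-variant identification and DVxy statistics."""

import math

import numpy as np
import pandas as pd
import pytest

import isodrift as iso
from isodrift.drifted import (
    chromosome_resample_ci,
    common_in_isolate_rare_in_general,
    dvxy_coding,
    dvxy_wg,
    find_drifted_variants,
    jackknife_log_z,
    make_resampling_blocks,
)
from isodrift.types import CohortPair, FrequencyTable, VariantTable

PAIR = CohortPair("X", "Y")


def ft_from_dafs(daf_x, daf_y):
    daf_x = np.asarray(daf_x, float)
    daf_y = np.asarray(daf_y, float)
    alt = np.round(np.stack([daf_x, daf_y]) * 100).astype(int)
    called = np.full_like(alt, 100)
    return FrequencyTable(["X", "Y"], alt, called, np.stack([daf_x, daf_y]), np.stack([daf_x, daf_y]))


def vt_with(cons, cadd=None, chrom=None):
    n = len(cons)
    return VariantTable(
        pd.DataFrame(
            {
                "chrom": chrom if chrom is not None else "chr1",
                "pos": np.arange(1, n + 1),
                "ref": "A",
                "alt": "C",
                "ancestral": "A",
                "gene": "",
                "consequence": cons,
                "cadd": cadd if cadd is not None else 1.0,
            }
        )
    )


class TestDvRule:
    def test_rule_evaluation(self):
        # (daf_x, daf_y, in_x?): three-fold band membership cases
        ft = ft_from_dafs([0.03, 0.03, 0.06, 0.03], [0.009, 0.011, 0.01, 0.0])
        dv = find_drifted_variants(ft, PAIR)
        assert list(dv.idx_x) == [0, 3]  # 0.03 >= 3*0.009; daf_y = 0 qualifies
        assert list(dv.idx_y) == []

    def test_band_endpoints_inclusive(self):
        ft = ft_from_dafs([0.02, 0.05, 0.0501], [0.0, 0.0, 0.0])
        dv = find_drifted_variants(ft, PAIR)
        assert list(dv.idx_x) == [0, 1]

    def test_no_defined_daf_errors(self):
        ft = ft_from_dafs([0.03], [0.01])
        ft.daf[:] = np.nan
        with pytest.raises(ValueError):
            find_drifted_variants(ft, PAIR)

    def test_agrees_with_bruteforce(self, neutral_small):
        ft, pair = neutral_small["ft"], neutral_small["pair"]
        dv = find_drifted_variants(ft, pair)
        dx, dy = ft.daf_of(pair.isolate), ft.daf_of(pair.general)
        brute_x, brute_y = [], []
        for v in range(len(dx)):
            if np.isnan(dx[v]) or np.isnan(dy[v]):
                continue
            if 0.02 <= dx[v] <= 0.05 and dx[v] >= 3 * dy[v]:
                brute_x.append(v)
            if 0.02 <= dy[v] <= 0.05 and dy[v] >= 3 * dx[v]:
                brute_y.append(v)
        assert list(dv.idx_x) == brute_x and list(dv.idx_y) == brute_y
        assert len(brute_x) > 10  # the fixture actually exercises the rule


class TestDvxy:
    def _dv(self, nx, ny):
        """DriftedVariantSet with nx index-range variants in x, ny in y."""
        from isodrift.drifted import DriftedVariantSet

        return DriftedVariantSet(np.arange(nx), np.arange(nx, nx + ny), None, None)

    def test_coding_hand_arithmetic(self):
        cons = ["missense"] * 30 + ["intergenic"] * 300 + ["missense"] * 20 + ["intergenic"] * 400
        res = dvxy_coding(self._dv(330, 420), vt_with(cons))
        assert res.counts == (30, 300, 20, 400)
        assert res.estimate == pytest.approx(2.0)

    def test_coding_symmetry_gives_one(self):
        cons = ["missense"] * 10 + ["intergenic"] * 100 + ["missense"] * 10 + ["intergenic"] * 100
        assert dvxy_coding(self._dv(110, 110), vt_with(cons)).estimate == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        cons = ["missense"] * 5 + ["intergenic"] * 5 + ["missense"] * 5  # no intergenic in y
        res = dvxy_coding(self._dv(10, 5), vt_with(cons))
        assert res.undefined and math.isnan(res.estimate)

    def test_wg_hand_arithmetic(self):
        cadd = [1.0] * 150 + [25.0] * 15 + [1.0] * 200 + [25.0] * 10
        res = dvxy_wg(self._dv(165, 210), vt_with(["other"] * 375, cadd))
        gt20 = [r for r in res if r.stratum == "cadd_gt20"][0]
        assert gt20.counts == (15, 150, 10, 200)
        assert gt20.estimate == pytest.approx(2.0)

    def test_antisymmetry_exact(self, neutral_small):
        ft, vt, pair = neutral_small["ft"], neutral_small["vt"], neutral_small["pair"]
        fwd = find_drifted_variants(ft, pair)
        rev = find_drifted_variants(ft, pair.swapped())
        assert dvxy_coding(rev, vt).estimate == pytest.approx(1.0 / dvxy_coding(fwd, vt).estimate)
        for a, b in zip(dvxy_wg(fwd, vt), dvxy_wg(rev, vt)):
            if not (a.undefined or b.undefined or a.estimate == 0):
                assert b.estimate == pytest.approx(1.0 / a.estimate)


class TestResampling:
    def test_constant_statistic_degenerate_ci(self):
        labels = np.repeat([f"c{i}" for i in range(25)], 10)
        lo, hi = chromosome_resample_ci(lambda m: 3.14, labels, n_blocks=20, reps=50, seed=0)
        assert lo == hi == 3.14

    def test_seed_determinism(self, neutral_small):
        vt, ft, pair = neutral_small["vt"], neutral_small["ft"], neutral_small["pair"]
        labels = make_resampling_blocks(vt)

        def stat(mask):
            sub = FrequencyTable(ft.populations, ft.alt_count[:, mask], ft.called[:, mask],
                                 ft.af[:, mask], ft.daf[:, mask])
            return dvxy_coding(find_drifted_variants(sub, pair), vt.subset(mask)).estimate

        ci1 = chromosome_resample_ci(stat, labels, reps=30, seed=5)
        ci2 = chromosome_resample_ci(stat, labels, reps=30, seed=5)
        assert ci1 == ci2

    def test_too_few_blocks_errors(self):
        labels = np.array(["c1"] * 5 + ["c2"] * 5)
        with pytest.raises(ValueError, match="n_blocks"):
            chromosome_resample_ci(lambda m: 1.0, labels, n_blocks=20)

    def test_blocks_respect_chromosomes(self, neutral_small):
        vt = neutral_small["vt"]
        labels = make_resampling_blocks(vt, min_blocks=20)
        assert len(set(labels)) >= 20
        # every block lies within one chromosome
        for b in set(labels):
            assert len(set(vt.chrom[labels == b])) == 1

    def test_jackknife_constant_statistic(self):
        labels = np.repeat(["a", "b", "c", "d"], 5)
        out = jackknife_log_z(lambda m: 2.0, labels)
        assert out["se"] == 0.0 and out["log_estimate"] == pytest.approx(math.log(2.0))


class TestCommonInIsolate:
    @pytest.mark.parametrize("iso_c,gen_c,included", [(4, 1, True), (4, 2, False), (3, 1, False), (10, 0, True)])
    def test_thresholds(self, iso_c, gen_c, included):
        alt = np.array([[iso_c], [gen_c]])
        called = np.full_like(alt, 72)
        ft = FrequencyTable(["X", "Y"], alt, called, alt / 72, alt / 72)
        out = common_in_isolate_rare_in_general(ft, PAIR)
        assert (0 in out) == included
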