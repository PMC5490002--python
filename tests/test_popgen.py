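"""FST, inbreeding F, ROH scan and LD decay."""

import numpy as np
import pandas as pd
import pytest

import isodrift as iso
from isodrift.popgen import hudson_fst, inbreeding_f, ld_decay_length, pairwise_r2, roh_scan
from isodrift.types import CohortPair, FrequencyTable, GenotypeMatrix, VariantTable

PAIR = CohortPair("X", "Y")


def ft_from_counts(alt_x, alt_y, n_x=50, n_y=50):
    alt = np.stack([np.asarray(alt_x), np.asarray(alt_y)])
    called = np.stack([np.full(len(alt_x), 2 * n_x), np.full(len(alt_y), 2 * n_y)])
    af = alt / called
    return FrequencyTable(["X", "Y"], alt, called, af, af.copy())


def make_vt(pos, chrom="chr1"):
    return VariantTable(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "C",
                "ancestral": "A",
                "gene": "",
                "consequence": "intergenic",
                "cadd": 1.0,
            }
        )
    )


class TestHudsonFst:
    def test_matches_per_site_bruteforce(self, rng):
        alt_x = rng.integers(0, 101, 40)
        alt_y = rng.integers(0, 101, 40)
        ft = ft_from_counts(alt_x, alt_y)
        fst, per_site = hudson_fst(ft, PAIR)
        nums, dens = [], []
        for ax, ay in zip(alt_x, alt_y):
            p1, p2, n1, n2 = ax / 100, ay / 100, 100, 100
            if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
                continue
            nums.append((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1))
            dens.append(p1 * (1 - p2) + p2 * (1 - p1))
        assert fst == pytest.approx(sum(nums) / sum(dens))

    def test_identical_frequencies_near_zero(self):
        fst, _ = hudson_fst(ft_from_counts([50] * 30, [50] * 30), PAIR)
        assert abs(fst) < 0.02

    def test_fixed_difference_is_one(self):
        fst, _ = hudson_fst(ft_from_counts([100, 100], [0, 0]), PAIR)
        assert fst == pytest.approx(1.0)

    def test_no_polymorphic_site_flagged(self):
        fst, _ = hudson_fst(ft_from_counts([0, 100], [0, 100]), PAIR)
        assert np.isnan(fst)

    def test_island_model_equilibrium_expectation(self):
        """Two-deme symmetric island at equilibrium: Hudson FST ~
        1/(1 + 8 N m) (Tw = 4N, Tb = 4N + 1/(2m))."""
        vals = []
        for seed in range(10):
            cfg = iso.SimConfig(
                ne_ancestral=1000, ne_ancient=1000, growth_gens=0, ne_general=1000,
                ne_isolate=1000, tdg_gens=20_000, mig=2e-3, n_chroms=2,
                chrom_length_bp=3_000_000, n_genes_per_chrom=0, n_coding_sites_per_chrom=0,
                n_isolate=30, n_general=30, seed=800 + seed,
                missense_s_mean=0, lof_s_mean=0,
            )
            vt, gm, truth = iso.simulate_cohort_pair(cfg)
            ft = iso.allele_frequencies(gm, vt, ["ISO", "GEN"])
            fst, _ = hudson_fst(ft, CohortPair("ISO", "GEN"))
            vals.append(fst)
        expected = truth.expected_fst_island
        assert abs(np.mean(vals) / expected - 1) < 0.20

    def test_wc_estimator_close_to_hudson(self, neutral_small):
        ft, pair = neutral_small["ft"], neutral_small["pair"]
        h, _ = hudson_fst(ft, pair)
        w, _ = hudson_fst(ft, pair, estimator="wc")
        assert abs(h - w) < 0.02


class TestInbreedingF:
    def test_hwe_null_near_zero(self, rng):
        n, m = 40, 2000
        p = rng.uniform(0.1, 0.9, m)
        dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        gm = GenotypeMatrix(dos, [f"s{i}" for i in range(n)], {f"s{i}": "P" for i in range(n)})
        _, mean_f = inbreeding_f(gm, "P")
        assert abs(mean_f) < 0.03

    def test_fully_homozygous_individual_is_one(self, rng):
        n, m = 30, 500
        p = rng.uniform(0.2, 0.8, m)
        dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        dos[0] = (dos[0] > 0).astype(np.int8) * 2  # make individual 0 all-homozygous
        gm = GenotypeMatrix(dos, [f"s{i}" for i in range(n)], {f"s{i}": "P" for i in range(n)})
        per, _ = inbreeding_f(gm, "P")
        assert per.loc[per["sample"] == "s0", "F"].iloc[0] == pytest.approx(1.0)

    def test_known_f_recovered(self, rng):
        """Genotypes drawn with IBD probability F = 0.3 recover F within 0.05."""
        n, m, f_true = 60, 4000, 0.3
        p = rng.uniform(0.1, 0.9, m)
        ibd = rng.random((n, m)) < f_true
        one = rng.binomial(1, p, size=(n, m))
        hwe = one + rng.binomial(1, p, size=(n, m))
        dos = np.where(ibd, 2 * one, hwe).astype(np.int8)
        gm = GenotypeMatrix(dos, [f"s{i}" for i in range(n)], {f"s{i}": "P" for i in range(n)})
        _, mean_f = inbreeding_f(gm, "P")
        assert abs(mean_f - f_true) < 0.05

    def test_too_few_sites_errors(self):
        gm = GenotypeMatrix(np.ones((3, 10), dtype=np.int8), list("abc"), dict.fromkeys("abc", "P"))
        with pytest.raises(ValueError):
            inbreeding_f(gm, "P")


class TestRohScan:
    def _gm(self, dosage_row):
        dos = np.asarray(dosage_row, dtype=np.int8)[None, :]
        return GenotypeMatrix(dos, ["s0"], {"s0": "P"})

    def test_all_homozygous_chromosome_single_segment(self):
        m = 500
        pos = np.arange(1, m + 1) * 10_000  # 5 Mb span
        out = roh_scan(self._gm([0] * m), make_vt(pos), "P", min_length_kb=1000)
        assert len(out) == 1
        assert out.iloc[0]["length_bp"] == pos[-1] - pos[0] + 1

    def test_alternating_hets_no_segment(self):
        m = 500
        pos = np.arange(1, m + 1) * 10_000
        dos = [1 if i % 2 else 0 for i in range(m)]
        out = roh_scan(self._gm(dos), make_vt(pos), "P", min_length_kb=100)
        assert len(out) == 0

    def test_matches_bruteforce_on_toy_haplotype(self, rng):
        m, w, max_het = 200, 25, 1
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=m, replace=False))
        dos = (rng.random(m) < 0.12).astype(np.int8)  # 0 = hom, 1 = het
        out = roh_scan(self._gm(dos), make_vt(pos), "P",
                       min_length_kb=50, window_sites=w, max_het_per_window=max_het)
        # brute force: site is ROH-compatible if a window covering it has <= max_het hets
        ok = np.zeros(m, bool)
        for s in range(m - w + 1):
            if dos[s:s + w].sum() <= max_het:
                ok[s:s + w] = True
        ok &= dos != 1
        segs = []
        start = None
        for i in range(m + 1):
            inside = i < m and ok[i]
            if inside and start is None:
                start = i
            if not inside and start is not None:
                if pos[i - 1] - pos[start] + 1 >= 50_000:
                    segs.append((int(pos[start]), int(pos[i - 1])))
                start = None
        assert [(r["start"], r["end"]) for _, r in out.iterrows()] == segs
        assert len(segs) > 0


class TestLdDecay:
    def test_perfectly_linked_pair_r2_one(self, rng):
        col = rng.binomial(2, 0.4, size=60).astype(np.int8)
        dos = np.stack([col, col], axis=1)
        gm = GenotypeMatrix(dos, [f"s{i}" for i in range(60)], {f"s{i}": "P" for i in range(60)})
        r2, dist, _, _ = pairwise_r2(gm, make_vt([100, 200]), "P", max_dist_bp=1000)
        assert r2[0] == pytest.approx(1.0)

    def test_independent_sites_at_noise_floor(self, rng):
        n, m = 100, 300
        dos = rng.binomial(2, 0.5, size=(n, m)).astype(np.int8)
        gm = GenotypeMatrix(dos, [f"s{i}" for i in range(n)], {f"s{i}": "P" for i in range(n)})
        pos = np.arange(1, m + 1) * 100
        r2, _, _, _ = pairwise_r2(gm, make_vt(pos), "P", max_dist_bp=5000, use_haplotypes=False)
        # E[r^2] for unlinked loci is ~1/n (dosage correlation bias level)
        assert abs(r2.mean() - 1 / n) < 3 / n

    def test_decay_length_monotone_in_ne(self):
        lengths = []
        for ne in (300, 2000, 10000):
            cfg = iso.SimConfig(
                ne_ancestral=ne, ne_ancient=ne, growth_gens=0, ne_general=ne, ne_isolate=ne,
                tdg_gens=0, mig=0, n_chroms=2, chrom_length_bp=3_000_000,
                n_genes_per_chrom=0, n_coding_sites_per_chrom=0, n_isolate=30, n_general=30,
                seed=55, missense_s_mean=0, lof_s_mean=0,
            )
            vt, gm, _ = iso.simulate_cohort_pair(cfg)
            length, profile, flagged = ld_decay_length(gm, vt, "ISO", r2_threshold=0.1, seed=0)
            lengths.append(length if not flagged else np.inf)
        assert lengths[0] >= lengths[1] >= lengths[2]
        assert lengths[0] > lengths[2]
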