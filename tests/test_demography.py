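"""LD-based demography, Delta Ancestry, admixture EM, Isx and correlations."""

import math

import numpy as np
import pandas as pd
import pytest

import isodrift as iso
from isodrift.demography import (
    NeTrajectory,
    admixture_em_k2,
    correlate_measures,
    delta_ancestry,
    estimate_tdg,
    isx,
    ne_from_ld,
    ne_from_r2,
    read_q_matrix,
)
from isodrift.types import CohortPair, GenotypeMatrix


class TestNeFromR2:
    def test_closed_form_example(self):
        assert ne_from_r2(0.0025, 0.1) == pytest.approx(800.0)

    def test_degenerate_inputs_dropped(self):
        assert math.isnan(ne_from_r2(0.005, 0.5))   # 1/r2 - 2 = 0 boundary
        assert math.isnan(ne_from_r2(0.005, -0.01))

    def test_time_index_is_inverse_distance(self):
        c = 0.0025
        assert 1 / (2 * c) == pytest.approx(200.0)


class TestNeRecovery:
    def test_constant_size_recent_bins_within_factor(self):
        """Constant-size coalescent (Ne = 1,000): recent-bin estimates
        within x1.5 of truth at the median over replicates."""
        medians = []
        for seed in range(4):
            cfg = iso.SimConfig(
                ne_ancestral=1000, ne_ancient=1000, growth_gens=0, ne_general=1000,
                ne_isolate=1000, tdg_gens=0, mig=0, n_chroms=2, chrom_length_bp=5_000_000,
                n_genes_per_chrom=0, n_coding_sites_per_chrom=0, n_isolate=25, n_general=25,
                seed=40 + seed, missense_s_mean=0, lof_s_mean=0,
            )
            vt, gm, _ = iso.simulate_cohort_pair(cfg)
            traj = ne_from_ld(gm, vt, "ISO", seed=1)
            recent = traj.table.sort_values("t").head(4)
            medians.append(recent["ne"].median())
        est = float(np.median(medians))
        assert 1000 / 1.5 < est < 1000 * 1.5


def traj_from(t, ne, half_width):
    ne = np.asarray(ne, float)
    return NeTrajectory(
        "P",
        pd.DataFrame(
            {
                "t": t,
                "c": 1 / (2 * np.asarray(t)),
                "ne": ne,
                "ne_low": ne * (1 - half_width),
                "ne_high": ne * (1 + half_width),
                "n_pairs": 1000,
            }
        ),
    )


class TestEstimateTdg:
    def test_identical_trajectories_flagged_zero(self):
        t = [800, 400, 200, 100, 50]
        a = traj_from(t, [5000] * 5, 0.2)
        tdg, flagged = estimate_tdg(a, traj_from(t, [5000] * 5, 0.2))
        assert tdg == 0.0 and flagged

    def test_constructed_split_at_100(self):
        t = [800, 400, 200, 100, 50]
        a = traj_from(t, [5000, 5000, 5000, 1000, 900], 0.2)
        b = traj_from(t, [5000, 5000, 5000, 5000, 5000], 0.2)
        tdg, flagged = estimate_tdg(a, b)
        assert tdg == 100 and not flagged

    def test_disjoint_grids_error(self):
        a = traj_from([800, 400], [1000, 1000], 0.2)
        b = traj_from([333, 111], [1000, 1000], 0.2)
        with pytest.raises(ValueError):
            estimate_tdg(a, b)

    def test_split_recovery_within_factor_two(self):
        """150-generation split recovered within x2 at the median."""
        ests = []
        for seed in range(6):
            cfg = iso.SimConfig(
                ne_ancestral=5000, ne_ancient=5000, growth_gens=0, ne_general=5000,
                ne_isolate=2000, tdg_gens=150, mig=0, n_chroms=2, chrom_length_bp=5_000_000,
                n_genes_per_chrom=0, n_coding_sites_per_chrom=0, n_isolate=40, n_general=40,
                seed=170 + seed, missense_s_mean=0, lof_s_mean=0,
            )
            vt, gm, _ = iso.simulate_cohort_pair(cfg)
            gm_min = iso.subsample_cohorts(gm, "minimum", seed=1)
            ti = ne_from_ld(gm_min, vt, "ISO", seed=1)
            tg = ne_from_ld(gm_min, vt, "GEN", seed=1)
            ests.append(estimate_tdg(ti, tg)[0])
        med = float(np.median(ests))
        assert 150 / 2 <= med <= 150 * 2


class TestDeltaAncestry:
    def _q(self, iso_mean, gen_mean, n=20):
        rows = {}
        for i in range(n):
            rows[f"i{i}"] = [iso_mean, 1 - iso_mean]
        for i in range(n):
            rows[f"g{i}"] = [gen_mean, 1 - gen_mean]
        return pd.DataFrame(rows).T

    def _pop_of(self, n=20):
        return {f"i{i}": "X" for i in range(n)} | {f"g{i}": "Y" for i in range(n)}

    def test_mean_difference(self):
        m = delta_ancestry(self._q(0.9, 0.4), self._pop_of(), CohortPair("X", "Y"))
        assert m == pytest.approx(0.5)

    def test_identical_distributions_zero(self):
        assert delta_ancestry(self._q(0.5, 0.5), self._pop_of(), CohortPair("X", "Y")) == pytest.approx(0.0)

    def test_component_relabeling_invariance(self):
        q = self._q(0.9, 0.4)
        swapped = q[[1, 0]].rename(columns={1: 0, 0: 1})
        pair = CohortPair("X", "Y")
        assert delta_ancestry(q, self._pop_of(), pair) == pytest.approx(
            delta_ancestry(swapped, self._pop_of(), pair)
        )

    def test_sample_order_invariance(self):
        q = self._q(0.8, 0.3)
        shuffled = q.sample(frac=1.0, random_state=3)
        pair = CohortPair("X", "Y")
        assert delta_ancestry(q, self._pop_of(), pair) == pytest.approx(
            delta_ancestry(shuffled, self._pop_of(), pair)
        )

    def test_k_not_two_errors(self):
        q = pd.DataFrame({0: [0.3], 1: [0.3], 2: [0.4]}, index=["i0"])
        with pytest.raises(ValueError, match="K"):
            delta_ancestry(q, {"i0": "X"}, CohortPair("X", "Y"))


class TestAdmixtureEm:
    def _gm_from(self, dos, n_iso):
        n = dos.shape[0]
        samples = [f"s{i}" for i in range(n)]
        pop_of = {s: ("X" if i < n_iso else "Y") for i, s in enumerate(samples)}
        return GenotypeMatrix(dos.astype(np.int8), samples, pop_of)

    def test_fully_diverged_sources_separate(self, rng):
        m = 400
        f1 = np.ones(m) * 0.98
        f2 = np.ones(m) * 0.02
        dos = np.concatenate([rng.binomial(2, f1, (15, m)), rng.binomial(2, f2, (15, m))])
        gm = self._gm_from(dos, 15)
        q, _ = admixture_em_k2(gm, CohortPair("X", "Y"), seed=0)
        m_hat = delta_ancestry(q, gm.pop_of, CohortPair("X", "Y"))
        assert m_hat > 0.9

    def test_panmictic_delta_near_zero(self, rng):
        m = 2000
        p = rng.uniform(0.2, 0.8, m)
        dos = rng.binomial(2, p, (30, m))
        gm = self._gm_from(dos, 15)
        q, _ = admixture_em_k2(gm, CohortPair("X", "Y"), seed=0)
        assert delta_ancestry(q, gm.pop_of, CohortPair("X", "Y")) < 0.15

    def test_admixed_q_recovery(self, rng):
        m = 1500
        f1 = rng.uniform(0.05, 0.95, m)
        f2 = np.clip(f1 + rng.normal(0, 0.25, m), 0.02, 0.98)
        q_true = np.concatenate([np.ones(20), np.zeros(20), np.full(20, 0.7)])
        dos = rng.binomial(2, np.outer(q_true, f1) + np.outer(1 - q_true, f2))
        gm = self._gm_from(dos, 40)
        q, converged = admixture_em_k2(gm, CohortPair("X", "Y"), seed=0)
        q_hat = q[0].to_numpy()
        err = min(np.abs(q_hat - q_true).mean(), np.abs(1 - q_hat - q_true).mean())
        assert err <= 0.1
        assert converged

    def test_too_few_sites_errors(self, rng):
        dos = rng.binomial(2, 0.5, (10, 50))
        with pytest.raises(ValueError):
            admixture_em_k2(self._gm_from(dos, 5))


class TestIsx:
    def test_arithmetic(self):
        assert isx(tdg=200, ne=1000, m=0.5) == pytest.approx(0.1)

    def test_no_private_ancestry_means_no_signal(self):
        assert isx(tdg=500, ne=100, m=0.0) == 0.0

    def test_monotonicities(self):
        base = isx(200, 1000, 0.5)
        assert isx(400, 1000, 0.5) == pytest.approx(2 * base)
        assert isx(200, 2000, 0.5) == pytest.approx(base / 2)
        assert isx(200, 1000, 1.0) == pytest.approx(2 * base)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            isx(100, 0, 0.5)
        with pytest.raises(ValueError):
            isx(100, 1000, 1.5)


class TestCorrelations:
    def test_identity_and_antisymmetry(self, rng):
        x = rng.normal(size=8)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": -x, "d": rng.normal(size=8)})
        r, p, flagged = correlate_measures(df)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert not flagged

    def test_constant_column_flagged(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=5), "k": np.ones(5)})
        r, p, flagged = correlate_measures(df)
        assert flagged == ["k"]
        assert np.isnan(r.loc["a", "k"])

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            correlate_measures(pd.DataFrame({"a": [1, 2]}))


class TestQMatrixIo:
    def test_round_trip_with_sample_order(self, tmp_path):
        qp = tmp_path / "t.2.Q"
        sp = tmp_path / "t.fam"
        qp.write_text("0.900000 0.100000\n0.200000 0.800000\n")
        sp.write_text("alice\nbob\n")
        q = read_q_matrix(qp, sp)
        assert list(q.index) == ["alice", "bob"]
        assert q.loc["alice", 0] == pytest.approx(0.9)

    def test_length_mismatch_errors(self, tmp_path):
        qp = tmp_path / "t.2.Q"
        sp = tmp_path / "t.fam"
        qp.write_text("0.9 0.1\n")
        sp.write_text("a\nb\n")
        with pytest.raises(ValueError):
            read_q_matrix(qp, sp)
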