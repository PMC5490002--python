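"""LD-based demography, Delta-Ancestry and the isolation index Isx.

Effective population size at time t = 1/(2c) generations before present
is inferred from mean r^2 between loci at recombination distance c
Morgans, after the finite-sample correction:

    r2_adj = mean r^2 - 1/n_chromosomes     (phased haplotypes)
             mean r^2 - 1/(2 n_individuals) (dosage-based r^2)
    Ne(t)  = (1 / (4 c)) * (1 / r2_adj - 2)

Divergence time Tdg between an isolate and its general population is
read off the two Ne(t) trajectories as the oldest time at which their
5-95% envelopes separate and stay separated to the present. Migration
is proxied inversely by Delta Ancestry (M): the difference in mean
ancestry component between the two populations under a two-component
admixture model. The isolation index combines the three:

    Isx = Tdg * M / Ne

higher for older splits, smaller recent Ne and more private ancestry.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import pairwise_r2
from .types import CohortPair, GenotypeMatrix, VariantTable

#: Default recombination-distance bins (Morgans): 0.025-1.0 cM,
#: log-spaced, indexing times 1/(2c) of ~2,000 down to 50 generations.
DEFAULT_C_BINS = np.geomspace(2.5e-4, 1.0e-2, 16)


def ne_from_r2(c_morgans: float, r2_adj: float) -> float:
    """Closed-form Ne from sample-corrected r^2 at distance c (Morgans).

    Ne = (1/(4c)) * (1/r2_adj - 2); e.g. r2_adj = 0.1 at c = 0.0025 M
    gives Ne = 100 * (10 - 2) = 800, indexing t = 1/(2c) = 200
    generations. Returns NaN when the corrected r^2 carries no drift
    signal (Ne would be non-positive).
    """
    if r2_adj <= 0:
        return math.nan
    inv = 1.0 / r2_adj - 2.0
    if inv <= 0:
        return math.nan
    return inv / (4.0 * c_morgans)


@dataclasses.dataclass
class NeTrajectory:
    """Ne(t) with per-bin median and 5-95% block envelope.

    ``table`` columns: t (generations before present), c (Morgans),
    ne (median over blocks), ne_low, ne_high, n_pairs.
    """

    population: str
    table: pd.DataFrame

    def harmonic_recent_ne(self, window_gens: float = 50.0) -> float:
        """Harmonic-mean Ne over bins within the recent window.

        Uses bins with t <= ``window_gens``; if the grid has none, the
        single most recent bin stands in.
        """
        tab = self.table.sort_values("t")
        recent = tab[tab["t"] <= window_gens]
        if recent.empty:
            recent = tab.iloc[:1]
        ne = recent["ne"].to_numpy()
        return float(len(ne) / np.sum(1.0 / ne))


def ne_from_ld(
    gm: GenotypeMatrix,
    vt: VariantTable,
    population: str,
    c_bins: np.ndarray = DEFAULT_C_BINS,
    cm_per_mb: float = 1.0,
    pairs_per_block: int = 75,
    max_pairs: int = 400_000,
    seed: int = 0,
) -> NeTrajectory:
    """LD-based Ne(t) trajectory for one population.

    Physical distance converts to Morgans through a constant
    ``cm_per_mb`` map. Within each c bin, locus pairs are grouped into
    small seeded blocks of ~``pairs_per_block`` pairs; Ne per block
    comes from the block's mean adjusted r^2, and the trajectory
    reports the median and 5th/95th percentiles over blocks — an
    across-loci envelope, so the interval reflects locus-level
    heterogeneity rather than just the standard error of the bin mean.
    Bins whose adjusted r^2 is non-positive (no drift signal above
    sampling noise) are dropped.
    """
    c_bins = np.asarray(c_bins, dtype=float)
    bp_per_morgan = 1e8 / cm_per_mb
    max_bp = int(c_bins[-1] * bp_per_morgan)
    min_bp = max(1, int(c_bins[0] * bp_per_morgan))
    use_hap = gm.haplotypes is not None
    r2, dist_bp, n_units, _ = pairwise_r2(
        gm, vt, population, max_dist_bp=max_bp, min_dist_bp=min_bp,
        max_pairs=max_pairs, seed=seed, use_haplotypes=use_hap,
    )
    if r2.size == 0:
        raise ValueError("no variant pairs in the requested distance range")
    correction = 1.0 / n_units if use_hap else 1.0 / (2 * n_units)
    c = dist_bp / bp_per_morgan
    which = np.digitize(c, c_bins) - 1
    rng = np.random.default_rng(seed + 1)
    rows = []
    for b in range(len(c_bins) - 1):
        sel = np.flatnonzero(which == b)
        n_blocks = int(np.clip(sel.size // pairs_per_block, 20, 400))
        if sel.size < 2 * n_blocks:
            continue
        block_of = rng.integers(0, n_blocks, size=sel.size)
        c_mid = float(c[sel].mean())
        ne_blocks = []
        for k in range(n_blocks):
            in_k = sel[block_of == k]
            if in_k.size == 0:
                continue
            ne_k = ne_from_r2(c_mid, float(r2[in_k].mean()) - correction)
            if not math.isnan(ne_k):
                ne_blocks.append(ne_k)
        if len(ne_blocks) < max(5, n_blocks // 2):
            continue
        ne_blocks = np.array(ne_blocks)
        rows.append(
            {
                "t": 1.0 / (2 * c_mid),
                "c": c_mid,
                "ne": float(np.percentile(ne_blocks, 50)),
                "ne_low": float(np.percentile(ne_blocks, 5)),
                "ne_high": float(np.percentile(ne_blocks, 95)),
                "n_pairs": int(sel.size),
            }
        )
    if not rows:
        raise ValueError("every distance bin was dropped (r2_adj <= 0 or too few pairs)")
    return NeTrajectory(population, pd.DataFrame(rows).sort_values("t", ascending=False).reset_index(drop=True))


def estimate_tdg(traj_isolate: NeTrajectory, traj_general: NeTrajectory, rtol: float = 1e-3):
    """Divergence time from the two trajectories' envelope separation.

    Scanning from the oldest shared bin toward the present, Tdg is the
    oldest time at which the two trajectories stop overlapping and
    remain separated through the most recent shared bin. Two bins are
    separated when each population's median Ne falls outside the
    other's 5-95% across-loci envelope (the envelopes themselves span
    locus-level heterogeneity, so full envelope-envelope disjointness
    would essentially never occur). Returns ``(tdg_generations,
    flagged)`` with ``flagged=True`` (Tdg 0) when the trajectories
    always overlap.
    """
    a = traj_isolate.table
    b = traj_general.table
    shared = []
    for _, ra in a.iterrows():
        match = b[np.isclose(b["t"], ra["t"], rtol=rtol)]
        if len(match):
            rb = match.iloc[0]
            a_med_inside = rb["ne_low"] <= ra["ne"] <= rb["ne_high"]
            b_med_inside = ra["ne_low"] <= rb["ne"] <= ra["ne_high"]
            overlap = a_med_inside or b_med_inside
            shared.append((float(ra["t"]), overlap))
    if not shared:
        raise ValueError("trajectories share no time bins")
    shared.sort(key=lambda x: x[0])  # youngest first
    tdg = 0.0
    for t, overlap in shared:
        if overlap:
            break
        tdg = t
    if tdg == 0.0:
        return 0.0, True
    return tdg, False


def read_q_matrix(q_path, sample_order_path) -> pd.DataFrame:
    """Read an ADMIXTURE-dialect .Q file with its parallel sample list.

    The Q file holds whitespace-delimited ancestry fractions, one row
    per sample in the order of ``sample_order_path`` (one sample ID per
    line, or the first column of a .fam-style file).
    """
    q = pd.read_csv(q_path, sep=r"\s+", header=None)
    with open(sample_order_path) as fh:
        samples = [line.split()[0] for line in fh if line.strip()]
    if len(samples) != len(q):
        raise ValueError("Q matrix rows and sample-order file length differ")
    q.index = samples
    return q


def delta_ancestry(q: pd.DataFrame, pop_of: dict[str, str], pair: CohortPair) -> float:
    """Delta Ancestry M from a K=2 ancestry matrix.

    Component 1 is the component with the higher isolate mean (so the
    value is invariant to component relabeling); M is the isolate-minus-
    general difference of its means, clipped into [0, 1].
    """
    if q.shape[1] != 2:
        raise ValueError(f"Delta Ancestry requires K=2, got K={q.shape[1]}")
    sums = q.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("Q rows must sum to 1")
    iso = [s for s in q.index if pop_of.get(s) == pair.isolate]
    gen = [s for s in q.index if pop_of.get(s) == pair.general]
    if not iso or not gen:
        raise ValueError("both populations must be present in the Q matrix")
    means_iso = q.loc[iso].mean(axis=0)
    comp = int(means_iso.idxmax())
    m = float(means_iso[comp] - q.loc[gen, comp].mean())
    return float(np.clip(m, 0.0, 1.0))


def admixture_em_k2(
    gm: GenotypeMatrix,
    pair: CohortPair | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    max_sites: int = 5000,
):
    """Lightweight K=2 admixture model fit by block-relaxation EM.

    Maximizes the standard admixture likelihood (individual dosage ~
    Binomial(2, q f1 + (1-q) f2)) jointly over per-individual ancestry
    fractions q and per-site component frequencies f1, f2. The
    log-likelihood is monotone non-decreasing per iteration; stops when
    the relative change falls below ``tol``. Returns ``(q_df,
    converged)`` where q_df has two columns indexed by sample.
    """
    dos = gm.dosages.astype(float)
    ok_sites = np.flatnonzero((dos.min(axis=0) >= 0) & (dos.std(axis=0) > 0))
    if ok_sites.size < 100:
        raise ValueError(f"need >= 100 polymorphic sites, have {ok_sites.size}")
    rng = np.random.default_rng(seed)
    if ok_sites.size > max_sites:
        ok_sites = np.sort(rng.choice(ok_sites, size=max_sites, replace=False))
    g = dos[:, ok_sites]
    n, m = g.shape
    # deliberately label-agnostic init: seeding q from the population
    # labels would project spurious structure onto them and inflate
    # Delta Ancestry on weakly diverged (or panmictic) pairs
    q = rng.uniform(0.3, 0.7, size=n)
    base = g.mean(axis=0) / 2.0
    f1 = np.clip(base + rng.uniform(-0.05, 0.05, size=m), 0.01, 0.99)
    f2 = np.clip(base + rng.uniform(-0.05, 0.05, size=m), 0.01, 0.99)

    def loglik(q, f1, f2):
        p = np.clip(np.outer(q, f1) + np.outer(1 - q, f2), 1e-9, 1 - 1e-9)
        return float(np.sum(g * np.log(p) + (2 - g) * np.log(1 - p)))

    ll_prev = loglik(q, f1, f2)
    converged = False
    for _ in range(max_iter):
        qf1 = np.outer(q, f1)
        qf2 = np.outer(1 - q, f2)
        a = qf1 / np.clip(qf1 + qf2, 1e-12, None)           # P(component 1 | alt allele)
        q1m = np.outer(q, 1 - f1)
        q2m = np.outer(1 - q, 1 - f2)
        b = q1m / np.clip(q1m + q2m, 1e-12, None)           # P(component 1 | ref allele)
        alt1 = g * a
        ref1 = (2 - g) * b
        q = np.clip((alt1 + ref1).sum(axis=1) / (2 * m), 1e-6, 1 - 1e-6)
        tot1 = alt1.sum(axis=0) + ref1.sum(axis=0)
        tot2 = 2 * n - tot1
        f1 = np.clip(alt1.sum(axis=0) / np.clip(tot1, 1e-12, None), 1e-6, 1 - 1e-6)
        f2 = np.clip((g - alt1).sum(axis=0) / np.clip(tot2, 1e-12, None), 1e-6, 1 - 1e-6)
        ll = loglik(q, f1, f2)
        if abs(ll - ll_prev) < tol * abs(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    q_df = pd.DataFrame({0: q, 1: 1 - q}, index=gm.samples)
    return q_df, converged


def isx(tdg: float, ne: float, m: float) -> float:
    """Isolation index: Isx = Tdg * M / Ne.

    Strictly increasing in divergence time and Delta Ancestry, strictly
    decreasing in recent effective size. Implemented behind this single
    function so an alternative functional form is a one-line change.
    """
    if ne <= 0:
        raise ValueError("ne must be positive")
    if tdg < 0:
        raise ValueError("tdg must be non-negative")
    if not 0 <= m <= 1:
        raise ValueError("m must lie in [0, 1]")
    return tdg * m / ne


GENERATION_YEARS = 29.0  # default generation time for year conversions


def generations_to_years(gens: float, generation_years: float = GENERATION_YEARS) -> float:
    return gens * generation_years


def correlate_measures(cohort_results: pd.DataFrame):
    """Pearson correlation matrix (r, p) across cohort measures.

    ``cohort_results``: rows = cohort pairs, columns = measures (Isx,
    DVxy, SVxy, FST, ...). Needs >= 3 rows; a constant column yields NaN
    with a flag. Returns ``(r_df, p_df, flagged_columns)``.
    """
    if len(cohort_results) < 3:
        raise ValueError("need at least 3 cohort pairs to correlate")
    cols = list(cohort_results.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    flagged = [c for c in cols if cohort_results[c].nunique() <= 1]
    for i, a in enumerate(cols):
        for b in cols[i:]:
            if a in flagged or b in flagged:
                continue
            x = cohort_results[a].to_numpy(float)
            y = cohort_results[b].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                continue
            rr, pp = stats.pearsonr(x[ok], y[ok])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p, flagged
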