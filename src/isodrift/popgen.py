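"""Standard isolation-correlated measures with explicit estimators.

Genome-wide pairwise FST (Hudson ratio-of-sums, with Weir-Cockerham as
an alternative), method-of-moments inbreeding F, a PLINK-style sliding
runs-of-homozygosity scan, and an LD-decay-length proxy from mean r^2
per physical-distance bin. All four rise as a population becomes more
isolated (smaller Ne, stronger drift), which is what the isolation
index is later correlated against.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .types import CohortPair, FrequencyTable, GenotypeMatrix, VariantTable


def hudson_fst(ft: FrequencyTable, pair: CohortPair, estimator: str = "hudson"):
    """Genome-wide FST between the pair, ratio-of-sums over sites.

    Hudson estimator per site (haploid sample sizes n1, n2; allele
    frequencies p1, p2):

        num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)

    Returns ``(fst, per_site)`` where per_site is a DataFrame of the
    numerators and denominators. Sites monomorphic in the pooled pair
    contribute nothing; with no polymorphic site FST is NaN (flagged).
    """
    if estimator not in ("hudson", "wc"):
        raise ValueError("estimator must be 'hudson' or 'wc'")
    p1 = ft.af_of(pair.isolate)
    p2 = ft.af_of(pair.general)
    n1 = ft.called_of(pair.isolate).astype(float)
    n2 = ft.called_of(pair.general).astype(float)
    ok = (n1 > 1) & (n2 > 1) & ~(np.isnan(p1) | np.isnan(p2))
    poly = ok & ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    p1, p2, n1, n2 = p1[poly], p2[poly], n1[poly], n2[poly]
    if p1.size == 0:
        return float("nan"), pd.DataFrame({"num": [], "den": []})
    if estimator == "hudson":
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    else:  # Weir & Cockerham (1984), two populations, no within-individual term
        nbar = (n1 + n2) / 2
        r = 2.0
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        num, den = a, a + b
    per_site = pd.DataFrame({"num": num, "den": den}, index=np.flatnonzero(poly))
    total_den = float(den.sum())
    fst = float(num.sum() / total_den) if total_den > 0 else float("nan")
    return fst, per_site


def inbreeding_f(gm: GenotypeMatrix, population: str, min_sites: int = 50):
    """Per-individual and mean method-of-moments inbreeding coefficient.

    F_i = 1 - observed_het_i / expected_het_i, with expected
    heterozygosity summed from that population's allele frequencies
    (2p(1-p) per site). Monomorphic sites are skipped.
    """
    idx = gm.pop_indices(population)
    dos = gm.dosages[idx].astype(float)
    dos[dos < 0] = np.nan
    p = np.nanmean(dos, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < min_sites:
        raise ValueError(f"need >= {min_sites} polymorphic sites, have {int(poly.sum())}")
    d = dos[:, poly]
    exp_het = 2 * p[poly] * (1 - p[poly])
    obs = np.nansum(d == 1, axis=1).astype(float)
    denom = np.array([exp_het[~np.isnan(row)].sum() for row in d])
    f = 1.0 - obs / denom
    samples = [gm.samples[i] for i in idx]
    per = pd.DataFrame({"sample": samples, "F": f})
    return per, float(np.mean(f))


@dataclasses.dataclass
class RohSegment:
    sample: str
    chrom: str
    start: int
    end: int
    n_sites: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def roh_scan(
    gm: GenotypeMatrix,
    vt: VariantTable,
    population: str,
    min_length_kb: float = 1000.0,
    window_sites: int = 50,
    max_het_per_window: int = 1,
) -> pd.DataFrame:
    """PLINK-like sliding-window runs-of-homozygosity scan.

    Per individual and chromosome, a site belongs to a candidate run if
    at least one ``window_sites``-site window covering it contains at
    most ``max_het_per_window`` heterozygous calls; maximal runs of such
    sites with length >= ``min_length_kb`` are reported. Returns one row
    per segment plus (sample-level) totals via groupby downstream.
    """
    idx = gm.pop_indices(population)
    chrom = vt.chrom
    pos = vt.pos
    segments: list[RohSegment] = []
    for i in idx:
        sample = gm.samples[i]
        row = gm.dosages[i]
        for c in dict.fromkeys(chrom):
            sel = np.flatnonzero(chrom == c)
            het = (row[sel] == 1).astype(int)
            m = len(sel)
            w = min(window_sites, m)
            # site is "ROH-compatible" if some window containing it has <= max_het hets
            csum = np.concatenate([[0], np.cumsum(het)])
            win_ok = np.array([csum[s + w] - csum[s] <= max_het_per_window for s in range(m - w + 1)])
            ok = np.zeros(m, dtype=bool)
            for s in np.flatnonzero(win_ok):
                ok[s:s + w] = True
            ok &= row[sel] != 1  # a het site itself never belongs to the run
            # maximal runs of ok sites
            d = np.diff(np.concatenate([[0], ok.astype(int), [0]]))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1) - 1
            for s, e in zip(starts, ends):
                seg = RohSegment(sample, str(c), int(pos[sel[s]]), int(pos[sel[e]]), int(e - s + 1))
                if seg.length_bp >= min_length_kb * 1000:
                    segments.append(seg)
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "length_bp": s.length_bp,
                "n_sites": s.n_sites,
            }
            for s in segments
        ],
        columns=["sample", "chrom", "start", "end", "length_bp", "n_sites"],
    )


def roh_totals(roh: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Per-individual total ROH length (Mb) and segment count."""
    out = pd.DataFrame({"sample": samples}).set_index("sample")
    out["total_mb"] = 0.0
    out["n_roh"] = 0
    if len(roh):
        g = roh.groupby("sample")
        out.loc[g.size().index, "n_roh"] = g.size()
        out.loc[g.size().index, "total_mb"] = g["length_bp"].sum() / 1e6
    return out.reset_index()


def _standardize(mat: np.ndarray) -> np.ndarray:
    x = mat.astype(float)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    return x / sd


def pairwise_r2(
    gm: GenotypeMatrix,
    vt: VariantTable,
    population: str,
    max_dist_bp: int,
    min_dist_bp: int = 1,
    max_pairs: int = 200_000,
    min_maf: float = 0.05,
    seed: int = 0,
    use_haplotypes: bool = True,
):
    """All (thinned) pairwise r^2 within a distance window, per population.

    Uses phased haplotype correlation when haplotypes are available,
    otherwise the composite (Rogers-Huff) dosage correlation. Returns
    ``(r2, dist_bp, n_chromosomes_sampled, chrom_of_pair)`` arrays,
    down-sampled to ``max_pairs`` pairs (seeded) for tractability.
    """
    idx = gm.pop_indices(population)
    if use_haplotypes and gm.haplotypes is not None:
        rows = np.column_stack([2 * idx, 2 * idx + 1]).ravel()
        mat = gm.haplotypes[rows]
        n_units = len(rows)
    else:
        mat = gm.dosages[idx]
        n_units = len(idx)
    freq = mat.mean(axis=0) / (1 if (use_haplotypes and gm.haplotypes is not None) else 2)
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= min_maf
    mat = mat[:, keep]
    pos = vt.pos[keep]
    chrom = vt.chrom[keep]
    z = _standardize(mat)
    pairs_i, pairs_j = [], []
    for c in dict.fromkeys(chrom):
        sel = np.flatnonzero(chrom == c)
        p = pos[sel]
        hi = np.searchsorted(p, p + max_dist_bp, side="right")
        lo = np.searchsorted(p, p + min_dist_bp, side="left")
        for k in range(len(sel)):
            if hi[k] > lo[k]:
                js = sel[lo[k]:hi[k]]
                pairs_i.append(np.full(len(js), sel[k]))
                pairs_j.append(js)
    if not pairs_i:
        return np.array([]), np.array([]), n_units, np.array([])
    pi = np.concatenate(pairs_i)
    pj = np.concatenate(pairs_j)
    if len(pi) > max_pairs:
        rng = np.random.default_rng(seed)
        take = rng.choice(len(pi), size=max_pairs, replace=False)
        pi, pj = pi[take], pj[take]
    r = np.einsum("ni,ni->i", z[:, pi], z[:, pj]) / z.shape[0]
    r2 = r**2
    dist = (pos[pj] - pos[pi]).astype(float)
    good = ~np.isnan(r2)
    return r2[good], dist[good], n_units, chrom[pi[good]]


def ld_decay_length(
    gm: GenotypeMatrix,
    vt: VariantTable,
    population: str,
    r2_threshold: float = 0.1,
    bins_kb: np.ndarray | None = None,
    seed: int = 0,
):
    """Distance (kb) at which mean r^2 first drops below a threshold.

    Mean r^2 is computed per physical-distance bin; the decay length is
    the midpoint of the smallest-distance bin whose mean is below
    ``r2_threshold``. If no bin falls below it, the largest bin midpoint
    is returned with ``flagged=True``.
    """
    if bins_kb is None:
        bins_kb = np.array([0, 10, 25, 50, 100, 200, 400, 800, 1500], dtype=float)
    r2, dist, _, _ = pairwise_r2(gm, vt, population, max_dist_bp=int(bins_kb[-1] * 1000), seed=seed)
    if r2.size == 0:
        raise ValueError("no variant pairs within the distance bins")
    edges = bins_kb * 1000.0
    which = np.digitize(dist, edges) - 1
    mids, means = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.sum() >= 2:
            mids.append((bins_kb[b] + bins_kb[b + 1]) / 2)
            means.append(float(r2[sel].mean()))
    profile = pd.DataFrame({"dist_mid_kb": mids, "mean_r2": means})
    below = profile[profile["mean_r2"] < r2_threshold]
    if len(below):
        return float(below["dist_mid_kb"].iloc[0]), profile, False
    return float(profile["dist_mid_kb"].iloc[-1]), profile, True
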