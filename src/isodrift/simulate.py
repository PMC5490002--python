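"""Seeded generator of isolate/general cohort pairs with known truth.

The generator emulates the data regime every statistic in this package
was designed for: two diploid populations that split ``tdg_gens``
generations ago with symmetric migration ``mig``, an isolate bottleneck
(small ``ne_isolate``), neutral intergenic variation, and genic variation
(synonymous neutral; missense/LoF under purifying selection) annotated
with pseudo-CADD scores correlated with deleteriousness.

Mechanism (hybrid, documented in the methods note):

* Intergenic sites come from an msprime coalescent simulation of the
  split-with-migration demography, so they carry realistic linkage
  disequilibrium for the LD-based statistics (Ne(t), Tdg, LD decay, ROH).
* Genic sites are simulated as independent loci: ancestral standing
  variation is drawn from a growth-skewed x^-gamma frequency spectrum,
  reweighted toward mutation-selection balance for deleterious classes,
  then propagated forward through ``tdg_gens`` Wright-Fisher generations
  of deterministic selection, symmetric migration, binomial drift (with
  a founder-event epoch when configured) and per-generation new-mutation
  input in each daughter population. Genotypes are sampled under HWE.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import msprime
import numpy as np
import pandas as pd

from .types import GenotypeMatrix, VariantTable

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class SimConfig:
    """Generating parameters of one synthetic isolate/general pair."""

    # demography (diploid sizes, generations)
    ne_ancestral: float = 10_000.0   # modern (post-expansion) ancestral size
    ne_ancient: float = 2_000.0      # pre-expansion ancestral size
    growth_gens: int = 600           # time of the ancestral expansion (generations ago)
    ne_general: float = 10_000.0
    ne_isolate: float = 1_000.0
    ne_founder: float | None = None  # founder-event size right after the split
    founder_gens: int = 15           # duration of the founder event (generations)
    tdg_gens: int = 170
    mig: float = 1e-3
    # mutation / recombination
    mu: float = 1.2e-8
    rec: float = 1e-8
    cm_per_mb: float = 1.0
    # genome layout
    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000
    n_genes_per_chrom: int = 40
    gene_length_bp: int = 20_000
    n_coding_sites_per_chrom: int = 12_000  # candidate genic loci before filtering
    coding_props: tuple[float, float, float] = (0.65, 0.05, 0.30)  # missense, lof, synonymous
    # selection (gamma-distributed coefficients; mean 0 switches a class off)
    missense_s_mean: float = 0.03
    missense_s_shape: float = 0.25
    lof_s_mean: float = 0.2
    lof_s_shape: float = 0.5
    coding_mut_scale: float = 1.0  # scaling of post-split genic mutation input
    essential_frac: float = 0.2
    essential_s_multiplier: float = 2.0
    # samples
    n_isolate: int = 40
    n_general: int = 60
    isolate_label: str = "ISO"
    general_label: str = "GEN"
    # bookkeeping
    flip_frac: float = 0.1          # fraction of sites written with ALT as the ancestral allele
    unknown_anc_frac: float = 0.02  # fraction of sites with unknown ancestral state
    spectrum_exponent: float = 2.0  # standing-variation SFS ~ x^-gamma (growth-skewed for gamma > 1)
    seed: int = 0

    def validate(self) -> None:
        if min(self.ne_ancestral, self.ne_general, self.ne_isolate) <= 0:
            raise ValueError("effective sizes must be positive")
        if self.tdg_gens < 0:
            raise ValueError("tdg_gens must be >= 0")
        if not 0 <= self.mig <= 0.5:
            raise ValueError("mig must lie in [0, 0.5]")
        if min(self.mu, self.rec) < 0:
            raise ValueError("rates must be non-negative")
        if self.n_isolate > 2 * self.ne_isolate or self.n_general > 2 * self.ne_general:
            raise ValueError("sample size exceeds 2*Ne; infeasible config")
        if self.ne_founder is not None:
            if self.ne_founder <= 0:
                raise ValueError("ne_founder must be positive")
            if self.founder_gens < 0 or self.founder_gens > self.tdg_gens:
                raise ValueError("founder_gens must lie in [0, tdg_gens]")
        if abs(sum(self.coding_props) - 1.0) > 1e-9:
            raise ValueError("coding_props must sum to 1")


@dataclasses.dataclass
class SimTruth:
    """Realized generating truth of one synthetic cohort pair."""

    config: SimConfig
    s: np.ndarray                     # per-variant selection coefficient (0 for neutral)
    origin: np.ndarray                # "coalescent" or "forward" per variant
    birth_x: np.ndarray               # post-split origin generation in the isolate (0 = standing)
    birth_y: np.ndarray               # post-split origin generation in the general pop (0 = standing)
    essential_genes: list[str]
    expected_fst_island: float        # two-deme equilibrium Hudson-FST expectation 1/(1+8Nm)

    def pseudo_cadd_association(self, vt: VariantTable) -> float:
        """Spearman rho between |s| and pseudo-CADD over deleterious classes."""
        from scipy import stats

        mask = np.isin(vt.consequence, ["missense", "lof"])
        if mask.sum() < 10:
            return float("nan")
        rho, _ = stats.spearmanr(np.abs(self.s[mask]), vt.cadd[mask])
        return float(rho)


def neutral_symmetric_config(**overrides) -> SimConfig:
    """Null-calibration conditions: equal demography, no selection."""
    cfg = SimConfig(
        ne_ancestral=5_000.0,
        ne_general=5_000.0,
        ne_isolate=5_000.0,
        tdg_gens=170,
        mig=1e-3,
        missense_s_mean=0.0,
        lof_s_mean=0.0,
        n_isolate=40,
        n_general=40,
    )
    return dataclasses.replace(cfg, **overrides)


def bottleneck_selected_config(**overrides) -> SimConfig:
    """Headline conditions: isolate founded by a severe founder event
    (brief, small founder size, then moderate Ne) with purifying
    selection on missense/LoF sites — the demographic regime of a
    genetically isolated population next to a large general one."""
    cfg = SimConfig(
        ne_ancestral=10_000.0,
        ne_general=10_000.0,
        ne_isolate=1_500.0,
        ne_founder=200.0,
        founder_gens=25,
        tdg_gens=200,
        mig=5e-4,
    )
    return dataclasses.replace(cfg, **overrides)


def _gene_layout(cfg: SimConfig) -> dict[str, list[tuple[str, int, int]]]:
    """Evenly spaced gene intervals (name, start, end) per chromosome."""
    layout = {}
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        genes = []
        if cfg.n_genes_per_chrom == 0:
            layout[chrom] = genes
            continue
        pitch = cfg.chrom_length_bp / cfg.n_genes_per_chrom
        for g in range(cfg.n_genes_per_chrom):
            mid = int((g + 0.5) * pitch)
            start = max(1, mid - cfg.gene_length_bp // 2)
            genes.append((f"{chrom}_G{g + 1:03d}", start, start + cfg.gene_length_bp - 1))
        layout[chrom] = genes
    return layout


def _simulate_neutral_chrom(cfg: SimConfig, seed: int):
    """msprime backbone for one chromosome: positions + 0/1 haplotypes."""
    if cfg.tdg_gens > 0:
        demog = msprime.Demography()
        demog.add_population(name="ISO", initial_size=cfg.ne_isolate)
        demog.add_population(name="GEN", initial_size=cfg.ne_general)
        demog.add_population(name="ANC", initial_size=cfg.ne_ancestral)
        if cfg.mig > 0:
            demog.set_symmetric_migration_rate(["ISO", "GEN"], cfg.mig)
        if cfg.ne_founder is not None and cfg.founder_gens > 0:
            demog.add_population_parameters_change(
                time=cfg.tdg_gens - cfg.founder_gens, population="ISO", initial_size=cfg.ne_founder
            )
        demog.add_population_split(time=cfg.tdg_gens, derived=["ISO", "GEN"], ancestral="ANC")
        if cfg.growth_gens > cfg.tdg_gens:
            demog.add_population_parameters_change(
                time=cfg.growth_gens, population="ANC", initial_size=cfg.ne_ancient
            )
        demog.sort_events()
        samples = {"ISO": cfg.n_isolate, "GEN": cfg.n_general}
    else:
        demog = msprime.Demography()
        demog.add_population(name="ANC", initial_size=cfg.ne_ancestral)
        if cfg.growth_gens > 0:
            demog.add_population_parameters_change(
                time=cfg.growth_gens, population="ANC", initial_size=cfg.ne_ancient
            )
        samples = {"ANC": cfg.n_isolate + cfg.n_general}
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demog,
        sequence_length=cfg.chrom_length_bp,
        recombination_rate=cfg.rec,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(ts, rate=cfg.mu, random_seed=seed + 1, model=msprime.BinaryMutationModel())
    geno = mts.genotype_matrix()  # sites x haplotypes
    pos = np.array([int(s.position) for s in mts.sites()])
    biallelic = geno.max(axis=1) <= 1
    geno, pos = geno[biallelic], pos[biallelic]
    _, first = np.unique(pos, return_index=True)
    return pos[first], geno[first].astype(np.int8)


def _ancestral_spectrum(
    n: int,
    rng: np.random.Generator,
    gamma: float = 2.0,
    x_min: float = 1e-4,
    x_max: float = 0.9,
) -> np.ndarray:
    """Draws from an x^-gamma standing-variation frequency spectrum.

    gamma = 1 is the constant-size neutral equilibrium (1/x); gamma > 1
    adds the excess of ultra-rare variation left by a recent population
    expansion, matching the expansion epoch of the coalescent backbone.
    """
    u = rng.random(n)
    if abs(gamma - 1.0) < 1e-9:
        return x_min * (x_max / x_min) ** u
    a = 1.0 - gamma
    return (x_min**a + u * (x_max**a - x_min**a)) ** (1.0 / a)


def _forward_frequencies(
    p0: np.ndarray,
    s: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    birth_x: np.ndarray | None = None,
    birth_y: np.ndarray | None = None,
):
    """Wright-Fisher propagation of independent loci through the split.

    Standing variants start at ``p0`` in both daughter populations; a
    site with ``birth_x[i] == g`` (1-based generation after the split)
    instead enters population x as a single copy at generation g (and
    symmetrically for ``birth_y``) — the post-split mutational input
    without which an isolate would only ever lose rare variation.
    Each generation applies deterministic additive selection
    (heterozygote fitness 1 - s/2), symmetric migration, then binomial
    drift with 2*Ne chromosomes per population.
    """
    px = p0.copy()
    py = p0.copy()
    nx_by_gen = isolate_chrom_sizes(cfg)
    ny = int(round(2 * cfg.ne_general))
    if birth_x is not None:
        px[birth_x > 0] = 0.0
        py[birth_x > 0] = 0.0
        px[birth_y > 0] = 0.0
        py[birth_y > 0] = 0.0
    w = 1.0 - s / 2.0
    for g in range(1, cfg.tdg_gens + 1):
        nx = nx_by_gen[g - 1]
        if birth_x is not None:
            px[birth_x == g] = 1.0 / nx
            py[birth_y == g] = 1.0 / ny
        px = px * w / (1.0 - px * s / 2.0)
        py = py * w / (1.0 - py * s / 2.0)
        if cfg.mig > 0:
            px, py = (1 - cfg.mig) * px + cfg.mig * py, (1 - cfg.mig) * py + cfg.mig * px
        px = rng.binomial(nx, px) / nx
        py = rng.binomial(ny, py) / ny
    return px, py


def isolate_chrom_sizes(cfg: SimConfig) -> np.ndarray:
    """2N of the isolate per post-split generation (founder phase first)."""
    nx = np.full(max(cfg.tdg_gens, 1), int(round(2 * cfg.ne_isolate)), dtype=np.int64)
    if cfg.ne_founder is not None and cfg.founder_gens > 0:
        nx[: cfg.founder_gens] = int(round(2 * cfg.ne_founder))
    return nx


def _pseudo_cadd(s: np.ndarray, neutral: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-CADD scores: a CADD-like baseline plus a monotone |s| signal.

    Sites without a selection signal (neutral classes, or deleterious
    classes with s = 0) draw from a genome-like baseline mixture that
    populates all four score strata (mostly 0-5, thinning towards >20),
    mimicking that a deleteriousness score assigns high values to some
    neutral sites too. Sites under selection score
    ``12 * log10(1 + |s| / 1e-4) + N(0, 2)``, clipped to [0, 50], which
    is monotone in |s| up to noise.
    """
    cadd = np.empty(len(s))
    n_neu = int(neutral.sum())
    stratum = rng.choice(4, size=n_neu, p=[0.70, 0.15, 0.10, 0.05])
    lows = np.array([0.0, 5.0, 10.0, 20.0])
    highs = np.array([4.99, 9.99, 19.99, 35.0])
    cadd[neutral] = lows[stratum] + rng.random(n_neu) * (highs[stratum] - lows[stratum])
    sel = ~neutral
    cadd[sel] = np.clip(
        12.0 * np.log10(1.0 + np.abs(s[sel]) / 1e-4) + rng.normal(0, 2.0, size=int(sel.sum())),
        0,
        50,
    )
    return cadd


def simulate_cohort_pair(cfg: SimConfig):
    """Simulate one isolate/general pair.

    Returns ``(VariantTable, GenotypeMatrix, SimTruth)``. The genotype
    matrix carries phased haplotypes; variants are annotated with gene,
    consequence class and pseudo-CADD; ``SimTruth`` records per-variant
    selection coefficients and the essential-gene list.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = _gene_layout(cfg)
    genes_all = [name for genes in layout.values() for name, _, _ in genes]
    if genes_all:
        n_ess = max(1, int(cfg.essential_frac * len(genes_all)))
        essential = sorted(rng.choice(genes_all, size=n_ess, replace=False).tolist())
    else:
        essential = []
    essential_set = set(essential)

    n_total = cfg.n_isolate + cfg.n_general
    chrom_names, positions, hap_cols = [], [], []
    cons_list, gene_list, s_list, origin_list = [], [], [], []
    bx_list, by_list = [], []

    class_names = np.array(["missense", "lof", "synonymous"])
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        ms_seed = int(rng.integers(1, 2**31 - 2))
        pos_n, hap_n = _simulate_neutral_chrom(cfg, ms_seed)
        genes = layout[chrom]
        gstart = np.array([s for _, s, _ in genes])
        gend = np.array([e for _, _, e in genes])
        gnames = np.array([n for n, _, _ in genes])

        def gene_of(p: np.ndarray):
            gi = np.searchsorted(gstart, p, side="right") - 1
            gi = np.clip(gi, 0, len(genes) - 1)
            inside = (p >= gstart[gi]) & (p <= gend[gi])
            return np.where(inside, gnames[gi], "")

        if genes:
            g_n = gene_of(pos_n)
        else:
            g_n = np.full(len(pos_n), "", dtype=object)
        cons_n = np.where(g_n == "", "intergenic", "other")

        # genic forward-simulated loci: ancestral standing variation ...
        m0 = cfg.n_coding_sites_per_chrom if genes else 0
        p0 = _ancestral_spectrum(m0, rng, cfg.spectrum_exponent)
        # ... plus post-split new mutations in each daughter population,
        # Poisson with the genic mutational target of that population
        l_cod = len(genes) * cfg.gene_length_bp
        per_copy = cfg.mu * cfg.coding_mut_scale * l_cod
        nx_by_gen = isolate_chrom_sizes(cfg)[: cfg.tdg_gens]
        m_x = rng.poisson(per_copy * nx_by_gen.sum()) if cfg.tdg_gens > 0 else 0
        m_y = rng.poisson(per_copy * 2 * cfg.ne_general * cfg.tdg_gens) if cfg.tdg_gens > 0 else 0
        m = m0 + m_x + m_y
        birth_x = np.zeros(m, dtype=np.int64)
        birth_y = np.zeros(m, dtype=np.int64)
        if cfg.tdg_gens > 0:
            gen_w = nx_by_gen / nx_by_gen.sum()
            birth_x[m0:m0 + m_x] = rng.choice(np.arange(1, cfg.tdg_gens + 1), size=m_x, p=gen_w)
            birth_y[m0 + m_x:] = rng.integers(1, cfg.tdg_gens + 1, size=m_y)
        p0 = np.concatenate([p0, np.zeros(m_x + m_y)])

        cls = rng.choice(class_names, size=m, p=list(cfg.coding_props))
        gi = rng.integers(0, max(len(genes), 1), size=m)
        pos_f = gstart[gi] + rng.integers(0, cfg.gene_length_bp, size=m)
        s = np.zeros(m)
        for name, mean, shape in (
            ("missense", cfg.missense_s_mean, cfg.missense_s_shape),
            ("lof", cfg.lof_s_mean, cfg.lof_s_shape),
        ):
            sel = cls == name
            if mean > 0:
                s[sel] = rng.gamma(shape, mean / shape, size=int(sel.sum()))
        ess_site = np.isin(gnames[gi], list(essential_set))
        s = np.where(ess_site & (s > 0), np.minimum(s * cfg.essential_s_multiplier, 0.5), s)
        s = np.minimum(s, 0.5)

        # mutation-selection reweighting of the ancestral standing variation
        standing = birth_x + birth_y == 0
        accept = ~standing | (rng.random(m) < np.exp(-2.0 * cfg.ne_ancestral * s * p0))
        cls, gi, pos_f, s, p0 = cls[accept], gi[accept], pos_f[accept], s[accept], p0[accept]
        birth_x, birth_y = birth_x[accept], birth_y[accept]
        px, py = _forward_frequencies(p0, s, cfg, rng, birth_x, birth_y)
        # phased genotype draws under HWE
        m_f = len(px)
        hap_f = np.empty((2 * n_total, m_f), dtype=np.int8)
        hap_f[: 2 * cfg.n_isolate] = rng.random((2 * cfg.n_isolate, m_f)) < px
        hap_f[2 * cfg.n_isolate:] = rng.random((2 * cfg.n_general, m_f)) < py

        # merge, drop duplicate/colliding positions and monomorphic sites
        pos_all = np.concatenate([pos_n, pos_f])
        hap_all = np.concatenate([hap_n, hap_f.T], axis=0)  # sites x haplotypes
        cons_all = np.concatenate([cons_n, cls])
        gene_all = np.concatenate([g_n, gnames[gi]])
        s_all = np.concatenate([np.zeros(len(pos_n)), s])
        origin_all = np.concatenate([np.full(len(pos_n), "coalescent"), np.full(m_f, "forward")])
        bx_all = np.concatenate([np.zeros(len(pos_n), dtype=np.int64), birth_x])
        by_all = np.concatenate([np.zeros(len(pos_n), dtype=np.int64), birth_y])

        order = np.argsort(pos_all, kind="stable")
        pos_all, hap_all = pos_all[order], hap_all[order]
        cons_all, gene_all, s_all, origin_all = cons_all[order], gene_all[order], s_all[order], origin_all[order]
        bx_all, by_all = bx_all[order], by_all[order]
        uniq = np.concatenate([[True], np.diff(pos_all) > 0])
        seg = hap_all.sum(axis=1)
        keep = uniq & (seg > 0) & (seg < hap_all.shape[1])
        pos_all, hap_all = pos_all[keep], hap_all[keep]
        cons_all, gene_all, s_all, origin_all = cons_all[keep], gene_all[keep], s_all[keep], origin_all[keep]
        bx_all, by_all = bx_all[keep], by_all[keep]

        chrom_names.append(np.full(len(pos_all), chrom))
        positions.append(pos_all + 1)  # 1-based coordinates
        hap_cols.append(hap_all)
        cons_list.append(cons_all)
        gene_list.append(gene_all)
        s_list.append(s_all)
        origin_list.append(origin_all)
        bx_list.append(bx_all)
        by_list.append(by_all)

    chrom_arr = np.concatenate(chrom_names)
    pos_arr = np.concatenate(positions)
    hap = np.concatenate(hap_cols, axis=0).T  # haplotypes x variants
    cons = np.concatenate(cons_list)
    gene = np.concatenate(gene_list)
    s_arr = np.concatenate(s_list)
    origin = np.concatenate(origin_list)
    V = len(pos_arr)

    # allele strings and ancestral bookkeeping
    ref_idx = rng.integers(0, 4, size=V)
    alt_shift = rng.integers(1, 4, size=V)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]
    flip = rng.random(V) < cfg.flip_frac
    # at flipped sites the derived allele is written as REF
    hap[:, flip] = 1 - hap[:, flip]
    ref[flip], alt[flip] = alt[flip].copy(), ref[flip].copy()
    ancestral = np.where(flip, alt, ref)
    unknown = rng.random(V) < cfg.unknown_anc_frac
    ancestral = np.where(unknown, "", ancestral)

    neutral_mask = ~np.isin(cons, ["missense", "lof"]) | (s_arr == 0)
    cadd = _pseudo_cadd(s_arr, neutral_mask, rng)

    vt = VariantTable(
        pd.DataFrame(
            {
                "chrom": chrom_arr,
                "pos": pos_arr,
                "ref": ref,
                "alt": alt,
                "ancestral": ancestral,
                "gene": gene,
                "consequence": cons,
                "cadd": cadd,
            }
        )
    )
    samples = [f"{cfg.isolate_label}_{i:03d}" for i in range(cfg.n_isolate)] + [
        f"{cfg.general_label}_{i:03d}" for i in range(cfg.n_general)
    ]
    pop_of = {s: (cfg.isolate_label if s.startswith(cfg.isolate_label) else cfg.general_label) for s in samples}
    dosages = hap[0::2] + hap[1::2]
    gm = GenotypeMatrix(dosages, samples, pop_of, hap)
    n_harm = 2.0 / (1.0 / cfg.ne_isolate + 1.0 / cfg.ne_general)
    expected_fst = 1.0 / (1.0 + 8.0 * n_harm * cfg.mig) if cfg.mig > 0 else float("nan")
    truth = SimTruth(cfg, s_arr, origin, np.concatenate(bx_list), np.concatenate(by_list), essential, expected_fst)
    return vt, gm, truth


def assign_annotations(vt: VariantTable, truth: SimTruth, seed: int | None = None) -> VariantTable:
    """Re-draw pseudo-CADD scores from the recorded selection truth.

    Provided for regenerating annotation columns on an existing table
    (e.g., after subsetting); class/gene assignment is positional and
    already fixed by the simulation.
    """
    rng = np.random.default_rng(truth.config.seed if seed is None else seed)
    neutral = ~np.isin(vt.consequence, ["missense", "lof"]) | (truth.s == 0)
    df = vt.df.copy()
    df["cadd"] = _pseudo_cadd(truth.s, neutral, rng)
    return VariantTable(df)


def make_cohort_panel(base_cfg: SimConfig, n_cohorts: int = 8, seed: int = 0):
    """A gradient of cohort pairs with monotonically increasing isolation.

    Cohort i has a linearly increasing split time and geometrically
    decreasing isolate Ne and migration rate, so the generating
    isolation ranking is strict. Returns a list of
    ``(SimConfig, VariantTable, GenotypeMatrix, SimTruth)`` tuples.
    """
    if n_cohorts < 3:
        raise ValueError("need at least 3 cohorts")
    tdgs = np.linspace(100, 250, n_cohorts).astype(int)
    nes = np.geomspace(8000, 800, n_cohorts)
    founders = np.geomspace(6000, 150, n_cohorts)
    migs = np.geomspace(5e-3, 1e-4, n_cohorts)
    out = []
    for i in range(n_cohorts):
        cfg = dataclasses.replace(
            base_cfg,
            tdg_gens=int(tdgs[i]),
            ne_isolate=float(nes[i]),
            ne_founder=float(founders[i]),
            founder_gens=min(base_cfg.founder_gens, int(tdgs[i]) // 2),
            mig=float(migs[i]),
            isolate_label=f"ISO{i}",
            general_label=f"GEN{i}",
            seed=seed + 1000 * (i + 1),
        )
        vt, gm, truth = simulate_cohort_pair(cfg)
        out.append((cfg, vt, gm, truth))
    return out


def write_vcf(vt: VariantTable, gm: GenotypeMatrix, path) -> None:
    """Write a minimal phased VCF 4.2 with the AA INFO tag."""
    path = pathlib.Path(path)
    hap = gm.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(vt.chrom):
            length = int(vt.pos[vt.chrom == chrom].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        df = vt.df
        for v in range(len(vt)):
            info = f"AA={df.at[v, 'ancestral']}" if df.at[v, "ancestral"] else "."
            if hap is not None:
                gts = "\t".join(f"{hap[2*i, v]}|{hap[2*i+1, v]}" for i in range(gm.n_individuals))
            else:
                gts = "\t".join(
                    {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(gm.dosages[i, v]), "./.")
                    for i in range(gm.n_individuals)
                )
            fh.write(
                f"{df.at[v, 'chrom']}\t{df.at[v, 'pos']}\t.\t{df.at[v, 'ref']}\t{df.at[v, 'alt']}"
                f"\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def write_inputs(vt: VariantTable, gm: GenotypeMatrix, truth: SimTruth, outdir) -> dict[str, pathlib.Path]:
    """Write every input format the pipeline consumes.

    VCF (with AA tag), annotation TSV, sample map, essential-gene list,
    truth ancestry Q matrix (+ sample order) and a manifest JSON with
    the full SimConfig. Byte-stable given the config seed.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "annotation": outdir / "annotation.tsv",
        "sample_map": outdir / "samples.tsv",
        "essential": outdir / "essential_genes.txt",
        "q_matrix": outdir / "truth.2.Q",
        "q_samples": outdir / "truth.fam",
        "manifest": outdir / "manifest.json",
    }
    write_vcf(vt, gm, paths["vcf"])
    ann = vt.df[["chrom", "pos", "ref", "alt", "gene", "consequence", "cadd"]].copy()
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    with open(paths["sample_map"], "w") as fh:
        for s in gm.samples:
            fh.write(f"{s}\t{gm.pop_of[s]}\n")
    with open(paths["essential"], "w") as fh:
        fh.write("\n".join(truth.essential_genes) + "\n")
    iso = truth.config.isolate_label
    with open(paths["q_matrix"], "w") as fh:
        for s in gm.samples:
            q1 = 1.0 if gm.pop_of[s] == iso else 0.0
            fh.write(f"{q1:.6f} {1 - q1:.6f}\n")
    with open(paths["q_samples"], "w") as fh:
        fh.write("\n".join(gm.samples) + "\n")
    with open(paths["manifest"], "w") as fh:
        json.dump({"config": dataclasses.asdict(truth.config)}, fh, indent=2, default=float)
    return paths
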