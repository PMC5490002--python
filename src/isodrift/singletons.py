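"""Singleton-based relaxation-of-selection statistics.

A singleton (SV) is a variant whose alternative-allele count is exactly
one within a population's own minimum-size (36-individual) sample.
SVgene is the per-gene ratio of missense to synonymous singletons;
SVpop pools the counts over all genes with at least one singleton in
either population of the pair; SVxy is the isolate-to-general ratio of
SVpop and exceeds 1 when purifying selection is relaxed in the isolate.
G_SV compares the proportions of essential versus non-essential genes
showing SVgene > 1.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .types import CohortPair, FrequencyTable, VariantTable


def find_singletons(ft: FrequencyTable, population: str) -> np.ndarray:
    """Indices of variants with alternative-allele count exactly 1."""
    return np.flatnonzero(ft.alt_count_of(population) == 1)


def gene_singleton_counts(ft: FrequencyTable, vt: VariantTable, pair: CohortPair) -> pd.DataFrame:
    """Per-gene missense and synonymous singleton counts for each
    population of the pair.

    Only genes with at least one singleton (either class, either
    population) are retained — the shared gene universe every pooled
    statistic uses. Index: gene; columns: missense_x, synonymous_x,
    missense_y, synonymous_y.
    """
    cons = vt.consequence
    gene = vt.gene
    counts: dict[str, np.ndarray] = {}
    for suffix, pop in (("x", pair.isolate), ("y", pair.general)):
        sv = find_singletons(ft, pop)
        for cls in ("missense", "synonymous"):
            idx = sv[(cons[sv] == cls) & (gene[sv] != "")]
            counts[f"{cls}_{suffix}"] = idx
    genes = sorted(set().union(*(set(gene[v]) for v in counts.values())))
    df = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                      columns=["missense_x", "synonymous_x", "missense_y", "synonymous_y"])
    for col, idx in counts.items():
        vc = pd.Series(gene[idx]).value_counts()
        df.loc[vc.index, col] = vc.to_numpy()
    return df


def sv_gene(n_missense: int, n_synonymous: int) -> tuple[float, str]:
    """Per-gene missense/synonymous singleton ratio and its class.

    Returns ``(ratio, cls)`` with cls in {">1", "=1", "<1"}. A gene with
    missense singletons but no synonymous ones is classified ">1" with a
    NaN ratio (kept out of ratio averaging, counted for G_SV). A gene
    with neither is excluded upstream and is an error here.
    """
    if n_missense == 0 and n_synonymous == 0:
        raise ValueError("gene with no singletons should be excluded upstream")
    if n_synonymous == 0:
        return math.nan, ">1"
    ratio = n_missense / n_synonymous
    cls = ">1" if ratio > 1 else ("=1" if ratio == 1 else "<1")
    return ratio, cls


def sv_pop(gene_counts: pd.DataFrame) -> tuple[float, float]:
    """Pooled missense/synonymous singleton ratio per population.

    Sums counts over the shared gene universe of the pair; an all-zero
    synonymous total gives NaN (flagged by the caller), never infinity.
    """
    def pooled(m: int, s: int) -> float:
        return m / s if s > 0 else math.nan

    return (
        pooled(int(gene_counts["missense_x"].sum()), int(gene_counts["synonymous_x"].sum())),
        pooled(int(gene_counts["missense_y"].sum()), int(gene_counts["synonymous_y"].sum())),
    )


def sv_xy(sv_pop_isolate: float, sv_pop_general: float) -> float:
    """Isolate-to-general ratio of SVpop; NaN propagates."""
    if math.isnan(sv_pop_isolate) or math.isnan(sv_pop_general) or sv_pop_general == 0:
        return math.nan
    return sv_pop_isolate / sv_pop_general


def g_sv(gene_classes: pd.Series, essential_genes: Iterable[str]) -> float:
    """Essential-vs-non-essential ratio of the share of genes with SVgene > 1.

    ``gene_classes`` maps gene -> class string from :func:`sv_gene`.
    Undefined (NaN) when the non-essential share is zero.
    """
    essential = set(essential_genes) & set(gene_classes.index)
    if not essential:
        raise ValueError("no essential gene present in the gene universe")
    non_essential = set(gene_classes.index) - essential
    if not non_essential:
        raise ValueError("no non-essential gene present in the gene universe")
    pct_e = np.mean([gene_classes[g] == ">1" for g in sorted(essential)])
    pct_n = np.mean([gene_classes[g] == ">1" for g in sorted(non_essential)])
    if pct_n == 0:
        return math.nan
    return float(pct_e / pct_n)


@dataclasses.dataclass
class SvResult:
    """All singleton statistics for one cohort pair."""

    sv_pop_isolate: float
    sv_pop_general: float
    sv_xy: float
    g_sv_isolate: float | None
    g_sv_general: float | None
    ci_low: float
    ci_high: float
    n_genes: int
    gene_counts: pd.DataFrame | None = None  # per-gene singleton counts


def gene_bootstrap_ci(
    statistic_fn: Callable[[np.ndarray], float],
    genes: np.ndarray,
    frac: float = 0.8,
    reps: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """95% CI by recomputing a statistic on 80% gene subsamples.

    Each of ``reps`` replicates draws ``floor(frac * G)`` genes without
    replacement and evaluates ``statistic_fn`` on that gene subset;
    the CI is the 2.5/97.5 percentile of defined replicate values.
    """
    genes = np.asarray(genes)
    if len(genes) < 5:
        raise ValueError("need at least 5 genes for the gene bootstrap")
    k = int(frac * len(genes))
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        sub = rng.choice(genes, size=k, replace=False)
        v = statistic_fn(sub)
        if v == v:
            vals.append(v)
    if not vals:
        return math.nan, math.nan
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def sv_analysis(
    ft: FrequencyTable,
    vt: VariantTable,
    pair: CohortPair,
    essential_genes: Iterable[str] | None = None,
    reps: int = 100,
    seed: int = 0,
) -> SvResult:
    """Full SV workflow for one pair: SVpop, SVxy, G_SV and the 80%-gene
    bootstrap CI for SVxy."""
    gc = gene_singleton_counts(ft, vt, pair)
    svx, svy = sv_pop(gc)
    sxy = sv_xy(svx, svy)

    def stat(gene_subset: np.ndarray) -> float:
        sub = gc.loc[gene_subset]
        a, b = sv_pop(sub)
        return sv_xy(a, b)

    lo, hi = gene_bootstrap_ci(stat, gc.index.to_numpy(), reps=reps, seed=seed)
    gsv_i = gsv_g = None
    if essential_genes is not None:
        essential = set(essential_genes)
        cls_i = pd.Series(
            {g: sv_gene(int(r["missense_x"]), int(r["synonymous_x"]))[1]
             for g, r in gc.iterrows() if r["missense_x"] + r["synonymous_x"] > 0}
        )
        cls_g = pd.Series(
            {g: sv_gene(int(r["missense_y"]), int(r["synonymous_y"]))[1]
             for g, r in gc.iterrows() if r["missense_y"] + r["synonymous_y"] > 0}
        )
        if len(cls_i) and (set(cls_i.index) & essential):
            gsv_i = g_sv(cls_i, essential)
        if len(cls_g) and (set(cls_g.index) & essential):
            gsv_g = g_sv(cls_g, essential)
    return SvResult(svx, svy, sxy, gsv_i, gsv_g, lo, hi, len(gc), gene_counts=gc)
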