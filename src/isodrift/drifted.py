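"""Drifted-variant identification and the DVxy enrichment statistics.

A drifted variant (DV) is a variant at derived-allele frequency 2-5% in
one population of an isolate/general pair and at least three-fold lower
in the other. DVxy-coding compares the fraction of functional
(missense + LoF) DVs, corrected by intergenic DVs, between the two
populations; DVxy-wg does the same genome-wide per CADD-score stratum
with the 0-5 bin as the neutral reference. Values above 1 mean
enrichment of functional drifted variants in the isolate.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .types import CohortPair, FrequencyTable, VariantTable

DEFAULT_DAF_BAND = (0.02, 0.05)
DEFAULT_FOLD = 3.0
DEFAULT_CADD_BINS = ((0.0, 5.0), (5.0, 10.0), (10.0, 20.0), (20.0, math.inf))
FUNCTIONAL_CLASSES = frozenset({"missense", "lof"})
NEUTRAL_CLASSES = frozenset({"intergenic"})


@dataclasses.dataclass
class DriftedVariantSet:
    """Indices of drifted variants in each direction of a cohort pair.

    ``idx_x`` are DVs drifted in the isolate (DAF in the band there and
    >= fold times the general-population DAF); ``idx_y`` the symmetric
    set for the general population. ``daf_x`` / ``daf_y`` are the full
    per-variant DAF arrays for reporting.
    """

    idx_x: np.ndarray
    idx_y: np.ndarray
    daf_x: np.ndarray
    daf_y: np.ndarray
    band: tuple[float, float] = DEFAULT_DAF_BAND
    fold: float = DEFAULT_FOLD


@dataclasses.dataclass
class DvxyResult:
    """A DVxy point estimate for one stratum, with the four counts used.

    ``estimate`` is NaN (and ``undefined`` True) when a denominator
    count is zero — never silently 0 or infinity.
    """

    stratum: str
    estimate: float
    counts: tuple[int, int, int, int]  # functional_x, neutral_x, functional_y, neutral_y
    ci_low: float = math.nan
    ci_high: float = math.nan
    undefined: bool = False


def find_drifted_variants(
    ft: FrequencyTable,
    pair: CohortPair,
    band: tuple[float, float] = DEFAULT_DAF_BAND,
    fold: float = DEFAULT_FOLD,
) -> DriftedVariantSet:
    """Identify drifted variants in both directions of a pair.

    Band endpoints are inclusive. A DAF of exactly 0 in the comparison
    population satisfies the fold rule (absence is the extreme drift
    case). Variants with undefined DAF in either population are skipped;
    if no variant has a defined DAF the input is unusable.
    """
    lo, hi = band
    if not (0 < lo < hi < 0.5):
        raise ValueError("DAF band must lie within (0, 0.5)")
    daf_x = ft.daf_of(pair.isolate)
    daf_y = ft.daf_of(pair.general)
    defined = ~(np.isnan(daf_x) | np.isnan(daf_y))
    if not defined.any():
        raise ValueError("no variants with defined DAF in both populations")
    in_x = defined & (daf_x >= lo) & (daf_x <= hi) & (daf_x >= fold * daf_y)
    in_y = defined & (daf_y >= lo) & (daf_y <= hi) & (daf_y >= fold * daf_x)
    return DriftedVariantSet(np.flatnonzero(in_x), np.flatnonzero(in_y), daf_x, daf_y, (lo, hi), fold)


def _ratio_of_fractions(fx: int, nx: int, fy: int, ny: int) -> tuple[float, bool]:
    if min(nx, ny, fy) == 0:
        return math.nan, True
    return (fx / nx) / (fy / ny), False


def dvxy_coding(
    dv: DriftedVariantSet,
    vt: VariantTable,
    functional: frozenset[str] = FUNCTIONAL_CLASSES,
    neutral: frozenset[str] = NEUTRAL_CLASSES,
) -> DvxyResult:
    """DVxy for coding variants: functional-DV fraction of the isolate
    over that of the general population, each corrected by its
    intergenic-DV count."""
    cons = vt.consequence
    f_x = int(np.isin(cons[dv.idx_x], list(functional)).sum())
    n_x = int(np.isin(cons[dv.idx_x], list(neutral)).sum())
    f_y = int(np.isin(cons[dv.idx_y], list(functional)).sum())
    n_y = int(np.isin(cons[dv.idx_y], list(neutral)).sum())
    est, undef = _ratio_of_fractions(f_x, n_x, f_y, n_y)
    return DvxyResult("coding", est, (f_x, n_x, f_y, n_y), undefined=undef)


def dvxy_wg(
    dv: DriftedVariantSet,
    vt: VariantTable,
    bins: Sequence[tuple[float, float]] = DEFAULT_CADD_BINS,
) -> list[DvxyResult]:
    """DVxy genome-wide per CADD stratum, against the first (neutral) bin.

    Bins are half-open ``[lo, hi)``; the first bin (0-5 by default) is
    the neutral reference and its own entry is identically 1 when
    defined. Variants with missing CADD are excluded.
    """
    cadd = vt.cadd
    neutral_lo, neutral_hi = bins[0]

    def bin_count(idx: np.ndarray, lo: float, hi: float) -> int:
        c = cadd[idx]
        return int(np.sum(~np.isnan(c) & (c >= lo) & (c < hi)))

    ref_x = bin_count(dv.idx_x, neutral_lo, neutral_hi)
    ref_y = bin_count(dv.idx_y, neutral_lo, neutral_hi)
    out = []
    for lo, hi in bins:
        b_x = bin_count(dv.idx_x, lo, hi)
        b_y = bin_count(dv.idx_y, lo, hi)
        est, undef = _ratio_of_fractions(b_x, ref_x, b_y, ref_y)
        label = f"cadd_{lo:g}_{hi:g}" if math.isfinite(hi) else f"cadd_gt{lo:g}"
        out.append(DvxyResult(label, est, (b_x, ref_x, b_y, ref_y), undefined=undef))
    return out


def make_resampling_blocks(vt: VariantTable, min_blocks: int = 20) -> np.ndarray:
    """Per-variant block labels for chromosome resampling.

    With >= ``min_blocks`` chromosomes the blocks are whole chromosomes.
    Smaller genomes (few large synthetic scaffolds) have each chromosome
    split into equal-variant segments until at least ``min_blocks``
    blocks exist, so the resampling unit still respects linkage.
    """
    chrom = vt.chrom
    chroms = list(dict.fromkeys(chrom))
    if len(chroms) >= min_blocks:
        return chrom.astype(str)
    per = math.ceil(min_blocks / len(chroms))
    labels = np.empty(len(chrom), dtype=object)
    for c in chroms:
        idx = np.flatnonzero(chrom == c)
        parts = np.array_split(idx, per)
        for k, part in enumerate(parts):
            labels[part] = f"{c}.seg{k}"
    return labels.astype(str)


def chromosome_resample_ci(
    statistic_fn: Callable[[np.ndarray], float],
    block_labels: np.ndarray,
    n_blocks: int = 20,
    reps: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """95% CI by resampling ``n_blocks`` chromosome blocks, ``reps`` times.

    Each replicate draws ``n_blocks`` blocks without replacement,
    evaluates ``statistic_fn`` on the boolean variant mask of those
    blocks, and the CI is the 2.5/97.5 percentile of defined replicate
    values. Deterministic given ``seed``.
    """
    block_labels = np.asarray(block_labels)
    blocks = np.array(sorted(set(block_labels.tolist())))
    if len(blocks) < n_blocks:
        raise ValueError(
            f"only {len(blocks)} blocks available; use n_blocks <= {len(blocks)} (or smaller n_chroms)"
        )
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        chosen = rng.choice(blocks, size=n_blocks, replace=False)
        mask = np.isin(block_labels, chosen)
        v = statistic_fn(mask)
        if v == v:  # not NaN
            vals.append(v)
    if not vals:
        return math.nan, math.nan
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def jackknife_log_z(
    statistic_fn: Callable[[np.ndarray], float],
    block_labels: np.ndarray,
) -> dict:
    """Leave-one-block-out jackknife z-test of log(statistic) = 0.

    Returns the full-data log estimate, its jackknife standard error, the
    z score and a two-sided normal p value. Replicates where the
    statistic is undefined are dropped.
    """
    block_labels = np.asarray(block_labels)
    blocks = sorted(set(block_labels.tolist()))
    full = statistic_fn(np.ones(len(block_labels), dtype=bool))
    if not (full == full) or full <= 0:
        return {"log_estimate": math.nan, "se": math.nan, "z": math.nan, "p": math.nan}
    log_full = math.log(full)
    loo = []
    for b in blocks:
        v = statistic_fn(block_labels != b)
        if v == v and v > 0:
            loo.append(math.log(v))
    g = len(loo)
    if g < 2:
        return {"log_estimate": log_full, "se": math.nan, "z": math.nan, "p": math.nan}
    loo = np.array(loo)
    pseudo = g * log_full - (g - 1) * loo
    est = pseudo.mean()
    se = float(np.sqrt(np.var(pseudo, ddof=1) / g))
    if se == 0:
        return {"log_estimate": log_full, "se": 0.0, "z": math.inf if est != 0 else 0.0, "p": 0.0 if est != 0 else 1.0}
    z = est / se
    p = 2 * stats.norm.sf(abs(z))
    return {"log_estimate": log_full, "se": se, "z": float(z), "p": float(p)}


def common_in_isolate_rare_in_general(
    ft: FrequencyTable,
    pair: CohortPair,
    min_count: int = 4,
    max_count: int = 1,
    all_general_pops: list[str] | None = None,
) -> np.ndarray:
    """Variants common in the isolate but not in its general population.

    Selects variants whose alternative-allele count in the isolate is
    >= ``min_count`` (MAF >= 5.6% at 36 diploids) and <= ``max_count``
    in the general population (MAF <= 1.4%). When ``all_general_pops``
    is given, returns a structured second column flagging variants that
    also satisfy the ceiling in every listed population.
    """
    iso = ft.alt_count_of(pair.isolate)
    gen = ft.alt_count_of(pair.general)
    selected = np.flatnonzero((iso >= min_count) & (gen <= max_count))
    if all_general_pops is None:
        return selected
    every = np.ones(len(iso), dtype=bool)
    for pop in all_general_pops:
        every &= ft.alt_count_of(pop) <= max_count
    return np.column_stack([selected, every[selected].astype(int)])
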