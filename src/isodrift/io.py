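"""File I/O, allele-frequency computation and cohort subsetting.

Reads multi-sample VCFs (via cyvcf2), variant-annotation TSVs and
sample-to-population maps; computes exact per-population allele counts;
and provides the three cohort subsetting schemes used throughout
("whole", "matched", and the 36-individual "minimum" set).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    CONSEQUENCE_CLASSES,
    MISSING,
    FrequencyTable,
    GenotypeMatrix,
    VariantTable,
)

logger = logging.getLogger(__name__)

#: Default size of the "minimum" subsetting scheme (individuals per population).
MINIMUM_N = 36

#: Version tag of the consequence-term collapse table below.
CONSEQUENCE_MAP_VERSION = "1"

#: Collapse of annotation (VEP-style) consequence terms onto the five
#: classes used by every statistic. Stop-gain and splice donor/acceptor
#: terms form the loss-of-function class; unknown terms map to "other".
CONSEQUENCE_MAP = {
    "missense": "missense",
    "missense_variant": "missense",
    "stop_gained": "lof",
    "splice_donor_variant": "lof",
    "splice_acceptor_variant": "lof",
    "lof": "lof",
    "synonymous": "synonymous",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "intergenic": "intergenic",
    "intergenic_variant": "intergenic",
}


def map_consequence(term: str) -> str:
    """Map a raw annotation consequence term onto the 5-class set."""
    return CONSEQUENCE_MAP.get(term.strip(), "other")


def read_sample_map(path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, population) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def read_vcf(path, sample_map: dict[str, str], multiallelic: str = "skip"):
    """Read a VCF 4.x into a (VariantTable, GenotypeMatrix) pair.

    Only samples present in ``sample_map`` are retained; a mapped sample
    absent from the VCF is an error. Multi-allelic records are skipped
    (``multiallelic="skip"``) or rejected (``"error"``). The ancestral
    allele is taken from the ``AA`` INFO tag when present. Missing
    genotypes load as the :data:`~isodrift.types.MISSING` sentinel.
    """
    if multiallelic not in ("skip", "error"):
        raise ValueError("multiallelic must be 'skip' or 'error'")
    vcf = VCF(str(path))
    present = set(vcf.samples)
    wanted = [s for s in sample_map if s in present]
    absent = sorted(set(sample_map) - present)
    if absent:
        raise ValueError(f"samples in map absent from VCF: {absent}")
    vcf.set_samples(wanted)
    samples = list(vcf.samples)

    rows = []
    dosage_cols = []
    hap_cols = []
    phased_all = True
    for var in vcf:
        if len(var.ALT) != 1:
            if multiallelic == "error":
                raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(len(gts), dtype=np.int8)
        hap = np.empty(2 * len(gts), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                dos[i] = MISSING
                hap[2 * i] = hap[2 * i + 1] = MISSING
            else:
                dos[i] = a0 + a1
                hap[2 * i] = a0
                hap[2 * i + 1] = a1
            phased_all = phased_all and bool(g[2])
        aa = var.INFO.get("AA")
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "ancestral": (aa or "").upper(),
                "gene": "",
                "consequence": "other",
                "cadd": np.nan,
            }
        )
        dosage_cols.append(dos)
        hap_cols.append(hap)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    vt = VariantTable(pd.DataFrame(rows))
    dosages = np.column_stack(dosage_cols)
    haplotypes = np.column_stack(hap_cols) if phased_all else None
    gm = GenotypeMatrix(dosages, samples, {s: sample_map[s] for s in samples}, haplotypes)
    return vt, gm


def read_annotation_tsv(path, vt: VariantTable) -> VariantTable:
    """Join gene / consequence / CADD annotation onto an existing table.

    The TSV must carry the header ``chrom pos ref alt gene consequence
    cadd``. Raw consequence terms are collapsed via
    :data:`CONSEQUENCE_MAP`; variants without a matching annotation row
    keep ``consequence="other"`` and missing CADD; annotation rows for
    absent variants are counted and logged.
    """
    try:
        ann = pd.read_csv(
            path,
            sep="\t",
            dtype={"chrom": str, "pos": int, "ref": str, "alt": str, "gene": str, "consequence": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed annotation file {path}: {exc}") from exc
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence", "cadd"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation header must contain {sorted(required)}")
    bad = ann["pos"].isna() | ann["cadd"].apply(lambda x: not (pd.isna(x) or isinstance(x, (int, float))))
    if bad.any():
        raise ValueError(f"malformed annotation row at line {int(np.flatnonzero(bad)[0]) + 2}")
    ann = ann.copy()
    ann["consequence"] = ann["consequence"].fillna("").map(map_consequence)
    ann["gene"] = ann["gene"].fillna("")
    key = ["chrom", "pos", "ref", "alt"]
    merged = vt.df.drop(columns=["gene", "consequence", "cadd"]).merge(
        ann[key + ["gene", "consequence", "cadd"]], on=key, how="left"
    )
    unmatched_ann = len(ann) - ann.merge(vt.df[key], on=key, how="inner").shape[0]
    if unmatched_ann:
        logger.info("%d annotation rows had no matching variant and were ignored", unmatched_ann)
    merged["consequence"] = merged["consequence"].fillna("other")
    merged["gene"] = merged["gene"].fillna("")
    return VariantTable(merged[vt.df.columns])


def allele_frequencies(gm: GenotypeMatrix, vt: VariantTable, populations: list[str]) -> FrequencyTable:
    """Exact per-population alternative-allele counts and frequencies.

    Missing genotypes are excluded from the called-chromosome
    denominator. DAF is defined from the table's ancestral allele and is
    NaN where that allele is neither REF nor ALT (unknown).
    """
    if len(vt) != gm.n_variants:
        raise ValueError("variant table and genotype matrix are not aligned")
    P, V = len(populations), gm.n_variants
    alt = np.zeros((P, V), dtype=np.int64)
    called = np.zeros((P, V), dtype=np.int64)
    for p, pop in enumerate(populations):
        idx = gm.pop_indices(pop)  # raises on empty population
        dos = gm.dosages[idx]
        ok = dos >= 0
        alt[p] = np.where(ok, dos, 0).sum(axis=0)
        called[p] = 2 * ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    anc = vt.df["ancestral"].to_numpy()
    ref = vt.df["ref"].to_numpy()
    altal = vt.df["alt"].to_numpy()
    daf = np.full_like(af, np.nan)
    is_ref = anc == ref
    is_alt = anc == altal
    daf[:, is_ref] = af[:, is_ref]
    daf[:, is_alt] = 1.0 - af[:, is_alt]
    n_unknown = int((~(is_ref | is_alt)).sum())
    if n_unknown:
        logger.info("%d variants have unknown ancestral allele; DAF undefined there", n_unknown)
    return FrequencyTable(list(populations), alt, called, af, daf)


def count_to_maf(allele_count: int, n_diploids: int) -> float:
    """Allele count in a diploid sample expressed as a percent MAF.

    ``(4, 36) -> 5.6`` and ``(1, 36) -> 1.4``: the printed frequency
    thresholds corresponding to allele counts 4 and 1 in 36 diploids.
    Reported to one decimal place.
    """
    if n_diploids <= 0:
        raise ValueError("n_diploids must be positive")
    if not 0 <= allele_count <= 2 * n_diploids:
        raise ValueError("allele_count outside [0, 2*n_diploids]")
    return round(100.0 * allele_count / (2 * n_diploids), 1)


def subsample_cohorts(gm: GenotypeMatrix, scheme: str, seed: int, n_minimum: int = MINIMUM_N) -> GenotypeMatrix:
    """Subsample each population per one of the three standard schemes.

    ``whole`` keeps everything; ``minimum`` draws ``n_minimum``
    individuals per population; ``matched`` downsamples every population
    to the size of the smallest. Draws are uniform without replacement
    and deterministic given ``seed``; selected samples keep input order.
    """
    if scheme not in ("whole", "minimum", "matched"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "whole":
        return gm
    pops = gm.populations
    sizes = {p: len(gm.pop_indices(p)) for p in pops}
    n_target = n_minimum if scheme == "minimum" else min(sizes.values())
    too_small = [p for p in pops if sizes[p] < n_target]
    if too_small:
        raise ValueError(f"populations smaller than requested n={n_target}: {too_small}")
    rng = np.random.default_rng(seed)
    keep_rows: list[int] = []
    for pop in pops:
        idx = gm.pop_indices(pop)
        chosen = rng.choice(idx, size=n_target, replace=False)
        keep_rows.extend(sorted(chosen))
    names = [gm.samples[i] for i in sorted(keep_rows)]
    return gm.subset_samples(names)


DEFAULT_MAF_BINS = ((0.0, 0.02), (0.02, 0.05), (0.05, 0.5))


def count_variants_stratified(
    ft: FrequencyTable,
    vt: VariantTable,
    bins=DEFAULT_MAF_BINS,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Counts of segregating variants per population x MAF bin x class.

    Bins are half-open ``(lo, hi]`` on the folded MAF, so a site at
    exactly 2% falls in the rare bin under the default bins. Monomorphic
    sites (MAF 0 in that population) are not counted.
    """
    bins = [tuple(b) for b in bins]
    for (lo1, hi1) in bins:
        for (lo2, hi2) in bins:
            if (lo1, hi1) != (lo2, hi2) and lo1 < hi2 and lo2 < hi1:
                raise ValueError(f"overlapping MAF bins: {(lo1, hi1)} and {(lo2, hi2)}")
    populations = populations or ft.populations
    cons = vt.consequence
    records = []
    for pop in populations:
        maf = ft.maf_of(pop)
        for (lo, hi) in bins:
            in_bin = (maf > lo) & (maf <= hi)
            for cls in CONSEQUENCE_CLASSES:
                records.append(
                    {
                        "population": pop,
                        "maf_lo": lo,
                        "maf_hi": hi,
                        "consequence": cls,
                        "count": int(np.sum(in_bin & (cons == cls))),
                    }
                )
    return pd.DataFrame(records)
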