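"""Core data containers shared by every analysis module.

The package works on three aligned structures: a :class:`VariantTable`
describing the sites (position, alleles, ancestral state, gene,
consequence class, CADD-style deleteriousness score), a
:class:`GenotypeMatrix` holding per-individual allele dosages (optionally
phased haplotypes) with population labels, and a :class:`FrequencyTable`
of per-population allele counts and derived-allele frequencies computed
from the two. A :class:`CohortPair` names the isolate / general
population pair every cross-population statistic compares.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The five consequence classes every annotation is collapsed onto.
#: "lof" covers stop-gain and splice donor/acceptor variants.
CONSEQUENCE_CLASSES = ("missense", "lof", "synonymous", "intergenic", "other")

#: Sentinel for a missing genotype call (excluded from called chromosomes).
MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "ancestral", "gene", "consequence", "cadd"]


class VariantTable:
    """Per-variant records: position, alleles, ancestral allele, gene,
    consequence class and CADD score.

    Thin wrapper around a :class:`pandas.DataFrame` with the columns in
    :data:`VARIANT_COLUMNS`. ``ancestral`` is an allele string or ``""``
    when unknown; ``gene`` is ``""`` outside genes; ``cadd`` is NaN when
    missing. Positions are 1-based and strictly increasing within a
    chromosome.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        bad = set(self.df["consequence"]) - set(CONSEQUENCE_CLASSES)
        if bad:
            raise ValueError(f"unknown consequence classes: {sorted(bad)}")
        for chrom, sub in self.df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def consequence(self) -> np.ndarray:
        return self.df["consequence"].to_numpy()

    @property
    def cadd(self) -> np.ndarray:
        return self.df["cadd"].to_numpy(dtype=float)

    @property
    def gene(self) -> np.ndarray:
        return self.df["gene"].to_numpy()

    def subset(self, mask_or_idx) -> "VariantTable":
        return VariantTable(self.df.iloc[np.asarray(mask_or_idx)].reset_index(drop=True), validate=False)


class GenotypeMatrix:
    """Individuals x variants allele-dosage matrix with population labels.

    ``dosages`` holds integers in {0, 1, 2} (or :data:`MISSING`);
    ``haplotypes`` optionally holds the phased 2N x V matrix in {0, 1}
    from which LD statistics can use haplotypic correlation.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        samples: Sequence[str],
        pop_of: Mapping[str, str],
        haplotypes: np.ndarray | None = None,
    ):
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        if len(samples) != dosages.shape[0]:
            raise ValueError("sample list length does not match dosage rows")
        unmapped = [s for s in samples if s not in pop_of]
        if unmapped:
            raise ValueError(f"samples without population label: {unmapped[:5]}")
        if haplotypes is not None:
            haplotypes = np.asarray(haplotypes, dtype=np.int8)
            if haplotypes.shape != (2 * dosages.shape[0], dosages.shape[1]):
                raise ValueError("haplotype matrix must be 2N x V matching dosages")
        self.dosages = dosages
        self.samples = list(samples)
        self.pop_of = dict(pop_of)
        self.haplotypes = haplotypes

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.pop_of[s], None)
        return list(seen)

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.samples) if self.pop_of[s] == population], dtype=int)
        if idx.size == 0:
            raise ValueError(f"no samples for population {population!r}")
        return idx

    def subset_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        names = list(names)
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in index]
        if missing:
            raise ValueError(f"samples not in matrix: {missing[:5]}")
        rows = np.array([index[n] for n in names], dtype=int)
        hap = None
        if self.haplotypes is not None:
            hrows = np.column_stack([2 * rows, 2 * rows + 1]).ravel()
            hap = self.haplotypes[hrows]
        return GenotypeMatrix(self.dosages[rows], names, {n: self.pop_of[n] for n in names}, hap)

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        hap = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return GenotypeMatrix(self.dosages[:, idx], self.samples, self.pop_of, hap)


@dataclasses.dataclass
class FrequencyTable:
    """Per-variant, per-population allele counts and frequencies.

    ``alt_count[p, v]`` and ``called[p, v]`` are exact integers (missing
    genotypes excluded from the ``called`` denominator). ``af`` is
    alt_count/called and ``daf`` the derived-allele frequency: equal to
    ``af`` where the ancestral allele is REF, ``1 - af`` where it is ALT,
    and NaN where the ancestral state is unknown.
    """

    populations: list[str]
    alt_count: np.ndarray
    called: np.ndarray
    af: np.ndarray
    daf: np.ndarray

    def _row(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"population {population!r} not in frequency table") from None

    def af_of(self, population: str) -> np.ndarray:
        return self.af[self._row(population)]

    def daf_of(self, population: str) -> np.ndarray:
        return self.daf[self._row(population)]

    def alt_count_of(self, population: str) -> np.ndarray:
        return self.alt_count[self._row(population)]

    def called_of(self, population: str) -> np.ndarray:
        return self.called[self._row(population)]

    def maf_of(self, population: str) -> np.ndarray:
        """Minor allele frequency, folded at 0.5."""
        a = self.af_of(population)
        return np.minimum(a, 1.0 - a)


@dataclasses.dataclass
class CohortPair:
    """An isolate and its closest general (non-isolated) population."""

    isolate: str
    general: str
    isolate_samples: list[str] | None = None
    general_samples: list[str] | None = None

    def __post_init__(self) -> None:
        if self.isolate == self.general:
            raise ValueError("isolate and general labels must differ")
        if self.isolate_samples is not None and self.general_samples is not None:
            overlap = set(self.isolate_samples) & set(self.general_samples)
            if overlap:
                raise ValueError(f"cohort sample sets overlap: {sorted(overlap)[:5]}")

    def swapped(self) -> "CohortPair":
        return CohortPair(self.general, self.isolate, self.general_samples, self.isolate_samples)
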