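"""Rare-variant sharing matrices (f2, f3-10) and the deltaDAF scan.

f2 variants carry exactly two copies of the alternative allele in the
pooled minimum-size sample; each contributes one unordered pair of
carrier individuals (a homozygous single carrier increments its own
diagonal cell), so the matrix total equals the number of f2 variants.
f3-10 variants (3-10 copies) each contribute one randomly drawn pair of
their allele copies. deltaDAF is the signed per-variant DAF difference,
isolate minus general.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .types import CohortPair, FrequencyTable, GenotypeMatrix


@dataclasses.dataclass
class SharingMatrix:
    """Symmetric individuals x individuals rare-allele sharing counts."""

    counts: np.ndarray
    samples: list[str]
    pop_of: dict[str, str]
    variant_class: str  # "f2" or "f3_10"
    seed: int | None = None

    def total(self) -> int:
        """Number of contributing variants (upper triangle + diagonal)."""
        return int(np.triu(self.counts).sum())

    def population_blocks(self) -> pd.DataFrame:
        """Sharing aggregated to population x population block sums."""
        pops = list(dict.fromkeys(self.pop_of[s] for s in self.samples))
        lab = np.array([self.pop_of[s] for s in self.samples])
        out = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
        for a in pops:
            for b in pops:
                block = self.counts[np.ix_(lab == a, lab == b)]
                out.loc[a, b] = int(np.triu(block).sum()) if a == b else int(block.sum())
        return out


def _pair_matrix(gm: GenotypeMatrix) -> np.ndarray:
    dos = gm.dosages
    if (dos < 0).any():
        raise ValueError("sharing statistics require complete genotypes")
    return dos


def f2_sharing(gm_pooled: GenotypeMatrix) -> SharingMatrix:
    """f2 sharing over the pooled minimum-size sample.

    For every variant with pooled alternative count exactly 2, the cell
    of the unordered carrier pair is incremented (diagonal for a single
    homozygous carrier).
    """
    dos = _pair_matrix(gm_pooled)
    n = gm_pooled.n_individuals
    counts = np.zeros((n, n), dtype=np.int64)
    totals = dos.sum(axis=0)
    for v in np.flatnonzero(totals == 2):
        carriers = np.flatnonzero(dos[:, v] > 0)
        if len(carriers) == 1:
            counts[carriers[0], carriers[0]] += 1
        else:
            a, b = carriers
            counts[a, b] += 1
            counts[b, a] += 1
    return SharingMatrix(counts, gm_pooled.samples, gm_pooled.pop_of, "f2")


def f3_10_sharing(gm_pooled: GenotypeMatrix, seed: int = 0, lo: int = 3, hi: int = 10) -> SharingMatrix:
    """f3-10 sharing: one random pair of allele copies per variant.

    For each variant with pooled count in [lo, hi], two of its allele
    copies are drawn uniformly without replacement (seeded) and the cell
    of the corresponding individual pair incremented; both copies from
    one homozygote land on the diagonal.
    """
    dos = _pair_matrix(gm_pooled)
    n = gm_pooled.n_individuals
    counts = np.zeros((n, n), dtype=np.int64)
    totals = dos.sum(axis=0)
    rng = np.random.default_rng(seed)
    for v in np.flatnonzero((totals >= lo) & (totals <= hi)):
        owners = np.repeat(np.arange(n), dos[:, v])  # individual of each allele copy
        i, j = rng.choice(len(owners), size=2, replace=False)
        a, b = owners[i], owners[j]
        counts[a, b] += 1
        if a != b:
            counts[b, a] += 1
    return SharingMatrix(counts, gm_pooled.samples, gm_pooled.pop_of, "f3_10", seed=seed)


def delta_daf(ft: FrequencyTable, pair: CohortPair) -> pd.DataFrame:
    """Signed per-variant DAF difference (isolate minus general)."""
    dx = ft.daf_of(pair.isolate)
    dy = ft.daf_of(pair.general)
    return pd.DataFrame(
        {
            "variant": np.arange(len(dx)),
            "daf_isolate": dx,
            "daf_general": dy,
            "delta_daf": dx - dy,
        }
    )
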