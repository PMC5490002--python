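"""Per-pair orchestration and the cross-cohort correlation report.

``run_pair`` executes the full statistic battery for one isolate/general
pair on the subsetting schemes each statistic calls for (DVxy, SVxy and
sharing on the 36-individual minimum set; Rxy and deltaDAF on the
matched set; LD-based demography on the minimum set), and ``run_panel``
assembles a panel of pairs into the Isx-versus-everything Pearson
correlation report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import pathlib
import time
from typing import Any

import numpy as np
import pandas as pd

from . import drifted, io, load, popgen, sharing, singletons
from . import demography as dem
from .types import CohortPair, FrequencyTable, GenotypeMatrix, VariantTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    pair: CohortPair
    seed: int = 0
    n_minimum: int = io.MINIMUM_N
    statistics: tuple[str, ...] = ("dvxy", "svxy", "rxy", "sharing", "popgen", "demography")
    essential_genes: list[str] | None = None
    dvxy_band: tuple[float, float] = drifted.DEFAULT_DAF_BAND
    dvxy_fold: float = drifted.DEFAULT_FOLD
    cadd_bins: tuple = drifted.DEFAULT_CADD_BINS
    reps: int = 100
    n_resample_blocks: int = 20
    c_bins: np.ndarray | None = None
    cm_per_mb: float = 1.0
    ld_stats_classes: tuple[str, ...] = ("intergenic", "other")  # non-coding sites only


@dataclasses.dataclass
class CohortPairResult:
    """All statistics for one isolate/general pair."""

    pair: CohortPair
    seed: int
    dvxy_coding: drifted.DvxyResult | None = None
    dvxy_wg: list[drifted.DvxyResult] | None = None
    dv: drifted.DriftedVariantSet | None = None
    sv: singletons.SvResult | None = None
    rxy: list[load.RxyResult] | None = None
    delta_daf: pd.DataFrame | None = None
    inbreeding: pd.DataFrame | None = None
    roh: pd.DataFrame | None = None
    ld_profile: pd.DataFrame | None = None
    ne_trajectory_isolate: pd.DataFrame | None = None
    ne_trajectory_general: pd.DataFrame | None = None
    fst: float = math.nan
    mean_f: float = math.nan
    roh_total_mb: float = math.nan
    n_roh: float = math.nan
    ld_decay_kb: float = math.nan
    ne_recent: float = math.nan
    tdg: float = math.nan
    tdg_flagged: bool = False
    m_delta_ancestry: float = math.nan
    isx: float = math.nan
    f2: sharing.SharingMatrix | None = None
    f3_10: sharing.SharingMatrix | None = None

    def summary_row(self) -> dict[str, float]:
        """Flat numeric summary used by the correlation analysis."""
        row: dict[str, float] = {
            "isx": self.isx,
            "fst": self.fst,
            "mean_f": self.mean_f,
            "roh_total_mb": self.roh_total_mb,
            "n_roh": self.n_roh,
            "ld_decay_kb": self.ld_decay_kb,
            "tdg": self.tdg,
            "ne_recent": self.ne_recent,
            "m": self.m_delta_ancestry,
        }
        if self.dvxy_coding is not None:
            row["dvxy_coding"] = self.dvxy_coding.estimate
        if self.sv is not None:
            row["sv_xy"] = self.sv.sv_xy
        return row


def _class_indices(vt: VariantTable):
    cons = vt.consequence
    cadd = vt.cadd
    return {
        "missense": np.flatnonzero(cons == "missense"),
        "lof": np.flatnonzero(cons == "lof"),
        "functional": np.flatnonzero(np.isin(cons, ["missense", "lof"])),
        "synonymous": np.flatnonzero(cons == "synonymous"),
        "cadd_gt10": np.flatnonzero(~np.isnan(cadd) & (cadd > 10)),
        "cadd_gt20": np.flatnonzero(~np.isnan(cadd) & (cadd > 20)),
        "cadd_lt5": np.flatnonzero(~np.isnan(cadd) & (cadd < 5)),
    }


def dvxy_with_ci(
    ft_min: FrequencyTable,
    vt: VariantTable,
    pair: CohortPair,
    cfg: RunConfig,
):
    """DVxy-coding and DVxy-wg with chromosome-resampling CIs.

    Block labels are built with headroom above the per-replicate draw
    (as with drawing 20 of 22 real chromosomes) so the resampled subsets
    actually vary.
    """
    labels = drifted.make_resampling_blocks(vt, min_blocks=cfg.n_resample_blocks + 10)

    def coding_stat(mask: np.ndarray) -> float:
        sub_ft = FrequencyTable(
            ft_min.populations, ft_min.alt_count[:, mask], ft_min.called[:, mask],
            ft_min.af[:, mask], ft_min.daf[:, mask],
        )
        dv = drifted.find_drifted_variants(sub_ft, pair, cfg.dvxy_band, cfg.dvxy_fold)
        return drifted.dvxy_coding(dv, vt.subset(mask)).estimate

    dv = drifted.find_drifted_variants(ft_min, pair, cfg.dvxy_band, cfg.dvxy_fold)
    coding = drifted.dvxy_coding(dv, vt)
    lo, hi = drifted.chromosome_resample_ci(
        coding_stat, labels, n_blocks=cfg.n_resample_blocks, reps=cfg.reps, seed=cfg.seed
    )
    coding.ci_low, coding.ci_high = lo, hi

    wg = drifted.dvxy_wg(dv, vt, cfg.cadd_bins)
    for k, bin_res in enumerate(wg):
        bin_lo, bin_hi = cfg.cadd_bins[k]

        def wg_stat(mask: np.ndarray, bl=bin_lo, bh=bin_hi) -> float:
            sub_ft = FrequencyTable(
                ft_min.populations, ft_min.alt_count[:, mask], ft_min.called[:, mask],
                ft_min.af[:, mask], ft_min.daf[:, mask],
            )
            dv_s = drifted.find_drifted_variants(sub_ft, pair, cfg.dvxy_band, cfg.dvxy_fold)
            res = drifted.dvxy_wg(dv_s, vt.subset(mask), [cfg.cadd_bins[0], (bl, bh)])
            return res[1].estimate

        bin_res.ci_low, bin_res.ci_high = drifted.chromosome_resample_ci(
            wg_stat, labels, n_blocks=cfg.n_resample_blocks, reps=cfg.reps, seed=cfg.seed + 7 + k
        )
    return coding, wg


def run_pair(
    cfg: RunConfig,
    vt: VariantTable,
    gm: GenotypeMatrix,
) -> CohortPairResult:
    """Execute every toggled statistic for one pair; deterministic given seeds."""
    pair = cfg.pair
    result = CohortPairResult(pair=pair, seed=cfg.seed)
    t0 = time.time()

    def stage(name: str):
        logger.info("stage=%s pair=%s/%s seed=%d elapsed=%.1fs",
                    name, pair.isolate, pair.general, cfg.seed, time.time() - t0)

    try:
        stage("subset")
        gm_min = io.subsample_cohorts(gm, "minimum", cfg.seed, cfg.n_minimum)
        gm_matched = io.subsample_cohorts(gm, "matched", cfg.seed)
        pops = [pair.isolate, pair.general]
        ft_min = io.allele_frequencies(gm_min, vt, pops)
        ft_matched = io.allele_frequencies(gm_matched, vt, pops)
        cls = _class_indices(vt)

        if "dvxy" in cfg.statistics:
            stage("dvxy")
            result.dvxy_coding, result.dvxy_wg = dvxy_with_ci(ft_min, vt, pair, cfg)
            result.dv = drifted.find_drifted_variants(ft_min, pair, cfg.dvxy_band, cfg.dvxy_fold)
        if "svxy" in cfg.statistics:
            stage("svxy")
            result.sv = singletons.sv_analysis(
                ft_min, vt, pair, cfg.essential_genes, reps=cfg.reps, seed=cfg.seed
            )
        if "rxy" in cfg.statistics:
            stage("rxy")
            result.rxy = []
            for label, control in (("missense", "synonymous"), ("lof", "synonymous"),
                                   ("cadd_gt10", "cadd_lt5"), ("cadd_gt20", "cadd_lt5")):
                if len(cls[label]) == 0 or len(cls[control]) == 0:
                    continue
                res = load.rxy(ft_matched, pair, cls[label], cls[control], label, control)
                res.boot_mean, res.boot_sd = load.rxy_bootstrap(
                    ft_matched, vt, pair, cls[label], cls[control],
                    reps=cfg.reps, seed=cfg.seed, min_blocks=cfg.n_resample_blocks,
                )
                result.rxy.append(res)
        if "sharing" in cfg.statistics:
            stage("sharing")
            result.f2 = sharing.f2_sharing(gm_min)
            result.f3_10 = sharing.f3_10_sharing(gm_min, seed=cfg.seed)
            result.delta_daf = sharing.delta_daf(ft_matched, pair)
        if "popgen" in cfg.statistics:
            stage("popgen")
            result.fst, _ = popgen.hudson_fst(ft_min, pair)
            result.inbreeding, result.mean_f = popgen.inbreeding_f(gm, pair.isolate)
            noncoding = np.isin(vt.consequence, list(cfg.ld_stats_classes))
            vt_nc, gm_nc = vt.subset(noncoding), gm.subset_variants(np.flatnonzero(noncoding))
            result.roh = popgen.roh_scan(gm_nc, vt_nc, pair.isolate, min_length_kb=250.0)
            totals = popgen.roh_totals(result.roh, [s for s in gm.samples if gm.pop_of[s] == pair.isolate])
            result.roh_total_mb = float(totals["total_mb"].mean())
            result.n_roh = float(totals["n_roh"].mean())
            result.ld_decay_kb, result.ld_profile, _ = popgen.ld_decay_length(
                gm_nc, vt_nc, pair.isolate, seed=cfg.seed
            )
        if "demography" in cfg.statistics:
            stage("demography")
            noncoding = np.isin(vt.consequence, list(cfg.ld_stats_classes))
            vt_nc = vt.subset(noncoding)
            gm_min_nc = gm_min.subset_variants(np.flatnonzero(noncoding))
            c_bins = cfg.c_bins if cfg.c_bins is not None else dem.DEFAULT_C_BINS
            traj_i = dem.ne_from_ld(gm_min_nc, vt_nc, pair.isolate, c_bins, cfg.cm_per_mb, seed=cfg.seed)
            traj_g = dem.ne_from_ld(gm_min_nc, vt_nc, pair.general, c_bins, cfg.cm_per_mb, seed=cfg.seed)
            result.ne_trajectory_isolate = traj_i.table
            result.ne_trajectory_general = traj_g.table
            result.tdg, result.tdg_flagged = dem.estimate_tdg(traj_i, traj_g)
            result.ne_recent = traj_i.harmonic_recent_ne()
            q, _ = dem.admixture_em_k2(gm_min, pair, seed=cfg.seed)
            result.m_delta_ancestry = dem.delta_ancestry(q, gm.pop_of, pair)
            result.isx = dem.isx(result.tdg, result.ne_recent, result.m_delta_ancestry)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed for pair {pair.isolate}/{pair.general}: {exc}") from exc
    return result


def run_panel(results: list[CohortPairResult]):
    """Correlation report across >= 3 cohort-pair results.

    Returns ``(summary_df, r_df, p_df)`` where summary_df has one row
    per pair and the correlation matrices cover every defined measure.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 cohort pairs for the correlation report")
    rows = {f"{r.pair.isolate}/{r.pair.general}": r.summary_row() for r in results}
    summary = pd.DataFrame(rows).T
    summary = summary.dropna(axis=1, how="all")
    r_df, p_df, flagged = dem.correlate_measures(summary)
    if flagged:
        logger.info("constant measures flagged in correlation: %s", flagged)
    return summary, r_df, p_df


def _jsonable(obj: Any):
    if isinstance(obj, pd.DataFrame):
        return None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, float)):
        return None if (isinstance(obj, float) or isinstance(obj, np.floating)) and math.isnan(float(obj)) else float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_pair_outputs(result: CohortPairResult, vt: VariantTable, outdir) -> None:
    """Write the per-pair TSV/JSON outputs."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.dvxy_coding is not None:
        rows = [dataclasses.asdict(result.dvxy_coding)] + [dataclasses.asdict(r) for r in result.dvxy_wg or []]
        pd.DataFrame(rows).to_csv(outdir / "dvxy.tsv", sep="\t", index=False)
    if result.rxy:
        pd.DataFrame([dataclasses.asdict(r) for r in result.rxy]).to_csv(outdir / "rxy.tsv", sep="\t", index=False)
    if result.dv is not None:
        rows = []
        for direction, idx in (("isolate", result.dv.idx_x), ("general", result.dv.idx_y)):
            for v in idx:
                rows.append(
                    {
                        "direction": direction,
                        "chrom": vt.df.at[v, "chrom"],
                        "pos": vt.df.at[v, "pos"],
                        "daf_isolate": result.dv.daf_x[v],
                        "daf_general": result.dv.daf_y[v],
                        "consequence": vt.df.at[v, "consequence"],
                        "cadd": vt.df.at[v, "cadd"],
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "dv_variants.tsv", sep="\t", index=False)
    if result.sv is not None and result.sv.gene_counts is not None:
        result.sv.gene_counts.to_csv(outdir / "sv_gene.tsv", sep="\t")
    if result.delta_daf is not None:
        result.delta_daf.reindex(
            result.delta_daf["delta_daf"].abs().sort_values(ascending=False).index
        ).to_csv(outdir / "deltadaf.tsv", sep="\t", index=False)
    if result.inbreeding is not None:
        result.inbreeding.to_csv(outdir / "inbreeding.tsv", sep="\t", index=False)
    if result.roh is not None:
        result.roh.to_csv(outdir / "roh.tsv", sep="\t", index=False)
    if result.ld_profile is not None:
        result.ld_profile.to_csv(outdir / "ld_decay.tsv", sep="\t", index=False)
    if result.ne_trajectory_isolate is not None:
        result.ne_trajectory_isolate.assign(population=result.pair.isolate).to_csv(
            outdir / "ne_trajectory_isolate.tsv", sep="\t", index=False
        )
        result.ne_trajectory_general.assign(population=result.pair.general).to_csv(
            outdir / "ne_trajectory_general.tsv", sep="\t", index=False
        )
    if result.f2 is not None:
        pd.DataFrame(result.f2.counts, index=result.f2.samples, columns=result.f2.samples).to_csv(
            outdir / "f2_sharing.tsv", sep="\t"
        )
    summary = {
        "pair": {"isolate": result.pair.isolate, "general": result.pair.general},
        "seed": result.seed,
        "measures": _jsonable(result.summary_row()),
        "sv": _jsonable(result.sv) if result.sv else None,
    }
    with open(outdir / "pair_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
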