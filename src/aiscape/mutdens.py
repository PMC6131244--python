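"""Somatic SNV density and allele statistics versus copy number.

Relates per-segment SNV counts (per strictly-callable megabase) and
per-SNV variant-allele statistics to the segment's LRR, and recovers the
per-copy mutation rate under the neutral model in which every chromosomal
copy accrues mutations independently at a constant rate per replicated
basepair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .config import PipelineConfig
from . import intervals

logger = logging.getLogger("aiscape")


def snv_density_per_segment(segments: pd.DataFrame, snvs: pd.DataFrame,
                            mask: pd.DataFrame,
                            config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Per-segment SNV count and density per callable Mb.

    SNVs are matched to segments of the same sample; only SNVs inside the
    callable mask count, and segments with less than the callable floor
    (default 0.5 Mb) are excluded.
    """
    if mask is None or not len(mask):
        raise ValueError("callable mask required")
    mask_by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                     for c, g in mask.groupby("chrom")}
    snv_groups = {k: g for k, g in snvs.groupby(["sample_id", "chrom"])} if len(snvs) else {}
    rows = []
    excluded = 0
    for seg in segments.itertuples():
        ms, me = mask_by_chrom.get(seg.chrom, (np.array([]), np.array([])))
        cs, ce = intervals.clip(ms, me, seg.start, seg.end)
        callable_mb = float((ce - cs).sum()) / 1e6
        if callable_mb < config.callable_floor_mb:
            excluded += 1
            continue
        grp = snv_groups.get((seg.sample_id, seg.chrom))
        count = 0
        if grp is not None:
            pos = grp["pos"].to_numpy()
            inside = (pos >= seg.start) & (pos < seg.end)
            count = int(intervals.points_in(pos[inside], cs, ce).sum())
        rows.append({"sample_id": seg.sample_id, "chrom": seg.chrom,
                     "start": seg.start, "end": seg.end, "klass": seg.klass,
                     "mean_lrr": seg.mean_lrr, "callable_mb": callable_mb,
                     "n_snvs": count, "density_per_mb": count / callable_mb})
    if excluded:
        logger.warning("excluded %d segments below callable floor", excluded)
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                       "klass", "mean_lrr", "callable_mb",
                                       "n_snvs", "density_per_mb"])


def vaf_stats(snvs: pd.DataFrame, segments: pd.DataFrame,
              config: PipelineConfig = PipelineConfig()
              ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-SNV (vaf, alt reads, containing-segment LRR) plus LRR-binned medians.

    Returns (per-SNV table, binned summary, number of SNVs in no segment).
    """
    seg_groups = {k: g for k, g in segments.groupby(["sample_id", "chrom"])}
    rows = []
    dropped = 0
    for (sample, chrom), grp in snvs.groupby(["sample_id", "chrom"]):
        segs = seg_groups.get((sample, chrom))
        if segs is None:
            dropped += len(grp)
            continue
        starts = segs["start"].to_numpy()
        ends = segs["end"].to_numpy()
        lrrs = segs["mean_lrr"].to_numpy()
        for snv in grp.itertuples():
            hit = (starts <= snv.pos) & (snv.pos < ends)
            if not hit.any():
                dropped += 1
                continue
            rows.append({"sample_id": sample, "chrom": chrom, "pos": snv.pos,
                         "vaf": snv.vaf, "alt_reads": snv.alt_reads,
                         "segment_lrr": float(lrrs[np.argmax(hit)])})
    per_snv = pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "vaf",
                                          "alt_reads", "segment_lrr"])
    if dropped:
        logger.warning("%d SNVs outside any segment dropped", dropped)
    if not len(per_snv):
        return per_snv, pd.DataFrame(columns=["lrr_bin", "n", "median_vaf",
                                              "mean_vaf", "median_alt",
                                              "mean_alt"]), dropped
    width = config.vaf_bin_width
    bins = np.floor(per_snv["segment_lrr"] / width) * width
    summary = (per_snv.assign(lrr_bin=bins.round(6))
               .groupby("lrr_bin")
               .agg(n=("vaf", "size"), median_vaf=("vaf", "median"),
                    mean_vaf=("vaf", "mean"), median_alt=("alt_reads", "median"),
                    mean_alt=("alt_reads", "mean"))
               .reset_index())
    return per_snv, summary, dropped


def lowess_curve(x, y, frac: float = 0.3, iters: int = 2) -> pd.DataFrame:
    """Robust locally weighted regression (tricube weights) as a visual guide."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("lowess needs at least 10 points")
    fitted = sm_lowess(y, x, frac=frac, it=iters, return_sorted=True)
    return pd.DataFrame({"x": fitted[:, 0], "y": fitted[:, 1]})


@dataclass
class PerCopyRateFit:
    mu: float                  # SNVs per callable Mb per chromosomal copy
    ci_low: float
    ci_high: float
    total_snvs: int
    total_copy_mb: float
    n_segments: int


def invert_copy_number(lrr, purity, attenuation: float = 0.55) -> np.ndarray:
    """Tumor copy number implied by LRR under the mixture model, clipped at 0."""
    rho = np.asarray(purity, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("purity must be positive")
    lrr = np.asarray(lrr, dtype=float)
    c = (2.0 * 2.0 ** (lrr / attenuation) - 2.0 * (1.0 - rho)) / rho
    return np.clip(c, 0.0, None)


def fit_per_copy_rate(density: pd.DataFrame, purity,
                      attenuation: float = 0.55,
                      conf_level: float = 0.95) -> PerCopyRateFit:
    """Poisson rate of SNVs per callable Mb per chromosomal copy.

    With exposure x_i = c_i * Mb_i, the identity-link Poisson regression
    count_i ~ mu * x_i has the closed-form MLE mu = sum(counts) / sum(x);
    the profile-likelihood CI is the exact chi-square (gamma) interval for
    a Poisson rate with fixed exposure.
    """
    c = invert_copy_number(density["mean_lrr"].to_numpy(), purity, attenuation)
    x = c * density["callable_mb"].to_numpy()
    total_x = float(x.sum())
    if total_x <= 0:
        raise ValueError("no exposure: all implied copy numbers are zero")
    k = int(density["n_snvs"].sum())
    mu = k / total_x
    alpha = 1.0 - conf_level
    lo = 0.0 if k == 0 else float(stats.chi2.ppf(alpha / 2, 2 * k) / 2 / total_x)
    hi = float(stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2 / total_x)
    return PerCopyRateFit(mu, lo, hi, k, total_x, len(density))
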