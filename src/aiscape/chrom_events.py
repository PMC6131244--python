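"""Per-sample isochromosome calls and within-chromosome gain/loss co-occurrence.

An isochromosome-like event (the i(8q) pattern: one arm lost, the other
duplicated in a single event) is called when at least 80% of an arm carries
allelic imbalance and the two arms' mean probe LRRs differ by at least 0.2.
The co-occurrence scan computes, on a genomic grid, the log2 odds ratio of
a sample having a gain at one locus and a loss at another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .genome import GenomeLayout
from . import intervals

logger = logging.getLogger("aiscape")


@dataclass
class IsochromosomeCall:
    sample_id: str
    chrom: str
    called: bool
    direction: str        # "i(q)" (p lost), "i(p)" (q lost, generalized), or ""
    p_ai_fraction: float
    q_ai_fraction: float
    mean_lrr_p: float
    mean_lrr_q: float


def _arm_ai_fraction(segments: pd.DataFrame, genome: GenomeLayout,
                     chrom: str, arm: str) -> float:
    lo, hi = genome.arm(chrom, arm)
    sel = segments[(segments["chrom"] == chrom)
                   & segments["klass"].isin(("gain", "loss"))]
    if not len(sel):
        return 0.0
    s, e = intervals.clip(sel["start"].to_numpy(), sel["end"].to_numpy(), lo, hi)
    return intervals.total_length(s, e) / (hi - lo)


def call_isochromosome(sample_segments: pd.DataFrame, sample_probes: pd.DataFrame,
                       genome: GenomeLayout, chrom: str,
                       config: PipelineConfig = PipelineConfig()) -> IsochromosomeCall:
    """Apply the arm-AI + LRR-gap rule to one sample and chromosome.

    The rule as stated detects i(q) (p-arm LRR at least 0.2 below q-arm);
    the mirrored condition is reported as i(p) and flagged by direction.
    """
    sample_id = (sample_segments["sample_id"].iloc[0] if len(sample_segments)
                 else (sample_probes["sample_id"].iloc[0]
                       if "sample_id" in sample_probes and len(sample_probes)
                       else "sample"))
    cen = genome.centromere(chrom)  # raises KeyError for unknown chromosome
    frac_p = _arm_ai_fraction(sample_segments, genome, chrom, "p")
    frac_q = _arm_ai_fraction(sample_segments, genome, chrom, "q")
    pr = sample_probes[sample_probes["chrom"] == chrom]
    on_p = pr["pos"].to_numpy() < cen
    lrr = pr["lrr"].to_numpy()
    mean_p = float(lrr[on_p].mean()) if on_p.any() else np.nan
    mean_q = float(lrr[~on_p].mean()) if (~on_p).any() else np.nan
    arm_ok = max(frac_p, frac_q) >= config.iso_arm_ai_fraction
    direction = ""
    called = False
    if arm_ok and np.isfinite(mean_p) and np.isfinite(mean_q):
        if mean_p <= mean_q - config.iso_lrr_gap:
            called, direction = True, "i(q)"
        elif mean_q <= mean_p - config.iso_lrr_gap:
            called, direction = True, "i(p)"
    return IsochromosomeCall(sample_id, chrom, called, direction,
                             frac_p, frac_q, mean_p, mean_q)


def call_isochromosomes_cohort(segments: pd.DataFrame, probes: pd.DataFrame,
                               genome: GenomeLayout, chrom: str,
                               config: PipelineConfig = PipelineConfig()
                               ) -> pd.DataFrame:
    rows = []
    for sample, pr in probes.groupby("sample_id", sort=False):
        segs = segments[segments["sample_id"] == sample]
        call = call_isochromosome(segs, pr, genome, chrom, config)
        rows.append(vars(call))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gain/loss co-occurrence odds-ratio scan
# ---------------------------------------------------------------------------

@dataclass
class ORScanResult:
    table: pd.DataFrame       # long format: x, y, log2_or
    best_x: int
    best_y: int
    best_log2_or: float
    fisher_p: float
    best_table: tuple[int, int, int, int]   # a, b, c, d (uncorrected)


def _covers(segments: pd.DataFrame, samples: list[str], chrom: str,
            klass: str, grid: np.ndarray) -> np.ndarray:
    """Boolean matrix (samples x grid): sample has a klass segment covering x."""
    out = np.zeros((len(samples), len(grid)), dtype=bool)
    index = {s: i for i, s in enumerate(samples)}
    sel = segments[(segments["chrom"] == chrom) & (segments["klass"] == klass)]
    for sample, grp in sel.groupby("sample_id"):
        if sample not in index:
            continue
        mask = intervals.points_in(grid, grp["start"].to_numpy(),
                                   grp["end"].to_numpy())
        out[index[sample]] = mask
    return out


def cooccurrence_or_scan(segments: pd.DataFrame, samples: list[str],
                         genome: GenomeLayout, chrom: str,
                         grid_step: int = 1_000_000) -> ORScanResult:
    """Log2 OR of (gain at x) x (loss at y) over a genomic grid.

    Zero cells are handled with the Haldane-Anscombe 0.5 correction for the
    displayed log2 OR; the two-sided Fisher exact test for the maximal pair
    uses the uncorrected table.
    """
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    length = genome.length(chrom)
    grid = np.arange(grid_step // 2, length, grid_step)
    G = _covers(segments, samples, chrom, "gain", grid)
    L = _covers(segments, samples, chrom, "loss", grid)
    n = len(samples)
    Gi = G.astype(np.int64)
    Li = L.astype(np.int64)
    a = Gi.T @ Li                       # gain at x AND loss at y
    gx = Gi.sum(axis=0)[:, None]
    ly = Li.sum(axis=0)[None, :]
    b = gx - a                          # gain at x, no loss at y
    c = ly - a
    d = n - gx - ly + a
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    af, bf, cf, df_ = (m.astype(float) for m in (a, b, c, d))
    af[zero] += 0.5
    bf[zero] += 0.5
    cf[zero] += 0.5
    df_[zero] += 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_or = np.log2((af * df_) / (bf * cf))
    # a locus with no (or universal) gain/loss coverage carries no
    # information about co-occurrence: its ORs are undefined
    informative = (gx > 0) & (gx < n) & (ly > 0) & (ly < n)
    log2_or[~informative] = np.nan
    if not informative.any():
        logger.warning("degenerate cohort: ORs undefined on %s", chrom)
        long = pd.DataFrame({"x": np.repeat(grid, len(grid)),
                             "y": np.tile(grid, len(grid)),
                             "log2_or": log2_or.ravel()})
        return ORScanResult(long, -1, -1, float("nan"), float("nan"),
                            (0, 0, 0, 0))
    xi, yi = np.unravel_index(np.nanargmax(log2_or), log2_or.shape)
    tab = (int(a[xi, yi]), int(b[xi, yi]), int(c[xi, yi]), int(d[xi, yi]))
    _, fisher_p = stats.fisher_exact([[tab[0], tab[1]], [tab[2], tab[3]]],
                                     alternative="two-sided")
    long = pd.DataFrame({
        "x": np.repeat(grid, len(grid)),
        "y": np.tile(grid, len(grid)),
        "log2_or": log2_or.ravel(),
    })
    return ORScanResult(long, int(grid[xi]), int(grid[yi]),
                        float(log2_or[xi, yi]), float(fisher_p), tab)
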