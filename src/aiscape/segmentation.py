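"""Allelic-imbalance segmentation from per-SNP BAF/LRR.

Changepoints are found on the mirrored BAF (|BAF - 0.5|) per chromosome by
penalized least-squares binary segmentation (BIC-style penalty). A segment
is called AI when its mean mirrored BAF clears a small deviation threshold;
AI segments are classified gain vs loss by mean LRR, where "loss" includes
copy-neutral LOH. Purity and per-segment clonality are recovered from the
same mixture model the simulator uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .genome import GenomeLayout
from . import intervals
from .io import SEGMENT_COLUMNS

logger = logging.getLogger("aiscape")


def mirror_baf(baf) -> np.ndarray:
    """Mirrored BAF m = |BAF - 0.5|, folding the two allelic directions."""
    return np.abs(np.asarray(baf, dtype=float) - 0.5)


# ---------------------------------------------------------------------------
# changepoint search
# ---------------------------------------------------------------------------

def _best_split(y: np.ndarray, lo: int, hi: int, min_size: int,
                csum: np.ndarray, csum2: np.ndarray):
    """Best single split of y[lo:hi] by SSE reduction; O(hi-lo)."""
    n = hi - lo
    if n < 2 * min_size:
        return None, 0.0
    total = csum[hi] - csum[lo]
    sse_full = (csum2[hi] - csum2[lo]) - total * total / n
    t = np.arange(lo + min_size, hi - min_size + 1)
    nl = t - lo
    nr = hi - t
    sl = csum[t] - csum[lo]
    sr = total - sl
    sse_split = ((csum2[t] - csum2[lo]) - sl * sl / nl
                 + (csum2[hi] - csum2[t]) - sr * sr / nr)
    k = int(np.argmin(sse_split))
    return int(t[k]), float(sse_full - sse_split[k])


def changepoints(y: np.ndarray, penalty: Optional[float] = None,
                 min_size: int = 5, penalty_scale: float = 2.0) -> list[int]:
    """Binary segmentation on a 1-D signal; returns sorted interior changepoints.

    A candidate split is accepted while its SSE reduction exceeds the
    penalty; the default penalty is ``penalty_scale * sigma^2 * log(n)``
    with sigma estimated robustly from successive differences.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * min_size:
        return []
    if penalty is None:
        d = np.diff(y)
        sigma = 1.4826 * np.median(np.abs(d)) / np.sqrt(2.0) if len(d) else 0.0
        penalty = max(penalty_scale * sigma * sigma * np.log(n), 1e-12)
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y * y)])
    cps: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        t, gain = _best_split(y, lo, hi, min_size, csum, csum2)
        if t is not None and gain > penalty:
            cps.append(t)
            stack.append((lo, t))
            stack.append((t, hi))
    return sorted(cps)


# ---------------------------------------------------------------------------
# segment calling
# ---------------------------------------------------------------------------

def classify_segments(segments: pd.DataFrame,
                      config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Gain iff mean LRR exceeds the gain threshold; otherwise loss.

    The loss class deliberately includes copy-neutral LOH (AI with
    near-zero LRR). Homozygous-deletion segments keep their class.
    """
    out = segments.copy()
    keep = out["klass"] != "homozygous_deletion" if "klass" in out else slice(None)
    klass = np.where(out["mean_lrr"] > config.gain_lrr_threshold, "gain", "loss")
    if "klass" in out.columns:
        out.loc[out["klass"] != "homozygous_deletion", "klass"] = \
            klass[(out["klass"] != "homozygous_deletion").to_numpy()]
    else:
        out["klass"] = klass
    return out


def _merge_adjacent(segs: list[dict], gap: int) -> list[dict]:
    """Merge same-class AI segments separated by less than ``gap`` bp."""
    merged: list[dict] = []
    for s in sorted(segs, key=lambda d: d["start"]):
        if (merged and s["klass"] == merged[-1]["klass"]
                and s["start"] - merged[-1]["end"] < gap):
            prev = merged[-1]
            w1, w2 = prev["n_probes"], s["n_probes"]
            prev["mean_lrr"] = (prev["mean_lrr"] * w1 + s["mean_lrr"] * w2) / (w1 + w2)
            prev["mean_mbaf"] = (prev["mean_mbaf"] * w1 + s["mean_mbaf"] * w2) / (w1 + w2)
            prev["n_probes"] = w1 + w2
            prev["end"] = s["end"]
        else:
            merged.append(s)
    return merged


def segment_sample(probes: pd.DataFrame,
                   config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Call classified AI segments for one sample's probe signals.

    ``probes`` must contain chrom, pos, baf, lrr for a single sample
    (a sample_id column, if present, must be constant) with positions
    sorted within each chromosome.
    """
    if "sample_id" in probes.columns and len(probes):
        ids = probes["sample_id"].unique()
        if len(ids) > 1:
            raise ValueError("segment_sample expects a single sample")
        sample_id = ids[0]
    else:
        sample_id = "sample"
    rows: list[dict] = []
    for chrom, grp in probes.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"unsorted probe positions on {chrom}")
        if len(pos) < config.min_probes_per_chrom:
            continue
        m = mirror_baf(grp["baf"].to_numpy())
        lrr = grp["lrr"].to_numpy()
        cps = changepoints(m, min_size=config.binseg_min_size,
                           penalty_scale=config.binseg_penalty_scale)
        bounds = [0, *cps, len(pos)]
        segs = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mean_mbaf = float(m[lo:hi].mean())
            if mean_mbaf < config.ai_mbaf_threshold:
                continue
            segs.append({"chrom": chrom,
                         "start": int(pos[lo]),
                         "end": int(pos[hi - 1]) + 1,
                         "sample_id": sample_id,
                         "mean_lrr": float(lrr[lo:hi].mean()),
                         "mean_mbaf": mean_mbaf,
                         "n_probes": int(hi - lo)})
        if not segs:
            continue
        seg_df = classify_segments(pd.DataFrame(segs), config)
        # merge before the probe-count filter so changepoint oversplits do
        # not shed small fragments off a real segment's edge
        merged = _merge_adjacent(seg_df.to_dict(orient="records"),
                                 config.merge_gap_bp)
        rows.extend(s for s in merged
                    if s["n_probes"] >= config.min_probes_per_segment)
    if not rows:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    return pd.DataFrame(rows)[SEGMENT_COLUMNS]


def segment_cohort(probes: pd.DataFrame,
                   config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Segment every sample in a multi-sample probe table."""
    frames = [segment_sample(grp, config)
              for _, grp in probes.groupby("sample_id", sort=False)]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def call_homozygous_deletions(probes: pd.DataFrame,
                              config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Maximal runs of consecutive probes with LRR below the deep-loss threshold."""
    if "sample_id" in probes.columns and len(probes):
        sample_id = probes["sample_id"].iloc[0]
    else:
        sample_id = "sample"
    rows = []
    for chrom, grp in probes.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        lrr = grp["lrr"].to_numpy()
        low = lrr < config.homdel_lrr_threshold
        if not low.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], low.view(np.int8), [0]])))
        for lo, hi in zip(edges[::2], edges[1::2]):
            if hi - lo < config.homdel_min_probes:
                continue
            rows.append({"chrom": chrom, "start": int(pos[lo]),
                         "end": int(pos[hi - 1]) + 1, "sample_id": sample_id,
                         "klass": "homozygous_deletion",
                         "mean_lrr": float(lrr[lo:hi].mean()),
                         "mean_mbaf": float(mirror_baf(grp["baf"].to_numpy()[lo:hi]).mean()),
                         "n_probes": int(hi - lo)})
    if not rows:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    return pd.DataFrame(rows)[SEGMENT_COLUMNS]


# ---------------------------------------------------------------------------
# purity, clonality, burden
# ---------------------------------------------------------------------------

def estimate_purity(segments: pd.DataFrame,
                    config: PipelineConfig = PipelineConfig(),
                    metadata_purity: Optional[float] = None) -> Optional[float]:
    """Purity as 2 * max mean mirrored BAF over near-neutral-LRR AI segments.

    Assumes the strongest copy-neutral segment is clonal cn-LOH, for which
    the mirrored-BAF deviation equals rho/2. A metadata purity, when
    supplied, takes precedence. Returns None when no usable segment exists.
    """
    if metadata_purity is not None:
        return float(metadata_purity)
    ai = segments[segments["klass"].isin(("gain", "loss"))]
    neutral = ai[ai["mean_lrr"].abs() <= config.gain_lrr_threshold]
    if not len(neutral):
        return None
    return float(min(2.0 * neutral["mean_mbaf"].max(), 1.0))


@dataclass
class ClonalityEstimate:
    chrom: str
    start: int
    end: int
    delta: float          # mean mirrored BAF of the segment
    model: str            # "cnloh" or "deletion"
    clonality: float
    purity: float
    flagged: bool         # estimate beyond 1 + tolerance


def estimate_clonality(segment, purity: float,
                       config: PipelineConfig = PipelineConfig(),
                       tolerance: float = 0.1) -> ClonalityEstimate:
    """Clonal fraction of a loss-class segment from its purity-corrected BAF.

    Copy-neutral model (|LRR| <= gain threshold): f = 2*delta/rho.
    One-copy deletion model: with minor fraction B = 0.5 - delta,
    f = (1 - 2B) / (rho * (1 - B)).
    """
    if purity <= 0:
        raise ValueError("purity must be positive")
    if isinstance(segment, pd.DataFrame):
        segment = segment.iloc[0]
    delta = float(segment["mean_mbaf"] if hasattr(segment, "keys") else segment.mean_mbaf)
    lrr = float(segment["mean_lrr"] if hasattr(segment, "keys") else segment.mean_lrr)
    chrom = segment["chrom"] if hasattr(segment, "keys") else segment.chrom
    start = int(segment["start"] if hasattr(segment, "keys") else segment.start)
    end = int(segment["end"] if hasattr(segment, "keys") else segment.end)
    if abs(lrr) <= config.gain_lrr_threshold:
        model = "cnloh"
        f = 2.0 * delta / purity
    else:
        model = "deletion"
        bhat = 0.5 - delta
        f = (1.0 - 2.0 * bhat) / (purity * (1.0 - bhat))
    return ClonalityEstimate(chrom, start, end, delta, model, f, purity,
                             flagged=f > 1.0 + tolerance)


def ai_burden(segments: pd.DataFrame) -> pd.Series:
    """Total AI basepairs per sample, counting overlapping segments once."""
    ai = segments[segments["klass"].isin(("gain", "loss"))]
    out = {}
    for sample, grp in ai.groupby("sample_id"):
        total = 0
        for _, cgrp in grp.groupby("chrom"):
            total += intervals.total_length(cgrp["start"].to_numpy(),
                                            cgrp["end"].to_numpy())
        out[sample] = total
    return pd.Series(out, dtype=float, name="ai_bp")


def group_fold(burdens: pd.Series, groups: pd.Series,
               numerator: str, denominator: str) -> float:
    """Ratio of mean AI burden between two sample groups (e.g. MSS / MSI)."""
    groups = groups.reindex(burdens.index)
    num = burdens[groups == numerator]
    den = burdens[groups == denominator]
    if not len(num) or not len(den) or den.mean() == 0:
        raise ValueError("empty group or zero denominator burden")
    return float(num.mean() / den.mean())
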