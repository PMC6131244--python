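"""Cohort recurrence peaks on AI count tracks.

For each class (gain / loss) the cohort's AI segments are turned into a
piecewise-constant count track over breakpoint intervals (number of distinct
tumors covering each interval), smoothed with a max filter over a window of
consecutive inter-breakpoint intervals, and local maxima of the smoothed
track are called as peaks. Peaks are ranked by topographic prominence —
the height of the peak above the lowest contour line that surrounds it
without containing a higher peak — computed on the unsmoothed track; the
highest peak of a chromosome has prominence equal to its height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from .config import PipelineConfig
from .genome import GenomeLayout
from . import intervals


@dataclass
class CountTrack:
    chrom: str
    klass: str
    breakpoints: np.ndarray   # sorted bp positions incl. both chromosome ends
    values: np.ndarray        # one count per inter-breakpoint interval
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.values) != len(self.breakpoints) - 1:
            raise ValueError("values must have one entry per interval")
        if (np.diff(self.breakpoints) <= 0).any():
            raise ValueError("breakpoints must be strictly increasing")
        if (np.asarray(self.values) < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "klass": self.klass,
                           "start": self.breakpoints[:-1],
                           "end": self.breakpoints[1:],
                           "count": self.values})
        if self.smoothed is not None:
            df["smoothed"] = self.smoothed
        return df


@dataclass
class Peak:
    chrom: str
    klass: str
    apex_start: int
    apex_end: int
    height: int               # unsmoothed apex height, in tumors
    prominence: int
    genes: tuple[str, ...] = ()
    rank: int = 0
    spans_chromosome: bool = False


# ---------------------------------------------------------------------------
# track construction and smoothing
# ---------------------------------------------------------------------------

def build_count_track(segments: pd.DataFrame, klass: str, genome: GenomeLayout,
                      chrom: str) -> CountTrack:
    """Count distinct tumors with a ``klass`` segment covering each interval."""
    length = genome.length(chrom)
    sel = segments[(segments["klass"] == klass) & (segments["chrom"] == chrom)]
    if len(sel) and int(sel["end"].max()) > length:
        raise ValueError(f"segment beyond end of {chrom}")
    starts_all, ends_all = [], []
    for _, grp in sel.groupby("sample_id"):
        s, e = intervals.union(grp["start"].to_numpy(), grp["end"].to_numpy())
        starts_all.append(s)
        ends_all.append(e)
    if not starts_all:
        return CountTrack(chrom, klass, np.array([0, length]), np.zeros(1, dtype=int))
    starts = np.concatenate(starts_all)
    ends = np.concatenate(ends_all)
    bps = np.unique(np.concatenate([[0, length], starts, ends]))
    delta = np.zeros(len(bps), dtype=int)
    np.add.at(delta, np.searchsorted(bps, starts), 1)
    np.add.at(delta, np.searchsorted(bps, ends), -1)
    values = np.cumsum(delta)[:-1]
    return CountTrack(chrom, klass, bps, values)


def smooth_values(values: np.ndarray, window: int, align: str = "centered") -> np.ndarray:
    """Max filter over ``window`` consecutive inter-breakpoint intervals.

    Centered alignment puts interval i at the max over intervals
    i - ceil(w/2) + 1 ... i + floor(w/2); trailing uses i - w + 1 ... i.
    Windows are clipped at chromosome ends.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values)
    if window == 1 or len(values) <= 1:
        return values.copy()
    # scipy's origin shifts the window left for positive values:
    # window(i) = [i - w//2 - origin, i + w - 1 - w//2 - origin]
    if align == "centered":
        # window [i - ceil(w/2) + 1, i + floor(w/2)]
        origin = 0 if window % 2 else -1
    elif align == "trailing":
        # window [i - w + 1, i]
        origin = (window - 1) // 2
    else:
        raise ValueError("align must be 'centered' or 'trailing'")
    if len(values) < window:
        # track shorter than the window: evaluate clipped windows directly
        if align == "centered":
            back, fwd = (window + 1) // 2 - 1, window // 2
        else:
            back, fwd = window - 1, 0
        n = len(values)
        return np.array([values[max(0, i - back):min(n, i + fwd + 1)].max()
                         for i in range(n)])
    # mode="nearest" replicates edge values, which max-reduces identically
    # to clipping the window at chromosome ends
    return maximum_filter1d(values, size=window, mode="nearest", origin=origin)


def smooth_track(track: CountTrack, window: int,
                 align: str = "centered") -> CountTrack:
    return CountTrack(track.chrom, track.klass, track.breakpoints.copy(),
                      track.values.copy(),
                      smoothed=smooth_values(track.values, window, align))


# ---------------------------------------------------------------------------
# local maxima and prominence
# ---------------------------------------------------------------------------

def _runs(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Run-length encode: list of (lo, hi) half-open index runs with value."""
    out = []
    lo = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[lo]:
            out.append((lo, i, values[lo]))
            lo = i
    return out


def find_local_maxima(values: np.ndarray) -> list[tuple[int, int]]:
    """Apex plateaus: maximal equal-value runs strictly above both neighbors.

    A run touching a chromosome end qualifies if strictly above its single
    inner neighbor; a constant nonzero track yields one apex spanning it.
    Zero-height runs are never apexes.
    """
    values = np.asarray(values)
    apexes = []
    runs = _runs(values)
    for k, (lo, hi, val) in enumerate(runs):
        if val <= 0:
            continue
        left_ok = k == 0 or runs[k - 1][2] < val
        right_ok = k == len(runs) - 1 or runs[k + 1][2] < val
        if left_ok and right_ok:
            apexes.append((lo, hi))
    return apexes


def prominence(raw: np.ndarray, apex: tuple[int, int]) -> int:
    """Topographic prominence of an apex on the unsmoothed track.

    Walk outward from the apex on each side recording the running minimum
    until an interval higher than the apex is met; that minimum is the
    side's col. Prominence is the height minus the highest col among sides
    that reach higher terrain, or the full height when neither side does
    (sea level 0 at both chromosome ends).
    """
    raw = np.asarray(raw)
    lo, hi = apex
    if not (0 <= lo < hi <= len(raw)):
        raise ValueError("apex not on track")
    h = raw[lo:hi].max()
    cols = []
    for rng in (range(lo - 1, -1, -1), range(hi, len(raw))):
        minv = h
        for i in rng:
            if raw[i] > h:
                cols.append(minv)
                break
            minv = min(minv, raw[i])
    return int(h - max(cols)) if cols else int(h)


def prominence_oracle(raw: np.ndarray, apex: tuple[int, int]) -> int:
    """Flood-fill reference for the same contour definition (testing aid).

    Descending from the apex height, the prominence is the height minus the
    largest level whose connected region containing the apex already holds
    an interval higher than the apex; if no level does, it is the height.
    """
    raw = np.asarray(raw)
    lo, hi = apex
    h = int(raw[lo:hi].max())
    for level in range(h, -1, -1):
        above = raw >= level
        # connected run containing the apex
        i = lo
        while i > 0 and above[i - 1]:
            i -= 1
        j = hi - 1
        while j < len(raw) - 1 and above[j + 1]:
            j += 1
        if (raw[i:j + 1] > h).any():
            return h - level
    return h


# ---------------------------------------------------------------------------
# peak calling and gene assignment
# ---------------------------------------------------------------------------

def call_peaks_chrom(segments: pd.DataFrame, klass: str, genome: GenomeLayout,
                     chrom: str, config: PipelineConfig = PipelineConfig()
                     ) -> tuple[list[Peak], CountTrack]:
    """Unranked peaks above the prominence threshold for one chromosome."""
    track = build_count_track(segments, klass, genome, chrom)
    track = smooth_track(track, config.smoothing_window, config.smoothing_align)
    peaks = []
    for lo, hi in find_local_maxima(track.smoothed):
        prom = prominence(track.values, (lo, hi))
        if prom < config.prominence_threshold:
            continue
        height = int(track.values[lo:hi].max())
        peaks.append(Peak(chrom, klass,
                          int(track.breakpoints[lo]), int(track.breakpoints[hi]),
                          height, prom,
                          spans_chromosome=(lo == 0 and hi == len(track.values))))
    return peaks, track


def call_peaks(segments: pd.DataFrame, klass: str, genome: GenomeLayout,
               config: PipelineConfig = PipelineConfig(),
               genes: pd.DataFrame | None = None) -> list[Peak]:
    """Ranked peaks of one class across the genome.

    Rank 1 is the most prominent; ties break by height, then genomic order.
    """
    peaks: list[Peak] = []
    for chrom in genome.names:
        peaks.extend(call_peaks_chrom(segments, klass, genome, chrom, config)[0])
    peaks.sort(key=lambda p: (-p.prominence, -p.height,
                              genome.chrom_index(p.chrom), p.apex_start))
    for i, p in enumerate(peaks):
        p.rank = i + 1
        if genes is not None:
            p.genes = assign_genes(p, genes)
    return peaks


def call_all_peaks(segments: pd.DataFrame, genome: GenomeLayout,
                   config: PipelineConfig = PipelineConfig(),
                   genes: pd.DataFrame | None = None) -> list[Peak]:
    """Gain and loss peaks, ranked jointly by prominence."""
    peaks = (call_peaks(segments, "gain", genome, config, genes=None)
             + call_peaks(segments, "loss", genome, config, genes=None))
    peaks.sort(key=lambda p: (-p.prominence, -p.height,
                              genome.chrom_index(p.chrom), p.apex_start))
    for i, p in enumerate(peaks):
        p.rank = i + 1
        if genes is not None:
            p.genes = assign_genes(p, genes)
    return peaks


def assign_genes(peak: Peak, genes: pd.DataFrame) -> tuple[str, ...]:
    """Genes overlapping the apex; if none, the nearest gene on each side."""
    on_chrom = genes[genes["chrom"] == peak.chrom]
    hit = on_chrom[(on_chrom["start"] < peak.apex_end)
                   & (on_chrom["end"] > peak.apex_start)]
    if len(hit):
        return tuple(hit["name"])
    flanks = []
    left = on_chrom[on_chrom["end"] <= peak.apex_start]
    if len(left):
        flanks.append(left.loc[left["end"].idxmax(), "name"])
    right = on_chrom[on_chrom["start"] >= peak.apex_end]
    if len(right):
        flanks.append(right.loc[right["start"].idxmin(), "name"])
    return tuple(flanks)
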