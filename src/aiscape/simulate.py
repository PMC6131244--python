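"""Synthetic tumor/normal SNP-array cohort generator with known ground truth.

The emission model mixes normal cells (genotype AB) with a tumor clone at
purity rho; a fraction f of tumor cells carry each event with ``c_t`` total
and ``b_t`` B-allele copies. Observed BAF/LRR are the mixture expectations
plus Gaussian array noise; LRR is attenuated by a compression factor alpha,
as on genotyping arrays. Somatic SNVs accrue at a constant rate per Mb per
chromosomal copy, and sequencing depth scales with the local total copy
ratio so read counts behave like shotgun coverage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from . import intervals

# (total copies, B-allele copies) per event class in the tumor clone
_EVENT_COPIES = {
    "loss_del": (1, 0),
    "cnloh": (2, 0),
    "gain": (3, 2),
    "homdel": (0, 0),
}


@dataclass(frozen=True)
class DriverLocus:
    """A planted recurrent lesion: clonal event centred on one locus."""
    name: str
    chrom: str
    pos: int
    klass: str                       # loss_del | cnloh | gain
    prob: float                      # per-sample event probability
    clonal_fraction: tuple[float, float] = (1.0, 1.0)   # (lo, hi) for f


@dataclass(frozen=True)
class FragileSite:
    name: str
    chrom: str
    pos: int
    prob_mss: float = 0.05
    prob_msi: float = 0.25


def default_drivers() -> tuple[DriverLocus, ...]:
    mb = 1_000_000
    return (
        DriverLocus("DRV1", "chr1", 20 * mb, "loss_del", 0.60),
        DriverLocus("DRV2", "chr1", 70 * mb, "gain", 0.50),
        DriverLocus("DRV3", "chr3", 25 * mb, "cnloh", 0.40),
        DriverLocus("DRV4", "chr3", 80 * mb, "gain", 0.30),
        DriverLocus("DRV5", "chr4", 30 * mb, "loss_del", 0.20),
        DriverLocus("DRV6", "chr5", 60 * mb, "gain", 0.10),
    )


def default_fragile_sites() -> tuple[FragileSite, ...]:
    mb = 1_000_000
    return (FragileSite("FRA_A", "chr3", 60 * mb + 500_000),
            FragileSite("FRA_B", "chr5", 20 * mb + 500_000))


@dataclass
class SimulationConfig:
    genome: GenomeLayout = field(default_factory=GenomeLayout.default_toy)
    n_samples: int = 60
    snp_density_per_mb: float = 100.0
    # sample composition
    purity_alpha: float = 5.0          # purity ~ Beta(alpha, beta)
    purity_beta: float = 3.0
    msi_fraction: float = 0.15
    tp53_fraction: float = 0.55        # point-mutation prevalence of the instability marker
    tp53_rate_multiplier: float = 2.0  # background event-rate multiplier when mutated
    # events
    arm_event_rate_mss: float = 6.0    # Poisson mean of background arm events per sample
    arm_event_rate_msi: float = 1.5
    background_exclude_chroms: tuple[str, ...] = ()  # keep these free of background events
    subclonal_range: tuple[float, float] = (0.3, 1.0)
    drivers: tuple[DriverLocus, ...] = field(default_factory=default_drivers)
    driver_extent_mb: tuple[float, float] = (5.0, 30.0)
    iso_chrom: Optional[str] = "chr2"
    iso_prob: float = 0.2
    iso_stub_bp: int = 1_000_000       # retained (neutral) p-terminal stub
    fragile_sites: tuple[FragileSite, ...] = field(default_factory=default_fragile_sites)
    fragile_del_size: tuple[int, int] = (100_000, 1_000_000)
    homdel_loci: tuple[tuple[str, int], ...] = (("chr4", 70_500_000),)
    homdel_prob: float = 0.02
    homdel_size: tuple[int, int] = (200_000, 500_000)
    # emission noise
    lrr_attenuation: float = 0.55
    lrr_floor: float = -5.0
    sigma_lrr: float = 0.15
    sigma_baf: float = 0.03
    # somatic SNVs
    snv_rate_per_mb_per_copy: float = 0.05
    depth_mean: float = 40.0           # mean depth at diploid copy ratio
    depth_shape: float = 10.0          # negative-binomial dispersion (larger = tighter)
    callable_fraction: float = 0.8
    # expression
    expression_slope: float = 1.0      # dosage response per LRR unit
    expression_purity_coef: float = 0.5
    expression_sigma: float = 0.5
    n_null_genes: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.msi_fraction <= 1:
            raise ValueError("msi_fraction must be in [0,1]")
        if self.snp_density_per_mb <= 0 or self.snv_rate_per_mb_per_copy < 0:
            raise ValueError("densities/rates must be positive")
        for d in self.drivers:
            if d.chrom not in self.genome.names or not (
                    0 <= d.pos < self.genome.length(d.chrom)):
                raise ValueError(f"driver locus {d.name} outside genome")
        for fs in self.fragile_sites:
            if fs.chrom not in self.genome.names:
                raise ValueError(f"fragile site {fs.name} outside genome")

    @classmethod
    def peak_recovery_scenario(cls, n_samples: int = 300) -> "SimulationConfig":
        """Validation design for planted-peak recovery.

        Six clonal drivers at 10-60% recurrence on a sparse background
        (0.25 arm events/sample, no isochromosome/fragile/homozygous events).
        Two of the three background event classes fall on the loss track, so
        the expected per-arm loss coverage is n * (rate/arms) * 2/3 = 5
        tumors at n=300 — well below the 15-tumor reporting threshold, so
        every reported peak must reflect a planted locus.
        """
        return cls(n_samples=n_samples,
                   arm_event_rate_mss=0.25, arm_event_rate_msi=0.25,
                   tp53_rate_multiplier=1.0, iso_prob=0.0,
                   fragile_sites=(), homdel_prob=0.0, homdel_loci=())

    # ---- (de)serialisation for YAML configs ----------------------------
    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        d = {k: listify(v) for k, v in dataclasses.asdict(self).items()}
        d["genome"] = {"chromosomes": [list(c) for c in self.genome.chromosomes],
                       "centromeres": [list(c) for c in self.genome.centromeres]}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "genome" in d:
            g = d["genome"]
            d["genome"] = GenomeLayout(
                tuple((n, int(ln)) for n, ln in g["chromosomes"]),
                tuple((n, int(p)) for n, p in g["centromeres"]))
        if "drivers" in d:
            d["drivers"] = tuple(
                DriverLocus(**{**dd, "clonal_fraction": tuple(dd.get("clonal_fraction", (1.0, 1.0)))})
                for dd in d["drivers"])
        if "fragile_sites" in d:
            d["fragile_sites"] = tuple(FragileSite(**f) for f in d["fragile_sites"])
        for key in ("subclonal_range", "driver_extent_mb", "fragile_del_size", "homdel_size"):
            if key in d:
                d[key] = tuple(d[key])
        if "homdel_loci" in d:
            d["homdel_loci"] = tuple((c, int(p)) for c, p in d["homdel_loci"])
        return cls(**d)


# ---------------------------------------------------------------------------
# emission model
# ---------------------------------------------------------------------------

def expected_baf(purity, clonal_fraction, tumor_copies, tumor_b_copies):
    """Expected B-allele frequency under the normal/tumor mixture.

    Normal cells contribute one B copy of two; a fraction ``clonal_fraction``
    of tumor cells carries (``tumor_copies``, ``tumor_b_copies``), the rest
    stay diploid heterozygous. Returns NaN where no DNA remains (pure clonal
    homozygous deletion).
    """
    rho = np.asarray(purity, dtype=float)
    f = np.asarray(clonal_fraction, dtype=float)
    c = np.asarray(tumor_copies, dtype=float)
    b = np.asarray(tumor_b_copies, dtype=float)
    num = (1 - rho) + rho * ((1 - f) + f * b)
    den = 2 * (1 - rho) + rho * (2 * (1 - f) + f * c)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def expected_lrr(purity, clonal_fraction, tumor_copies, attenuation=0.55,
                 floor=-5.0):
    """Expected LRR: attenuated log2 of the mixture copy ratio, floored."""
    rho = np.asarray(purity, dtype=float)
    f = np.asarray(clonal_fraction, dtype=float)
    c = np.asarray(tumor_copies, dtype=float)
    ratio = (2 * (1 - rho) + rho * (2 * (1 - f) + f * c)) / 2.0
    with np.errstate(divide="ignore"):
        out = attenuation * np.log2(np.maximum(ratio, 0.0))
    out = np.maximum(out, floor)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class Event:
    chrom: str
    start: int
    end: int
    klass: str          # loss_del | cnloh | gain | homdel
    f: float            # clonal fraction in tumor cells
    c_t: int
    b_t: int
    origin: str         # background | driver:NAME | isochromosome | fragile:NAME | homdel_locus

    def to_tuple(self):
        return (self.chrom, self.start, self.end, self.klass, self.f,
                self.c_t, self.b_t, self.origin)


@dataclass
class SampleTruth:
    sample_id: str
    purity: float
    msi_status: str
    tp53_status: str
    events: list[Event]
    isochromosomes: list[str]


@dataclass
class CohortTruth:
    samples: dict[str, SampleTruth]
    drivers: tuple[DriverLocus, ...]
    snv_truth: pd.DataFrame  # sample_id, chrom, pos, c_t, multiplicity
    snv_rate_per_mb_per_copy: float

    def driver_recurrence(self, name: str) -> int:
        """Number of samples carrying the named planted driver event."""
        return sum(any(ev.origin == f"driver:{name}" for ev in st.events)
                   for st in self.samples.values())

    def to_json(self, path) -> None:
        payload = {
            "snv_rate_per_mb_per_copy": self.snv_rate_per_mb_per_copy,
            "drivers": [dataclasses.asdict(d) for d in self.drivers],
            "samples": {
                sid: {
                    "purity": st.purity, "msi_status": st.msi_status,
                    "tp53_status": st.tp53_status,
                    "isochromosomes": st.isochromosomes,
                    "events": [ev.to_tuple() for ev in st.events],
                } for sid, st in self.samples.items()},
            "snv_truth": self.snv_truth.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        with open(path) as fh:
            payload = json.load(fh)
        samples = {}
        for sid, st in payload["samples"].items():
            events = [Event(*ev) for ev in st["events"]]
            samples[sid] = SampleTruth(sid, st["purity"], st["msi_status"],
                                       st["tp53_status"], events,
                                       st["isochromosomes"])
        drivers = tuple(DriverLocus(**{**d, "clonal_fraction": tuple(d["clonal_fraction"])})
                        for d in payload["drivers"])
        return cls(samples, drivers, pd.DataFrame(payload["snv_truth"]),
                   payload["snv_rate_per_mb_per_copy"])


@dataclass
class Cohort:
    """Everything the simulator emits for one cohort."""
    probes: pd.DataFrame          # sample_id, chrom, pos, baf, lrr
    snvs: pd.DataFrame            # sample_id, chrom, pos, ref_reads, alt_reads, vaf
    meta: pd.DataFrame            # sample_id, msi_status, purity, tp53_status
    genes: pd.DataFrame           # chrom, start, end, name
    mask: pd.DataFrame            # chrom, start, end
    expression: pd.DataFrame     # gene, sample_id, lrr, expression
    truth: CohortTruth
    genome: GenomeLayout
    config: SimulationConfig


# ---------------------------------------------------------------------------
# event sampling
# ---------------------------------------------------------------------------

def _uniform(rng, lo_hi):
    lo, hi = lo_hi
    return lo if lo == hi else float(rng.uniform(lo, hi))


def _overlaps(events, chrom, start, end) -> bool:
    return any(ev.chrom == chrom and ev.start < end and start < ev.end
               for ev in events)


def _draw_events(cfg: SimulationConfig, rng: np.random.Generator,
                 msi: bool, tp53_mut: bool) -> tuple[list[Event], list[str]]:
    genome = cfg.genome
    events: list[Event] = []
    isochroms: list[str] = []

    # planted drivers: clonal-by-default events centred on the locus
    for d in cfg.drivers:
        if rng.random() >= d.prob:
            continue
        arm = "p" if d.pos < genome.centromere(d.chrom) else "q"
        a_lo, a_hi = genome.arm(d.chrom, arm)
        ext_l = int(_uniform(rng, cfg.driver_extent_mb) * 1e6)
        ext_r = int(_uniform(rng, cfg.driver_extent_mb) * 1e6)
        start = max(a_lo, d.pos - ext_l)
        end = min(a_hi, d.pos + ext_r)
        c, b = _EVENT_COPIES[d.klass]
        f = _uniform(rng, d.clonal_fraction)
        if not _overlaps(events, d.chrom, start, end):
            events.append(Event(d.chrom, start, end, d.klass, f, c, b,
                                f"driver:{d.name}"))

    # isochromosome on the designated chromosome: p-arm loss (minus retained
    # terminal stub) coupled with q-arm gain, clonal, single event
    if cfg.iso_chrom is not None and rng.random() < cfg.iso_prob:
        cen = genome.centromere(cfg.iso_chrom)
        ln = genome.length(cfg.iso_chrom)
        stub = min(cfg.iso_stub_bp, cen // 2)
        if not _overlaps(events, cfg.iso_chrom, stub, ln):
            events.append(Event(cfg.iso_chrom, stub, cen, "loss_del", 1.0, 1, 0,
                                "isochromosome"))
            events.append(Event(cfg.iso_chrom, cen, ln, "gain", 1.0, 3, 2,
                                "isochromosome"))
            isochroms.append(cfg.iso_chrom)

    # background arm-level events (chromosomal instability)
    rate = cfg.arm_event_rate_msi if msi else cfg.arm_event_rate_mss
    if tp53_mut:
        rate *= cfg.tp53_rate_multiplier
    bg_chroms = [c for c in genome.names if c not in cfg.background_exclude_chroms]
    for _ in range(rng.poisson(rate)):
        chrom = bg_chroms[rng.integers(len(bg_chroms))]
        arm = "p" if rng.random() < 0.5 else "q"
        start, end = genome.arm(chrom, arm)
        klass = ("loss_del", "cnloh", "gain")[rng.integers(3)]
        if _overlaps(events, chrom, start, end):
            continue
        c, b = _EVENT_COPIES[klass]
        events.append(Event(chrom, start, end, klass, _uniform(rng, cfg.subclonal_range),
                            c, b, "background"))

    # focal fragile-site deletions, enriched in MSI samples
    for fs in cfg.fragile_sites:
        prob = fs.prob_msi if msi else fs.prob_mss
        if rng.random() >= prob:
            continue
        size = int(rng.integers(cfg.fragile_del_size[0], cfg.fragile_del_size[1] + 1))
        start = max(0, fs.pos - size // 2)
        end = min(genome.length(fs.chrom), start + size)
        if not _overlaps(events, fs.chrom, start, end):
            events.append(Event(fs.chrom, start, end, "loss_del",
                                _uniform(rng, cfg.subclonal_range), 1, 0,
                                f"fragile:{fs.name}"))

    # rare clonal homozygous deletions
    for chrom, pos in cfg.homdel_loci:
        if rng.random() >= cfg.homdel_prob:
            continue
        size = int(rng.integers(cfg.homdel_size[0], cfg.homdel_size[1] + 1))
        start = max(0, pos - size // 2)
        end = min(genome.length(chrom), start + size)
        if not _overlaps(events, chrom, start, end):
            events.append(Event(chrom, start, end, "homdel", 1.0, 0, 0,
                                "homdel_locus"))
    return events, isochroms


# ---------------------------------------------------------------------------
# probe emission
# ---------------------------------------------------------------------------

def emit_probes(cfg: SimulationConfig, rng: np.random.Generator,
                events: list[Event], purity: float) -> pd.DataFrame:
    """Per-probe BAF/LRR for one sample under the mixture emission model."""
    frames = []
    for chrom, length in cfg.genome.chromosomes:
        n = int(round(cfg.snp_density_per_mb * length / 1e6))
        pos = np.sort(rng.integers(0, length, size=n))
        f = np.ones(n)
        c = np.full(n, 2.0)
        b = np.ones(n)
        for ev in events:
            if ev.chrom != chrom:
                continue
            idx = (pos >= ev.start) & (pos < ev.end)
            f[idx], c[idx], b[idx] = ev.f, ev.c_t, ev.b_t
        eb = expected_baf(purity, f, c, b)
        eb = np.where(np.isnan(eb), 0.5, eb)   # no-DNA regime: noise around 0.5
        swap = rng.random(n) < 0.5             # which homolog carries the B allele
        mean_baf = np.where(swap, 1.0 - eb, eb)
        baf = np.clip(mean_baf + rng.normal(0.0, cfg.sigma_baf, n), 0.0, 1.0)
        lrr = (expected_lrr(purity, f, c, cfg.lrr_attenuation, cfg.lrr_floor)
               + rng.normal(0.0, cfg.sigma_lrr, n))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                    "baf": baf, "lrr": lrr}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# somatic SNVs
# ---------------------------------------------------------------------------

def default_callable_mask(genome: GenomeLayout, fraction: float = 0.8,
                          block: int = 1_000_000) -> pd.DataFrame:
    """Regular callable mask: the first ``fraction`` of every 1 Mb block."""
    rows = []
    span = int(block * fraction)
    for chrom, length in genome.chromosomes:
        for start in range(0, length, block):
            rows.append((chrom, start, min(start + span, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _truth_segments(cfg: SimulationConfig, events: list[Event]):
    """Partition each chromosome into constant-copy truth segments."""
    for chrom, length in cfg.genome.chromosomes:
        evs = sorted([e for e in events if e.chrom == chrom], key=lambda e: e.start)
        cursor = 0
        for ev in evs:
            if ev.start > cursor:
                yield chrom, cursor, ev.start, 1.0, 2, 1   # neutral gap
            yield chrom, ev.start, ev.end, ev.f, ev.c_t, ev.b_t
            cursor = ev.end
        if cursor < length:
            yield chrom, cursor, length, 1.0, 2, 1


def place_snvs(cfg: SimulationConfig, rng: np.random.Generator,
               events: list[Event], purity: float,
               mask: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place somatic SNVs at rate mu per callable Mb per chromosomal copy.

    Each SNV has multiplicity 1 (carried on a single copy). Depth follows a
    negative binomial whose mean tracks the local total copy ratio, so the
    expected mutated-read count is independent of copy number while the SNV
    density is proportional to it.
    """
    mu = cfg.snv_rate_per_mb_per_copy
    rows, truth_rows = [], []
    mask_by_chrom = {c: g for c, g in mask.groupby("chrom")}
    for chrom, start, end, f, c_t, b_t in _truth_segments(cfg, events):
        if mu == 0 or c_t == 0:
            continue
        mg = mask_by_chrom.get(chrom)
        if mg is None:
            continue
        s, e = intervals.clip(mg["start"].to_numpy(), mg["end"].to_numpy(), start, end)
        callable_bp = int((e - s).sum())
        if callable_bp == 0:
            continue
        lam = mu * c_t * callable_bp / 1e6
        count = rng.poisson(lam)
        if count == 0:
            continue
        # uniform positions within the callable sub-intervals
        offsets = rng.integers(0, callable_bp, size=count)
        cum = np.concatenate([[0], np.cumsum(e - s)])
        seg_idx = np.searchsorted(cum, offsets, side="right") - 1
        pos = s[seg_idx] + (offsets - cum[seg_idx])
        cbar = 2 * (1 - f) + f * c_t           # mean copies within tumor cells
        mix = 2 * (1 - purity) + purity * cbar  # mixture copies per cell
        vaf = purity * f * 1.0 / mix            # multiplicity m = 1
        mean_depth = cfg.depth_mean * mix / 2.0
        r = cfg.depth_shape
        depth = rng.negative_binomial(r, r / (r + mean_depth), size=count)
        depth = np.maximum(depth, 1)
        alt = rng.binomial(depth, min(vaf, 1.0))
        for p, d_, a in zip(pos, depth, alt):
            rows.append((chrom, int(p), int(d_ - a), int(a)))
            truth_rows.append((chrom, int(p), c_t, 1))
    snvs = pd.DataFrame(rows, columns=["chrom", "pos", "ref_reads", "alt_reads"])
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "c_t", "multiplicity"])
    return snvs, truth


# ---------------------------------------------------------------------------
# genes and expression
# ---------------------------------------------------------------------------

def build_gene_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Driver genes at planted loci plus evenly spaced background genes."""
    rows = [(d.chrom, d.pos - 50_000, d.pos + 50_000, d.name) for d in cfg.drivers]
    per_chrom = max(1, cfg.n_null_genes // max(len(cfg.genome.names), 1))
    for chrom, length in cfg.genome.chromosomes:
        step = length // (per_chrom + 1)
        for k in range(1, per_chrom + 1):
            rows.append((chrom, k * step, k * step + 100_000, f"BG_{chrom}_{k}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _gene_lrr(cfg, events, purity, gene_row) -> float:
    mid = (gene_row.start + gene_row.end) // 2
    for ev in events:
        if ev.chrom == gene_row.chrom and ev.start <= mid < ev.end:
            return expected_lrr(purity, ev.f, ev.c_t, cfg.lrr_attenuation, cfg.lrr_floor)
    return 0.0


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def iter_samples(cfg: SimulationConfig, seed: int):
    """Yield per-sample simulation results without holding the whole cohort.

    Yields ``(sample_truth, probes, snvs, snv_truth, gene_lrr_dict)`` in
    sample order; identical streams for identical seeds.
    """
    genes = build_gene_table(cfg)
    mask = default_callable_mask(cfg.genome, cfg.callable_fraction)
    seeds = np.random.SeedSequence(seed).spawn(cfg.n_samples)
    driver_names = {d.name for d in cfg.drivers}
    for i in range(cfg.n_samples):
        rng = np.random.default_rng(seeds[i])
        sid = f"S{i + 1:04d}"
        purity = float(rng.beta(cfg.purity_alpha, cfg.purity_beta))
        purity = min(max(purity, 0.05), 1.0)
        msi = rng.random() < cfg.msi_fraction
        tp53 = rng.random() < cfg.tp53_fraction
        events, isochroms = _draw_events(cfg, rng, msi, tp53)
        truth = SampleTruth(sid, purity, "MSI" if msi else "MSS",
                            "mutated" if tp53 else "WT", events, isochroms)
        probes = emit_probes(cfg, rng, events, purity)
        probes.insert(0, "sample_id", sid)
        snvs, snv_truth = place_snvs(cfg, rng, events, purity, mask)
        if len(snvs):
            snvs.insert(0, "sample_id", sid)
            snv_truth.insert(0, "sample_id", sid)
        gl = {g.name: _gene_lrr(cfg, events, purity, g)
              for g in genes.itertuples() if g.name in driver_names or True}
        yield truth, probes, snvs, snv_truth, gl


def simulate_cohort(cfg: SimulationConfig, seed: int) -> Cohort:
    """Simulate a full cohort; deterministic for a given seed."""
    genes = build_gene_table(cfg)
    mask = default_callable_mask(cfg.genome, cfg.callable_fraction)
    driver_names = {d.name for d in cfg.drivers}
    probe_frames, snv_frames, snvt_frames = [], [], []
    samples: dict[str, SampleTruth] = {}
    expr_rows = []
    expr_rng = np.random.default_rng(np.random.SeedSequence([seed, 991]))
    for truth, probes, snvs, snv_truth, gene_lrr in iter_samples(cfg, seed):
        samples[truth.sample_id] = truth
        probe_frames.append(probes)
        if len(snvs):
            snv_frames.append(snvs)
            snvt_frames.append(snv_truth)
        for gene, lrr in gene_lrr.items():
            lrr_obs = lrr + expr_rng.normal(0.0, 0.05)
            dosage = cfg.expression_slope * lrr if gene in driver_names else 0.0
            expr = (dosage + cfg.expression_purity_coef * truth.purity
                    + expr_rng.normal(0.0, cfg.expression_sigma))
            expr_rows.append((gene, truth.sample_id, lrr_obs, expr))
    probes = pd.concat(probe_frames, ignore_index=True)
    snvs = (pd.concat(snv_frames, ignore_index=True) if snv_frames
            else pd.DataFrame(columns=["sample_id", "chrom", "pos",
                                       "ref_reads", "alt_reads"]))
    if len(snvs):
        snvs["vaf"] = snvs["alt_reads"] / (snvs["ref_reads"] + snvs["alt_reads"])
    else:
        snvs["vaf"] = pd.Series(dtype=float)
    snv_truth = (pd.concat(snvt_frames, ignore_index=True) if snvt_frames
                 else pd.DataFrame(columns=["sample_id", "chrom", "pos",
                                            "c_t", "multiplicity"]))
    meta = pd.DataFrame(
        {"sample_id": list(samples),
         "msi_status": [samples[s].msi_status for s in samples],
         "purity": [samples[s].purity for s in samples],
         "tp53_status": [samples[s].tp53_status for s in samples]})
    expression = pd.DataFrame(expr_rows,
                              columns=["gene", "sample_id", "lrr", "expression"])
    cohort_truth = CohortTruth(samples, cfg.drivers, snv_truth,
                               cfg.snv_rate_per_mb_per_copy)
    return Cohort(probes, snvs, meta, genes, mask, expression, cohort_truth,
                  cfg.genome, cfg)
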