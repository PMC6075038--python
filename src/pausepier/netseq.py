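"""NET-seq pause analysis: robust-Z peak calling, sliding-window cluster
discovery with density scoring, fragment-level genotype ratios, dwell times
and genotype-dependence classification.

A pause peak is a position whose log2 read-start count is a robust-Z
outlier within its region (centromere fragment or transcript) and carries a
minimum number of unique reads.  Peaks are grouped by a sliding window into
clusters whose density (reads/kb over the occupied span) summarizes pausing
strength; comparing fragment-level cluster densities between genotypes
localizes the sequence segments whose pausing depends on the RNA-binding
protein under study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import Interval, SampleMeta, SignalTrack, rpm_normalize
from .stats import ks_two_sample, robust_zscore


@dataclass(frozen=True)
class Peak:
    chrom: str
    strand: str
    pos: int
    reads: float
    z: float

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.chrom, self.strand, self.pos)


@dataclass
class PeakCluster:
    iv: Interval
    peaks: list[Peak]
    reads_total: float
    density: float  # reads per kb over the cluster span

    def __post_init__(self) -> None:
        expect = self.reads_total * 1000.0 / self.iv.length
        if not math.isclose(self.density, expect, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("cluster density inconsistent with reads_total and span")


@dataclass
class DwellRecord:
    peak: Peak
    dwell: float  # peak reads / mean signal of surrounding 100 nt; may be inf
    genotype: str = ""
    replicate: int = 1
    seb1_dependent: bool | None = None


def call_peaks(
    track: SignalTrack,
    region: Interval,
    z_min: float = 2.0,
    min_reads: float = 10,
) -> list[Peak]:
    """Call pause peaks inside ``region`` on its strand.

    Robust Z-scores are computed over the log2 counts of the positions with
    at least one read in the region (zero positions carry no evidence of an
    engaged polymerase and are excluded); a peak needs Z >= ``z_min`` and
    at least ``min_reads`` reads.
    """
    counts = track.region_values(region)
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        return []
    z, degenerate = robust_zscore(np.log2(counts[nz]))
    if degenerate:
        return []
    keep = (z >= z_min) & (counts[nz] >= min_reads)
    return [
        Peak(region.chrom, region.strand, int(region.start + i), float(counts[i]), float(zi))
        for i, zi in zip(nz[keep], z[keep])
    ]


def find_clusters(
    peaks: Sequence[Peak],
    track: SignalTrack,
    region: Interval,
    width: int = 50,
    step: int = 10,
) -> list[PeakCluster]:
    """Group peaks with a sliding window (default width 50 nt, step 10 nt).

    Windows tile ``[region.start + j*step, region.start + j*step + width)``;
    two peaks belong to the same cluster iff some window contains both
    (taking the transitive closure).  The cluster interval spans from the
    first to the last member peak, and ``reads_total`` counts every read
    start inside that span, not only the peak positions.
    """
    if width < step:
        raise ValueError("width must be >= step (otherwise windows leave gaps)")
    if not peaks:
        return []
    peaks = sorted(peaks, key=lambda p: p.pos)
    for p in peaks:
        if not region.contains(p.chrom, p.pos):
            raise ValueError(f"peak at {p.chrom}:{p.pos} outside region")

    def connected(p1: int, p2: int) -> bool:
        # best window covering both starts at the last grid point <= p1
        g = region.start + ((p1 - region.start) // step) * step
        return p2 - g < width

    groups: list[list[Peak]] = [[peaks[0]]]
    for prev, cur in zip(peaks, peaks[1:]):
        if connected(prev.pos, cur.pos):
            groups[-1].append(cur)
        else:
            groups.append([cur])

    clusters = []
    for members in groups:
        iv = Interval(
            region.chrom, members[0].pos, members[-1].pos + 1, region.strand
        )
        reads_total = track.region_sum(iv)
        clusters.append(
            PeakCluster(
                iv=iv,
                peaks=members,
                reads_total=reads_total,
                density=reads_total * 1000.0 / iv.length,
            )
        )
    return clusters


class FragmentRatioRow(NamedTuple):
    fragment: str
    strand: str
    ratio: float  # mean over replicate pairs; inf/nan flagged via `flag`
    ratio_lo: float
    ratio_hi: float
    flag: str  # "", "n.p." (no peaks in numerator genotype) or "inf"


def fragment_cluster_ratio(
    clusters_by_sample: Mapping[SampleMeta, Sequence[PeakCluster]],
    fragments: Sequence[Interval],
    numerator_genotype: str,
    denominator_genotype: str,
) -> pd.DataFrame:
    """Per-fragment, per-strand genotype ratio of normalized cluster density.

    Within each sample, a fragment's score is the sum of densities of the
    clusters whose midpoint falls in the fragment (on the given strand),
    divided by the sum of all cluster densities in that sample.  Ratios
    (numerator genotype / denominator genotype) are taken per replicate
    pair; the reported value is their mean, with the replicate range as
    error bounds.  A ratio of 1 means no genotype effect.
    """
    by_geno: dict[str, dict[int, Sequence[PeakCluster]]] = {}
    for meta, clusters in clusters_by_sample.items():
        by_geno.setdefault(meta.genotype, {})[meta.replicate] = clusters
    for g in (numerator_genotype, denominator_genotype):
        if g not in by_geno:
            raise ValueError(f"genotype {g!r} absent from samples")
    reps = sorted(
        set(by_geno[numerator_genotype]) & set(by_geno[denominator_genotype])
    )
    if not reps:
        raise ValueError("no shared replicates between genotypes")

    def score(clusters: Sequence[PeakCluster], frag: Interval, strand: str) -> float:
        total = sum(c.density for c in clusters)
        if total == 0:
            return 0.0
        inside = sum(
            c.density
            for c in clusters
            if c.iv.strand == strand and frag.contains(c.iv.chrom, c.iv.midpoint)
        )
        return inside / total

    rows = []
    for frag in fragments:
        for strand in ("+", "-"):
            ratios: list[float] = []
            num_any = False
            for r in reps:
                num = score(by_geno[numerator_genotype][r], frag, strand)
                den = score(by_geno[denominator_genotype][r], frag, strand)
                if num > 0:
                    num_any = True
                if den == 0:
                    ratios.append(math.inf if num > 0 else math.nan)
                else:
                    ratios.append(num / den)
            if not num_any:
                flag, val, lo, hi = "n.p.", math.nan, math.nan, math.nan
            else:
                finite = [x for x in ratios if math.isfinite(x)]
                if any(math.isinf(x) for x in ratios):
                    flag, val = "inf", math.inf
                    lo = min(finite) if finite else math.inf
                    hi = math.inf
                else:
                    flag = ""
                    val = float(np.mean(finite))
                    lo, hi = min(finite), max(finite)
            rows.append(
                FragmentRatioRow(frag.name or f"{frag.chrom}:{frag.start}-{frag.end}",
                                 strand, val, lo, hi, flag)
            )
    return pd.DataFrame(rows)


def dwell_time(track: SignalTrack, peak: Peak, flank: int = 100) -> float:
    """Peak height over the mean signal of the surrounding ``flank`` nt
    (half on each side, excluding the peak position, truncated at
    chromosome ends).  Returns +inf when the flanks carry no signal."""
    v = track.values(peak.chrom, peak.strand)
    half = flank // 2
    lo = max(peak.pos - half, 0)
    hi = min(peak.pos + half + 1, v.size)
    window = np.concatenate((v[lo : peak.pos], v[peak.pos + 1 : hi]))
    if window.size == 0:
        return math.inf
    mean = float(window.mean())
    if mean == 0:
        return math.inf
    return float(v[peak.pos]) / mean


def classify_seb1_dependent(
    peaks_by_rep: Sequence[Sequence[Peak]],
    tracks_wt: Sequence[SignalTrack],
    tracks_mut: Sequence[SignalTrack],
    fold: float = 2.0,
) -> list[tuple[Peak, bool]]:
    """Label reference-genotype peaks whose RPM signal drops at least
    ``fold``-fold in the mutant in every replicate pair.

    A peak must be called at the exact same position in every reference
    replicate to be eligible; eligible peaks are dependent iff
    ``wt_rpm >= fold * mut_rpm`` for each replicate pair (a mutant signal
    of 0 counts as an infinite fold change).  All other peaks are
    independent.
    """
    if len(peaks_by_rep) < 2:
        raise ValueError("need >= 2 replicate peak sets")
    if len(tracks_wt) != len(peaks_by_rep) or len(tracks_mut) != len(peaks_by_rep):
        raise ValueError("one track per replicate per genotype required")
    wt_rpm = [rpm_normalize(t) for t in tracks_wt]
    mut_rpm = [rpm_normalize(t) for t in tracks_mut]

    keysets = [set(p.key for p in reps) for reps in peaks_by_rep]
    replicated = set.intersection(*keysets)

    seen: set[tuple[str, str, int]] = set()
    out: list[tuple[Peak, bool]] = []
    for reps in peaks_by_rep:
        for p in reps:
            if p.key in seen:
                continue
            seen.add(p.key)
            if p.key not in replicated:
                out.append((p, False))
                continue
            dependent = True
            for wt, mut in zip(wt_rpm, mut_rpm):
                w = float(wt.values(p.chrom, p.strand)[p.pos])
                m = float(mut.values(p.chrom, p.strand)[p.pos])
                if m == 0:
                    continue  # infinite fold decrease
                if w < fold * m:
                    dependent = False
                    break
            out.append((p, dependent))
    return out


class DwellComparison(NamedTuple):
    median_dependent: float
    median_independent: float
    ks_statistic: float
    ks_pvalue: float


def dwell_compare(
    dependent: Sequence[DwellRecord], independent: Sequence[DwellRecord]
) -> DwellComparison:
    """Compare dwell-time distributions of dependent vs independent pauses
    (medians plus a two-sample KS test; infinite dwells are excluded)."""
    dep = [r.dwell for r in dependent if math.isfinite(r.dwell)]
    ind = [r.dwell for r in independent if math.isfinite(r.dwell)]
    if not dep or not ind:
        raise ValueError("both dwell classes must be nonempty (after removing inf)")
    ks = ks_two_sample(dep, ind)
    return DwellComparison(
        float(np.median(dep)), float(np.median(ind)), ks.statistic, ks.pvalue
    )


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.chrom, p.pos, p.pos + 1, p.strand, p.reads, p.z) for p in peaks],
        columns=["chrom", "start", "end", "strand", "reads", "z"],
    )


def clusters_to_frame(clusters: Sequence[PeakCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.iv.chrom,
                c.iv.start,
                c.iv.end,
                c.iv.strand,
                len(c.peaks),
                c.reads_total,
                c.density,
            )
            for c in clusters
        ],
        columns=["chrom", "start", "end", "strand", "n_peaks", "reads_total", "density"],
    )
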