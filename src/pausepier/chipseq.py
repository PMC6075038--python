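"""Broad H3K9me2 domain discovery from ChIP-seq: background estimation,
enriched-region calling, PIER (pause-induced ectopic heterochromatic
region) discovery with exclusion rules, and region-enrichment values.

A PIER is a novel broad H3K9me2 domain called with two criteria — the
smoothed IP signal is at least 3-fold over genome background, and the
IP/WCE enrichment over the region is at least 3-fold over both the
enrichment background and the parental strain's enrichment — and excluded
if it lies within 10 kb of a curated heterochromatin-nucleation site or of
an H3K9me2 region already present in the parental strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Interval,
    SignalTrack,
    merge_intervals,
    region_rpkm,
    rpm_normalize,
    smooth_track,
)

EXCLUSION_REASONS = ("near_curated_site", "near_parental_region", "below_threshold", "none")


@dataclass
class PierCall:
    iv: Interval
    peak_fold_over_background: float
    enrichment_fold: float
    parental_fold: float
    excluded: bool
    exclusion_reason: str

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError("excluded flag inconsistent with exclusion_reason")


def prepare_chip_track(track: SignalTrack, window: int = 1000) -> SignalTrack:
    """Standard ChIP preprocessing: 1-kb smoothing then RPM normalization."""
    return rpm_normalize(smooth_track(track, window))


def background_level(track: SignalTrack, mask: Sequence[Interval] = ()) -> float:
    """Genome background: median per-nt value outside the masked intervals."""
    pieces = []
    for chrom, _strand, v in track.iter_chromosomes():
        keep = np.ones(v.size, dtype=bool)
        for iv in mask:
            if iv.chrom == chrom:
                keep[iv.start : iv.end] = False
        pieces.append(v[keep])
    allv = np.concatenate(pieces) if pieces else np.array([])
    if allv.size == 0:
        raise ValueError("mask covers the entire genome")
    return float(np.median(allv))


def find_enriched_regions(
    ip: SignalTrack,
    background: float,
    fold: float = 3.0,
    min_len: int = 1000,
    merge_gap: int = 1000,
) -> list[Interval]:
    """Maximal runs of positions at >= fold x background, with runs closer
    than ``merge_gap`` merged and runs shorter than ``min_len`` dropped."""
    if background <= 0:
        raise ValueError("background must be positive")
    threshold = fold * background
    raw: list[Interval] = []
    for chrom, _strand, v in ip.iter_chromosomes():
        above = v >= threshold
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for s, e in zip(run_starts, run_ends):
            raw.append(Interval(chrom, int(s), int(e)))
    merged = merge_intervals(raw, gap=merge_gap) if raw else []
    return [iv for iv in merged if iv.length >= min_len]


def _ratio_track(num: SignalTrack, den: SignalTrack, eps: float) -> SignalTrack:
    if num.chrom_sizes != den.chrom_sizes:
        raise ValueError("genome mismatch between tracks")
    out = num.copy()
    for key in out.data:
        out.data[key] = (num.data[key] + eps) / (den.data[key] + eps)
    return out


def discover_piers(
    ip: SignalTrack,
    wce: SignalTrack,
    parental_ip: SignalTrack,
    curated_sites: Sequence[Interval],
    fold: float = 3.0,
    exclusion_radius: int = 10_000,
    eps: float = 0.5,
    min_len: int = 1000,
    merge_gap: int = 1000,
) -> list[PierCall]:
    """Candidate ectopic H3K9me2 domains with exclusion flags.

    All tracks must be smoothed and RPM-normalized over the same genome
    (see :func:`prepare_chip_track`).  Each candidate receives exactly one
    exclusion reason (precedence: near_curated_site, near_parental_region,
    below_threshold); candidates with reason ``"none"`` are the PIERs.
    """
    for t in (wce, parental_ip):
        if t.chrom_sizes != ip.chrom_sizes:
            raise ValueError("genome mismatch between tracks")
    parental_bg = background_level(parental_ip, mask=curated_sites)
    parental_regions = (
        find_enriched_regions(parental_ip, parental_bg, fold, min_len, merge_gap)
        if parental_bg > 0
        else []
    )
    mask = list(curated_sites) + parental_regions
    bg = background_level(ip, mask=mask)
    if bg <= 0:
        raise ValueError("zero genome background in the isolate track")
    candidates = find_enriched_regions(ip, bg, fold, min_len, merge_gap)

    enrich = _ratio_track(ip, wce, eps)
    parental_enrich = _ratio_track(parental_ip, wce, eps)
    enrich_bg = background_level(enrich, mask=mask)

    calls: list[PierCall] = []
    for cand in candidates:
        e_mean = float(np.mean(enrich.values(cand.chrom)[cand.start : cand.end]))
        pe_mean = float(
            np.mean(parental_enrich.values(cand.chrom)[cand.start : cand.end])
        )
        peak_fold = float(np.max(ip.values(cand.chrom)[cand.start : cand.end])) / bg
        enrichment_fold = e_mean / enrich_bg if enrich_bg > 0 else math.inf
        parental_fold = e_mean / pe_mean if pe_mean > 0 else math.inf

        reason = "none"
        if any(
            iv.chrom == cand.chrom and cand.distance(iv) < exclusion_radius
            for iv in curated_sites
        ):
            reason = "near_curated_site"
        elif any(
            iv.chrom == cand.chrom and cand.distance(iv) < exclusion_radius
            for iv in parental_regions
        ):
            reason = "near_parental_region"
        elif enrichment_fold < fold or parental_fold < fold:
            reason = "below_threshold"
        calls.append(
            PierCall(
                iv=cand,
                peak_fold_over_background=peak_fold,
                enrichment_fold=enrichment_fold,
                parental_fold=parental_fold,
                excluded=reason != "none",
                exclusion_reason=reason,
            )
        )
    return calls


def pier_list(calls: Sequence[PierCall]) -> list[PierCall]:
    """The unexcluded, criteria-passing subset of candidate calls."""
    return [c for c in calls if not c.excluded]


def region_enrichment_heatmap(
    ip_tracks: Mapping[str, SignalTrack],
    wce: SignalTrack,
    regions: Sequence[Interval],
    flank: int = 5000,
) -> pd.DataFrame:
    """Region enrichment values for a heatmap.

    For each (region, isolate): region RPKM over flank RPKM in the isolate,
    divided by the same ratio in the whole-cell extract.  The flank is up
    to ``flank`` nt on each side of the region (region excluded, truncated
    at chromosome ends).  A zero/empty flank yields NaN (flagged missing).
    """
    rows = []
    for region in regions:
        size = wce.chrom_sizes[region.chrom]
        flanks = []
        if region.start > 0:
            flanks.append(Interval(region.chrom, max(0, region.start - flank), region.start))
        if region.end < size:
            flanks.append(Interval(region.chrom, region.end, min(size, region.end + flank)))

        def ratio(track: SignalTrack) -> float:
            r = region_rpkm(track, region)
            flank_len = sum(iv.length for iv in flanks)
            if flank_len == 0:
                return math.nan
            flank_reads = sum(track.region_sum(iv) for iv in flanks)
            f = (flank_reads / (flank_len / 1000.0)) / (track.total_reads / 1e6)
            if f == 0:
                return math.nan
            return r / f

        wce_ratio = ratio(wce)
        for name, track in ip_tracks.items():
            iso = ratio(track)
            value = (
                math.nan
                if (math.isnan(iso) or math.isnan(wce_ratio) or wce_ratio == 0)
                else iso / wce_ratio
            )
            rows.append(
                {
                    "region": region.name or f"{region.chrom}:{region.start}-{region.end}",
                    "isolate": name,
                    "value": value,
                    "missing": math.isnan(value),
                }
            )
    return pd.DataFrame(rows, columns=["region", "isolate", "value", "missing"])


def piers_to_frame(calls: Sequence[PierCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.iv.chrom,
                "start": c.iv.start,
                "end": c.iv.end,
                "peak_fold": c.peak_fold_over_background,
                "enrichment_fold": c.enrichment_fold,
                "parental_fold": c.parental_fold,
                "excluded": c.excluded,
                "reason": c.exclusion_reason,
            }
            for c in calls
        ],
        columns=[
            "chrom", "start", "end", "peak_fold", "enrichment_fold",
            "parental_fold", "excluded", "reason",
        ],
    )
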