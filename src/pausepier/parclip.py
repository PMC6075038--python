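"""PAR-CLIP binding-site cluster filtering and coverage statistics.

Candidate read clusters (from an external cluster caller or the synthetic
generator) are filtered by the supporting-read rules: reads shorter than
20 nt are discarded first, then a cluster needs at least 10 remaining reads
and at least two T->C conversion events.  The downstream statistic is the
coverage fraction: the proportion of an interval of interest covered by at
least one surviving cluster on the matching strand, compared across feature
classes (pericentromeric repeats vs coding genes vs ncRNAs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import UNSTRANDED, GenomeAnnotation, Interval
from .stats import ks_two_sample


@dataclass(frozen=True)
class ParclipCluster:
    iv: Interval
    read_count: int
    conversion_count: int
    #: lengths of supporting reads; None means lengths unknown (read_count
    #: is then taken at face value by the length filter)
    read_lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.read_count < 0 or self.conversion_count < 0:
            raise ValueError("read/conversion counts must be non-negative")


def filter_clusters(
    candidates: Sequence[ParclipCluster],
    min_read_len: int = 20,
    min_reads: int = 10,
    min_conversions: int = 2,
    dedup: bool = False,
) -> list[ParclipCluster]:
    """Apply the read-length, read-count and conversion-count filters.

    Short reads are removed from the support first; the surviving cluster
    set is a subset of the input and the operation is idempotent.  With
    ``dedup=True``, clusters identical in (interval, strand) are collapsed
    to the first occurrence (flattening of recurrent repeat sequences).
    """
    out: list[ParclipCluster] = []
    seen: set[tuple[str, int, int, str]] = set()
    for c in candidates:
        if c.read_lengths is not None:
            kept = tuple(l for l in c.read_lengths if l >= min_read_len)
            c = replace(c, read_count=len(kept), read_lengths=kept)
        if c.read_count < min_reads or c.conversion_count < min_conversions:
            continue
        if dedup:
            key = (c.iv.chrom, c.iv.start, c.iv.end, c.iv.strand)
            if key in seen:
                continue
            seen.add(key)
        out.append(c)
    return out


def _strand_match(cluster_strand: str, iv_strand: str) -> bool:
    return iv_strand == UNSTRANDED or cluster_strand == UNSTRANDED or cluster_strand == iv_strand


def coverage_fraction(clusters: Sequence[ParclipCluster], iv: Interval) -> float:
    """Fraction of ``iv`` covered by the union of overlapping clusters on
    its strand; in [0, 1] and monotone in the cluster set."""
    segs = sorted(
        (max(c.iv.start, iv.start), min(c.iv.end, iv.end))
        for c in clusters
        if c.iv.chrom == iv.chrom
        and _strand_match(c.iv.strand, iv.strand)
        and c.iv.start < iv.end
        and iv.start < c.iv.end
    )
    covered = 0
    cur_end = iv.start
    for s, e in segs:
        s = max(s, cur_end)
        if e > s:
            covered += e - s
            cur_end = e
    return covered / iv.length


def class_coverage_summary(
    clusters: Sequence[ParclipCluster],
    ann: GenomeAnnotation,
    reference_class: str = "coding",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Coverage-fraction distributions per transcript class.

    Returns (summary, per_interval, ks): class means with fold difference
    over ``reference_class``, the per-interval fractions behind them, and
    pairwise KS tests between class distributions.  Empty classes are
    omitted.
    """
    per_rows = []
    for t in ann.transcripts:
        per_rows.append(
            {
                "transcript_id": t.id,
                "cls": t.cls,
                "fraction": coverage_fraction(clusters, t.interval),
            }
        )
    per = pd.DataFrame(per_rows, columns=["transcript_id", "cls", "fraction"])
    per = per[per["cls"].notna()]
    classes = [c for c in per["cls"].unique() if (per["cls"] == c).any()]

    means = {c: float(per.loc[per["cls"] == c, "fraction"].mean()) for c in classes}
    ref_mean = means.get(reference_class)
    summary = pd.DataFrame(
        [
            {
                "cls": c,
                "n": int((per["cls"] == c).sum()),
                "mean_fraction": means[c],
                "fold_vs_" + reference_class: (
                    means[c] / ref_mean if ref_mean else np.nan
                ),
            }
            for c in classes
        ]
    )
    ks_rows = []
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1 :]:
            x = per.loc[per["cls"] == c1, "fraction"].to_numpy()
            y = per.loc[per["cls"] == c2, "fraction"].to_numpy()
            if x.size == 0 or y.size == 0:
                continue
            ks = ks_two_sample(x, y)
            ks_rows.append(
                {"cls_a": c1, "cls_b": c2, "ks_D": ks.statistic, "ks_p": ks.pvalue}
            )
    return summary, per, pd.DataFrame(ks_rows, columns=["cls_a", "cls_b", "ks_D", "ks_p"])
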