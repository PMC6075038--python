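"""Traveling-ratio (pausing-index) analysis.

The traveling ratio of a transcript is the read density in a fixed window
at one end (500 nt after the TSS for the 5' ratio, 500 nt before the
cleavage/polyadenylation site for the 3' ratio) divided by the read density
over the whole transcript.  Values above 1 indicate polymerase dwelling in
the window.  Transcripts are K-means-clustered on their log ratios in two
genotypes to find classes of genes whose pausing responds to a mutation,
and per-cluster genotype differences are scored by two-sample KS tests.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomeAnnotation, Interval, SignalTrack, Transcript
from .stats import kmeans_fit, ks_two_sample

LOG_FLOOR = 0.01  # floor applied to ratios before log2 (zeros are legitimate)


def eligible_transcripts(
    ann: GenomeAnnotation,
    track: SignalTrack,
    min_len: int = 1000,
    min_reads: float = 50,
) -> list[Transcript]:
    """Transcripts that overlap no other annotated transcript (either
    strand), are at least ``min_len`` nt long, and carry at least
    ``min_reads`` read starts on their own strand."""
    by_chrom: dict[str, list[Transcript]] = {}
    for t in ann.transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    overlapping: set[str] = set()
    for ts in by_chrom.values():
        ts.sort(key=lambda t: t.start)
        for a, b in zip(ts, ts[1:]):
            if b.start < a.end:
                overlapping.add(a.id)
                overlapping.add(b.id)
    out = []
    for t in ann.transcripts:
        if t.id in overlapping or t.length < min_len:
            continue
        if track.region_sum(t.interval) >= min_reads:
            out.append(t)
    return out


def traveling_ratio(
    track: SignalTrack,
    t: Transcript,
    which: str,
    window: int = 500,
) -> float:
    """One traveling ratio (``"tr5"`` or ``"tr3"``) for transcript ``t``.

    Windows are measured in the direction of transcription: on the minus
    strand the 5' window abuts the higher genomic coordinate.
    """
    if which not in ("tr5", "tr3"):
        raise ValueError("which must be 'tr5' or 'tr3'")
    if window > t.length // 2:
        raise ValueError("window exceeds half the transcript length")
    total = track.region_sum(t.interval)
    if total == 0:
        raise ValueError(f"transcript {t.id} has zero reads (pre-filter eligibility)")
    at_low_end = (which == "tr5") == (t.strand == "+")
    if at_low_end:
        win = Interval(t.chrom, t.start, t.start + window, t.strand)
    else:
        win = Interval(t.chrom, t.end - window, t.end, t.strand)
    win_reads = track.region_sum(win)
    return (win_reads / window) / (total / t.length)


def traveling_ratio_table(
    ann: GenomeAnnotation,
    track: SignalTrack,
    min_len: int = 1000,
    min_reads: float = 50,
    window: int = 500,
) -> pd.DataFrame:
    """tr5/tr3 for every eligible transcript of one sample."""
    rows = []
    for t in eligible_transcripts(ann, track, min_len, min_reads):
        rows.append(
            {
                "transcript_id": t.id,
                "tr5": traveling_ratio(track, t, "tr5", window),
                "tr3": traveling_ratio(track, t, "tr3", window),
                "sample": track.sample.name,
                "genotype": track.sample.genotype,
                "replicate": track.sample.replicate,
            }
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "tr5", "tr3", "sample", "genotype", "replicate"]
    )


def _feature_matrix(
    records: pd.DataFrame, genotypes: tuple[str, str]
) -> tuple[pd.Index, np.ndarray]:
    """Per-transcript feature vector (log2 tr5/tr3 in each genotype) for
    transcripts measured in both genotypes."""
    pieces = []
    for g in genotypes:
        sub = records[records["genotype"] == g]
        if sub.empty:
            raise ValueError(f"genotype {g!r} missing from records")
        piece = sub.set_index("transcript_id")[["tr5", "tr3"]]
        piece.columns = [f"tr5_{g}", f"tr3_{g}"]
        pieces.append(piece)
    joined = pieces[0].join(pieces[1], how="inner")
    X = np.log2(np.maximum(joined.to_numpy(dtype=float), LOG_FLOOR))
    return joined.index, X


def tr_cluster(
    records: pd.DataFrame,
    genotypes: tuple[str, str],
    k: int = 3,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """K-means clustering of transcripts on their traveling ratios in two
    genotypes (single replicate).

    ``records`` is long format with columns transcript_id / genotype / tr5 /
    tr3.  Returns (assignments, summary): per-transcript cluster labels, and
    per-cluster size plus KS comparisons of the two genotypes for each end.
    """
    index, X = _feature_matrix(records, genotypes)
    fit = kmeans_fit(X, k=k, seed=seed, restarts=restarts)
    assign = pd.DataFrame({"transcript_id": index, "cluster": fit.labels})

    wt, mut = genotypes
    merged = assign.set_index("transcript_id")
    by_geno = {
        g: records[records["genotype"] == g].set_index("transcript_id")
        for g in genotypes
    }
    rows = []
    for c in range(k):
        ids = merged.index[merged["cluster"] == c]
        row: dict[str, float | int] = {"cluster": c, "n": len(ids)}
        for end in ("tr5", "tr3"):
            x = by_geno[wt].loc[ids, end].to_numpy(dtype=float)
            y = by_geno[mut].loc[ids, end].to_numpy(dtype=float)
            if len(ids) >= 2:
                ks = ks_two_sample(x, y)
                row[f"{end}_ks_D"] = ks.statistic
                row[f"{end}_ks_p"] = ks.pvalue
            else:
                row[f"{end}_ks_D"] = np.nan
                row[f"{end}_ks_p"] = np.nan
            row[f"{end}_median_{wt}"] = float(np.median(x)) if len(ids) else np.nan
            row[f"{end}_median_{mut}"] = float(np.median(y)) if len(ids) else np.nan
        rows.append(row)
    return assign, pd.DataFrame(rows)


def tr_compare(
    records: pd.DataFrame,
    clusters: Mapping[str, int] | pd.DataFrame,
    genotypes: tuple[str, str],
) -> pd.DataFrame:
    """Per-cluster, per-end, per-replicate-pair KS comparison of traveling
    ratios between two genotypes.

    ``records`` is long format with columns transcript_id / genotype /
    replicate / tr5 / tr3.  Clusters with fewer than 2 members are skipped.
    """
    if isinstance(clusters, pd.DataFrame):
        clusters = dict(zip(clusters["transcript_id"], clusters["cluster"]))
    df = records.copy()
    df["cluster"] = df["transcript_id"].map(clusters)
    df = df.dropna(subset=["cluster"])
    wt, mut = genotypes
    reps = sorted(
        set(df.loc[df["genotype"] == wt, "replicate"])
        & set(df.loc[df["genotype"] == mut, "replicate"])
    )
    rows = []
    for c in sorted(df["cluster"].unique()):
        for rep in reps:
            for end in ("tr5", "tr3"):
                x = df[
                    (df["cluster"] == c) & (df["genotype"] == wt) & (df["replicate"] == rep)
                ][end].to_numpy(dtype=float)
                y = df[
                    (df["cluster"] == c) & (df["genotype"] == mut) & (df["replicate"] == rep)
                ][end].to_numpy(dtype=float)
                if x.size < 2 or y.size < 2:
                    continue
                ks = ks_two_sample(x, y)
                rows.append(
                    {
                        "cluster": int(c),
                        "replicate": rep,
                        "end": end,
                        "ks_D": ks.statistic,
                        "ks_p": ks.pvalue,
                        "median_" + wt: float(np.median(x)),
                        "median_" + mut: float(np.median(y)),
                    }
                )
    return pd.DataFrame(rows)


def ecdf_table(values: Sequence[float]) -> pd.DataFrame:
    """Empirical CDF as a (value, quantile) table; quantiles end at 1.0."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("ecdf of empty sample")
    q = np.arange(1, v.size + 1) / v.size
    return pd.DataFrame({"value": v, "quantile": q})
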