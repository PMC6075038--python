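"""Readers and writers for BedGraph, BED, GFF3 and sample sheets.

Everything is normalized to 0-based half-open coordinates at the boundary:
BedGraph and BED are native, GFF3 (1-based inclusive) is converted on read.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    UNSTRANDED,
    GenomeAnnotation,
    Interval,
    SampleMeta,
    SignalTrack,
    Transcript,
)


def read_bedgraph(
    path: str | os.PathLike,
    chrom_sizes: Mapping[str, int],
    strand: str = UNSTRANDED,
    sample: SampleMeta | None = None,
) -> SignalTrack:
    """Read a 4-column BedGraph into a dense single-strand track.

    Uncovered positions are 0.  Overlapping records, negative values and
    unknown chromosomes are errors (malformed exports should fail loudly).
    The returned track is stranded when ``strand`` is ``+`` or ``-`` (the
    opposite strand is all-zero), unstranded when ``strand`` is ``"."``.
    """
    track = SignalTrack(chrom_sizes, sample=sample, stranded=strand != UNSTRANDED)
    covered: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            if start < 0 or end > chrom_sizes[chrom] or end <= start:
                raise ValueError(f"{path}:{lineno}: bad interval [{start},{end})")
            covered.setdefault(chrom, []).append((start, end))
            track.values(chrom, strand)[start:end] = value
    for chrom, spans in covered.items():
        spans.sort()
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping BedGraph records on {chrom}: "
                    f"[{s1},{e1}) and starting at {s2}"
                )
    return track


def write_bedgraph(
    track: SignalTrack,
    path: str | os.PathLike,
    strand: str | None = None,
    header: str | None = None,
) -> None:
    """Write one strand of a track as BedGraph (zero runs omitted,
    adjacent equal values merged). Round-trips integer tracks exactly."""
    if strand is None:
        strand = UNSTRANDED if not track.stranded else "+"
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for chrom in sorted(track.chrom_sizes):
            v = track.values(chrom, strand)
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0:
                    continue
                sval = f"{int(val)}" if float(val).is_integer() else repr(float(val))
                fh.write(f"{chrom}\t{s}\t{e}\t{sval}\n")


def read_intervals(
    path: str | os.PathLike,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Interval]:
    """Read a BED3/BED6 file as a list of intervals (strand from column 6)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else UNSTRANDED
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise ValueError(f"{path}:{lineno}: interval beyond chromosome end")
            out.append(Interval(chrom, start, end, strand, name))
    return out


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_annotation(
    path: str | os.PathLike,
    chrom_sizes: Mapping[str, int],
    dialect: str = "gff3",
) -> GenomeAnnotation:
    """Read transcript annotation from GFF3 or BED6(+2).

    GFF3: every non-comment feature line becomes a transcript; the id comes
    from the ``ID`` attribute, class from ``biotype`` (default ``coding``)
    and the essential flag from ``essential`` (default false).  Coordinates
    are converted from 1-based inclusive to 0-based half-open.

    BED6+2: columns 7 and 8, when present, carry the class and essential
    flag.
    """
    transcripts: list[Transcript] = []
    if dialect == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
                chrom, _src, _ftype, start1, end1, _score, strand, _frame, attr = parts[:9]
                attrs = _parse_gff_attributes(attr)
                transcripts.append(
                    Transcript(
                        id=attrs.get("ID", f"feature_{lineno}"),
                        chrom=chrom,
                        strand=strand,
                        start=int(start1) - 1,
                        end=int(end1),
                        cls=attrs.get("biotype", "coding"),
                        essential=attrs.get("essential", "false").lower()
                        in ("true", "1", "yes"),
                    )
                )
    elif dialect == "bed6":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
                transcripts.append(
                    Transcript(
                        id=parts[3],
                        chrom=parts[0],
                        strand=parts[5],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        cls=parts[6] if len(parts) > 6 else "coding",
                        essential=(
                            parts[7].lower() in ("true", "1", "yes")
                            if len(parts) > 7
                            else False
                        ),
                    )
                )
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    # GenomeAnnotation.validate raises on out-of-bounds features
    return GenomeAnnotation(chrom_sizes=dict(chrom_sizes), transcripts=transcripts)


def write_annotation_gff3(ann: GenomeAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in sorted(ann.chrom_sizes.items()):
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for t in ann.transcripts:
            attrs = f"ID={t.id};biotype={t.cls};essential={str(t.essential).lower()}"
            fh.write(
                f"{t.chrom}\ttoy\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )


def write_intervals_bed(ivs: Sequence[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with columns name/genotype/replicate/assay/path (and optionally
    strand for stranded BedGraphs)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "genotype", "replicate", "assay", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def sample_meta_from_row(row: Mapping) -> SampleMeta:
    return SampleMeta(
        name=str(row["name"]),
        genotype=str(row["genotype"]),
        replicate=int(row["replicate"]),
        assay=str(row["assay"]),
    )
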