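"""Genomic domain types and signal-track arithmetic.

All coordinates are 0-based half-open, matching the BED/BedGraph convention.
NET-seq tracks are stranded (one vector per chromosome per strand, holding
the number of read 5'-starts per nucleotide, i.e. RNAPII active-site
positions); ChIP tracks are unstranded (single vector per chromosome under
the strand code ``"."``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

STRAND_PLUS = "+"
STRAND_MINUS = "-"
UNSTRANDED = "."
STRANDED = (STRAND_PLUS, STRAND_MINUS)

TRANSCRIPT_CLASSES = ("coding", "ncRNA", "repeat")


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (STRAND_PLUS, STRAND_MINUS, UNSTRANDED):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "Interval") -> int:
        """Boundary-to-boundary distance in nt; 0 if overlapping or abutting."""
        if self.chrom != other.chrom:
            raise ValueError("distance between intervals on different chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class Transcript:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    cls: str = "coding"
    essential: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"transcript {self.id}: end must exceed start")
        if self.strand not in STRANDED:
            raise ValueError(f"transcript {self.id}: strand must be + or -")
        if self.cls not in TRANSCRIPT_CLASSES:
            raise ValueError(f"transcript {self.id}: unknown class {self.cls!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand, self.id)


@dataclass(frozen=True)
class SampleMeta:
    """Identity of a sequencing sample: genotype, replicate and assay."""

    name: str
    genotype: str = ""
    replicate: int = 1
    assay: str = "netseq"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus transcripts, repeat fragments and curated sites."""

    chrom_sizes: dict[str, int]
    transcripts: list[Transcript] = field(default_factory=list)
    fragments: list[Interval] = field(default_factory=list)
    curated_sites: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for t in self.transcripts:
            size = self._size(t.chrom, f"transcript {t.id}")
            if t.start < 0 or t.end > size:
                raise ValueError(
                    f"transcript {t.id} [{t.start},{t.end}) outside {t.chrom} (len {size})"
                )
        for label, ivs in (("fragment", self.fragments), ("curated site", self.curated_sites)):
            for iv in ivs:
                size = self._size(iv.chrom, f"{label} {iv.name}")
                if iv.start < 0 or iv.end > size:
                    raise ValueError(
                        f"{label} {iv.name} [{iv.start},{iv.end}) outside {iv.chrom}"
                    )

    def _size(self, chrom: str, what: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise ValueError(f"{what}: unknown chromosome {chrom!r}") from None

    def transcripts_of_class(self, cls: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.cls == cls]


class SignalTrack:
    """Dense per-nucleotide, per-strand signal over a genome.

    ``data`` maps ``(chrom, strand)`` to a float vector of chromosome length.
    A stranded track carries strands ``+`` and ``-``; an unstranded track
    (ChIP coverage) carries the single strand code ``"."``.
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        sample: SampleMeta | None = None,
        stranded: bool = True,
    ) -> None:
        self.chrom_sizes = dict(chrom_sizes)
        self.sample = sample or SampleMeta(name="unnamed")
        self.stranded = stranded
        strands = STRANDED if stranded else (UNSTRANDED,)
        self.data: dict[tuple[str, str], np.ndarray] = {
            (chrom, s): np.zeros(size, dtype=float)
            for chrom, size in self.chrom_sizes.items()
            for s in strands
        }

    @property
    def strands(self) -> tuple[str, ...]:
        return STRANDED if self.stranded else (UNSTRANDED,)

    def values(self, chrom: str, strand: str = UNSTRANDED) -> np.ndarray:
        if not self.stranded:
            strand = UNSTRANDED
        try:
            return self.data[(chrom, strand)]
        except KeyError:
            raise KeyError(f"no vector for chromosome {chrom!r} strand {strand!r}") from None

    @property
    def total_reads(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self) -> "SignalTrack":
        out = SignalTrack(self.chrom_sizes, self.sample, self.stranded)
        for key, v in self.data.items():
            out.data[key] = v.copy()
        return out

    def region_values(self, iv: Interval) -> np.ndarray:
        """Signal inside ``iv`` on its own strand (all strands summed if ``.``)."""
        self._check_bounds(iv)
        if not self.stranded:
            return self.values(iv.chrom)[iv.start : iv.end]
        if iv.strand == UNSTRANDED:
            return sum(
                self.values(iv.chrom, s)[iv.start : iv.end] for s in STRANDED
            )
        return self.values(iv.chrom, iv.strand)[iv.start : iv.end]

    def region_sum(self, iv: Interval) -> float:
        return float(self.region_values(iv).sum())

    def _check_bounds(self, iv: Interval) -> None:
        size = self.chrom_sizes.get(iv.chrom)
        if size is None:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.start < 0 or iv.end > size:
            raise ValueError(f"interval [{iv.start},{iv.end}) outside {iv.chrom}")

    def iter_chromosomes(self) -> Iterator[tuple[str, str, np.ndarray]]:
        for (chrom, strand), v in sorted(self.data.items()):
            yield chrom, strand, v


def _centered_mean(v: np.ndarray, window: int) -> np.ndarray:
    # centered window, truncated and renormalized at the ends; for even
    # windows the extra position goes downstream
    lo = (window - 1) // 2
    hi = window // 2
    n = v.size
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    a = np.maximum(idx - lo, 0)
    b = np.minimum(idx + hi + 1, n)
    return (csum[b] - csum[a]) / (b - a)


def smooth_track(track: SignalTrack, window: int = 1000) -> SignalTrack:
    """Centered moving average of width ``window`` nt, per chromosome/strand.

    The window is truncated (and renormalized) at chromosome ends, so a
    uniform track stays uniform all the way to the telomeres.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out = track.copy()
    if window == 1:
        return out
    for key, v in track.data.items():
        out.data[key] = _centered_mean(v, window)
    return out


def rpm_normalize(track: SignalTrack) -> SignalTrack:
    """Scale to reads per million mapped reads (new total is 1e6)."""
    total = track.total_reads
    if total <= 0:
        raise ValueError("cannot RPM-normalize a track with zero total reads")
    out = track.copy()
    scale = 1e6 / total
    for key in out.data:
        out.data[key] = out.data[key] * scale
    return out


def region_rpkm(track: SignalTrack, iv: Interval) -> float:
    """Reads per kilobase per million mapped reads over ``iv``."""
    total = track.total_reads
    if total <= 0:
        raise ValueError("RPKM undefined for a track with zero total reads")
    reads = track.region_sum(iv)
    return (reads / (iv.length / 1000.0)) / (total / 1e6)


def merge_intervals(ivs: Iterable[Interval], gap: int = 0) -> list[Interval]:
    """Union of intervals per chromosome, merging gaps smaller than ``gap``."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        pending = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = pending[0].start, pending[0].end
        for iv in pending[1:]:
            if iv.start - cur_end < gap or iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(chrom, cur_start, cur_end))
    return out
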