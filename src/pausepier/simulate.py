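"""Synthetic data with planted truth for every analysis stage.

The generator emulates the statistical structure of the assays analysed by
the pipeline on a toy genome: stranded per-nucleotide NET-seq read-start
tracks with Poisson background inside transcripts and planted pause sites
whose height is genotype-dependent; 5'-enriched pause classes whose reads
relocate into the gene body in the mutant (conserving transcript totals);
ChIP IP/WCE track pairs with broad enriched domains, including ectopic
domains absent from a parental strain; and PAR-CLIP cluster placements
hitting per-class coverage targets.  Everything is deterministic given
(seed, role, replicate), and the planted truth is serializable so each
analysis stage can be scored for recovery.

Counts follow a Poisson model throughout; replicate variation is
resampling noise over shared truth, matching a duplicate experimental
design.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    GenomeAnnotation,
    Interval,
    SampleMeta,
    SignalTrack,
    Transcript,
)
from .parclip import ParclipCluster

GENOTYPES = ("wt", "mut")  # baseline vs pausing-factor mutant
CHIP_ROLES = ("isolate", "parental", "wce")

# stream codes keep the per-assay random streams independent
_STREAM = {"genome": 1, "truth": 2, "netseq": 3, "chip": 4, "parclip": 5}
_GENO_CODE = {"wt": 1, "mut": 2}
_ROLE_CODE = {"isolate": 1, "parental": 2, "wce": 3}


@dataclass(frozen=True)
class PauseSite:
    chrom: str
    pos: int
    strand: str
    wt_reads: float  # expected read starts at the site in the baseline
    mut_fold_decrease: float  # 1 = no genotype effect; inf = fully lost
    dwell_fold: float = 1.0  # height multiplier distinguishing long-lived pauses

    @property
    def dependent(self) -> bool:
        """Ground truth for the twofold-decrease dependence rule."""
        return self.mut_fold_decrease >= 2.0


@dataclass(frozen=True)
class ChipDomain:
    iv: Interval
    enrichment_fold: float
    in_parental: bool


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chrI": 300_000})
    n_genes: int = 40
    n_ncrna: int = 6
    gene_length_range: tuple[int, int] = (1500, 2500)
    ncrna_length_range: tuple[int, int] = (500, 900)
    min_gene_gap: int = 2000
    essential_fraction: float = 0.15
    repeat_region: Interval | None = field(
        default_factory=lambda: Interval("chrI", 250_000, 270_000, name="cenR")
    )
    n_fragments: int = 9
    n_curated_sites: int = 4
    curated_site_length: int = 3000
    # NET-seq
    netseq_background_rate: float = 0.2  # reads/nt inside transcripts
    noise_rate: float = 0.002  # reads/nt everywhere (mapping noise)
    n_pauses: int = 40
    pause_wt_reads: float = 30.0
    pause_mut_fold: float = 4.0
    pause_dependent_fraction: float = 0.5
    pause_dwell_fold: float = 5.0  # extra height of dependent (long-lived) pauses
    pause_min_spacing: int = 150
    tr_class_props: tuple[float, ...] = (0.224, 0.546, 0.230)
    tr_boosts: tuple[float, ...] = (6.0, 2.0, 0.0)  # 5' pause strength per class
    tr_window: int = 500
    replicates: int = 2
    # ChIP
    chip_depth: int = 1_000_000
    chip_domains: tuple[ChipDomain, ...] = ()
    # PAR-CLIP
    parclip_class_coverage: dict[str, float] = field(
        default_factory=lambda: {"repeat": 0.60, "coding": 0.05, "ncRNA": 0.90}
    )
    parclip_cluster_len: int = 30
    parclip_decoy_fraction: float = 0.0

    def __post_init__(self) -> None:
        if any(f < 0 for f in (self.netseq_background_rate, self.noise_rate)):
            raise ValueError("rates must be non-negative")
        if self.pause_mut_fold < 1:
            raise ValueError("pause_mut_fold must be >= 1")
        for cls, frac in self.parclip_class_coverage.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"coverage target for {cls!r} outside [0,1]")
        if not math.isclose(sum(self.tr_class_props), 1.0, abs_tol=1e-6):
            raise ValueError("tr_class_props must sum to 1")


@dataclass
class SimTruth:
    pauses: list[PauseSite] = field(default_factory=list)
    domains: list[ChipDomain] = field(default_factory=list)
    gene_classes: dict[str, int] = field(default_factory=dict)
    parclip_targets: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "pauses": [dataclasses.asdict(p) for p in self.pauses],
                "domains": [
                    {
                        "chrom": d.iv.chrom,
                        "start": d.iv.start,
                        "end": d.iv.end,
                        "enrichment_fold": d.enrichment_fold,
                        "in_parental": d.in_parental,
                    }
                    for d in self.domains
                ],
                "gene_classes": self.gene_classes,
                "parclip_targets": self.parclip_targets,
            },
            indent=2,
            default=lambda x: "inf" if x == math.inf else x,
        )


def _rng(cfg: SimulationConfig, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _STREAM[stream], *extra])
    )


def make_toy_genome(cfg: SimulationConfig) -> GenomeAnnotation:
    """Build the toy annotation: non-overlapping genes and ncRNAs with
    >= 2-kb gaps, a repeat region with sense and antisense transcription
    units plus overlapping named fragments, and curated (decoy) sites."""
    rng = _rng(cfg, "genome")
    chroms = sorted(cfg.chrom_sizes)
    rep = cfg.repeat_region
    if rep is not None:
        if rep.chrom not in cfg.chrom_sizes or rep.end > cfg.chrom_sizes[rep.chrom]:
            raise ValueError("repeat_region outside the genome")

    transcripts: list[Transcript] = []
    placements = [("gene", i, cfg.gene_length_range) for i in range(cfg.n_genes)] + [
        ("ncrna", i, cfg.ncrna_length_range) for i in range(cfg.n_ncrna)
    ]
    chrom_iter = iter(chroms)
    chrom = next(chrom_iter)
    cursor = 1000
    for kind, i, (lo, hi) in placements:
        length = int(rng.integers(lo, hi + 1))
        placed = False
        while not placed:
            # keep clear of the repeat region (with the standard gap)
            if (
                rep is not None
                and chrom == rep.chrom
                and cursor + length > rep.start - cfg.min_gene_gap
                and cursor < rep.end + cfg.min_gene_gap
            ):
                cursor = rep.end + cfg.min_gene_gap
                continue
            if cursor + length > cfg.chrom_sizes[chrom] - 1000:
                try:
                    chrom = next(chrom_iter)
                    cursor = 1000
                    continue
                except StopIteration:
                    raise ValueError(
                        "genome too small for the requested transcripts"
                    ) from None
            placed = True
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "gene":
            transcripts.append(
                Transcript(
                    id=f"gene{i + 1:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=cursor,
                    end=cursor + length,
                    cls="coding",
                    essential=bool(rng.random() < cfg.essential_fraction),
                )
            )
        else:
            transcripts.append(
                Transcript(
                    id=f"ncrna{i + 1:03d}",
                    chrom=chrom,
                    strand=strand,
                    start=cursor,
                    end=cursor + length,
                    cls="ncRNA",
                )
            )
        cursor += length + cfg.min_gene_gap + int(rng.integers(0, 500))

    fragments: list[Interval] = []
    if rep is not None:
        transcripts.append(
            Transcript("repeat_sense", rep.chrom, "+", rep.start, rep.end, cls="repeat")
        )
        transcripts.append(
            Transcript("repeat_antisense", rep.chrom, "-", rep.start, rep.end, cls="repeat")
        )
        # overlapping fragments tiling the repeat region
        n = cfg.n_fragments
        frag_len = max(rep.length // (n // 2 + 1), 1)
        if n > 1:
            stride = (rep.length - frag_len) / (n - 1)
        else:
            stride = 0
        for j in range(n):
            s = rep.start + int(round(j * stride))
            fragments.append(
                Interval(rep.chrom, s, min(s + frag_len, rep.end), name=f"Frag{j + 1}")
            )

    curated: list[Interval] = []
    if cfg.n_curated_sites > 0:
        chrom0 = chroms[0]
        size = cfg.chrom_sizes[chrom0]
        span_end = rep.start - 20_000 if (rep is not None and rep.chrom == chrom0) else size
        span_end = max(span_end, cfg.curated_site_length * cfg.n_curated_sites + 1)
        anchors = np.linspace(
            0.05 * span_end, 0.95 * span_end - cfg.curated_site_length, cfg.n_curated_sites
        )
        for j, a in enumerate(anchors):
            s = int(a)
            curated.append(
                Interval(chrom0, s, s + cfg.curated_site_length, name=f"curated{j + 1}")
            )

    return GenomeAnnotation(
        chrom_sizes=dict(cfg.chrom_sizes),
        transcripts=transcripts,
        fragments=fragments,
        curated_sites=curated,
    )


def plant_truth(ann: GenomeAnnotation, cfg: SimulationConfig) -> SimTruth:
    """Draw the shared ground truth: pause sites inside the repeat region,
    traveling-ratio gene classes, ChIP domains and PAR-CLIP targets."""
    rng = _rng(cfg, "truth")
    truth = SimTruth(parclip_targets=dict(cfg.parclip_class_coverage))
    truth.domains = list(cfg.chip_domains)

    rep = cfg.repeat_region
    if rep is not None and cfg.n_pauses > 0:
        per_strand = cfg.n_pauses // 2 + cfg.n_pauses % 2
        usable = rep.length - 200
        if per_strand * cfg.pause_min_spacing > usable:
            raise ValueError("repeat region too small for the requested pauses")
        placed = 0
        # exact class counts (randomly assigned to sites), so downstream
        # comparisons run at the intended per-class sample size
        n_dep = int(round(cfg.pause_dependent_fraction * cfg.n_pauses))
        dep_flags = np.zeros(cfg.n_pauses, dtype=bool)
        dep_flags[rng.choice(cfg.n_pauses, size=n_dep, replace=False)] = True
        for strand in ("+", "-"):
            n_here = min(per_strand, cfg.n_pauses - placed)
            offsets = np.sort(
                rng.choice(usable // cfg.pause_min_spacing, size=n_here, replace=False)
            )
            for j, off in enumerate(offsets):
                pos = rep.start + 100 + int(off) * cfg.pause_min_spacing
                dependent = bool(dep_flags[placed])
                truth.pauses.append(
                    PauseSite(
                        chrom=rep.chrom,
                        pos=pos,
                        strand=strand,
                        wt_reads=cfg.pause_wt_reads
                        * (cfg.pause_dwell_fold if dependent else 1.0),
                        mut_fold_decrease=cfg.pause_mut_fold if dependent else 1.0,
                        dwell_fold=cfg.pause_dwell_fold if dependent else 1.0,
                    )
                )
                placed += 1

    coding = [t for t in ann.transcripts if t.cls == "coding"]
    classes = rng.choice(
        len(cfg.tr_class_props), size=len(coding), p=np.asarray(cfg.tr_class_props)
    )
    truth.gene_classes = {t.id: int(c) for t, c in zip(coding, classes)}
    return truth


def simulate_netseq(
    ann: GenomeAnnotation,
    cfg: SimulationConfig,
    truth: SimTruth,
    genotype: str,
    replicate: int = 1,
) -> SignalTrack:
    """One stranded NET-seq read-start track for (genotype, replicate).

    Inside every transcript the background is Poisson(netseq_background_rate)
    per nt on the transcript's strand; a low mapping-noise rate applies
    genome-wide.  Planted pauses add Poisson(wt_reads) in the baseline and
    Poisson(wt_reads / mut_fold_decrease) in the mutant.  Genes in a boosted
    traveling-ratio class carry extra 5'-window signal in the baseline that
    relocates uniformly over the gene body in the mutant, conserving the
    expected transcript total.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    rng = _rng(cfg, "netseq", _GENO_CODE[genotype], replicate)
    track = SignalTrack(
        ann.chrom_sizes,
        sample=SampleMeta(
            name=f"netseq_{genotype}_r{replicate}",
            genotype=genotype,
            replicate=replicate,
            assay="netseq",
        ),
        stranded=True,
    )
    for key, v in track.data.items():
        if cfg.noise_rate > 0:
            v += rng.poisson(cfg.noise_rate, size=v.size)

    bg = cfg.netseq_background_rate
    for t in ann.transcripts:
        v = track.values(t.chrom, t.strand)
        if bg > 0:
            v[t.start : t.end] += rng.poisson(bg, size=t.length)
        cls = truth.gene_classes.get(t.id)
        boost = cfg.tr_boosts[cls] if cls is not None else 0.0
        if boost > 0:
            w = min(cfg.tr_window, t.length)
            if genotype == "wt":
                if t.strand == "+":
                    lo, hi = t.start, t.start + w
                else:
                    lo, hi = t.end - w, t.end
                v[lo:hi] += rng.poisson(bg * boost, size=hi - lo)
            else:
                rate = bg * boost * w / t.length
                v[t.start : t.end] += rng.poisson(rate, size=t.length)

    for p in truth.pauses:
        mean = p.wt_reads
        if genotype == "mut":
            mean = 0.0 if math.isinf(p.mut_fold_decrease) else p.wt_reads / p.mut_fold_decrease
        if mean > 0:
            track.values(p.chrom, p.strand)[p.pos] += rng.poisson(mean)
    return track


def simulate_chipseq(
    ann: GenomeAnnotation,
    cfg: SimulationConfig,
    truth: SimTruth,
    role: str,
    replicate: int = 1,
) -> SignalTrack:
    """One unstranded ChIP coverage track.

    The whole-cell extract (``wce``) is flat Poisson noise at a rate giving
    roughly ``chip_depth`` total reads.  IP tracks multiply the rate by
    each domain's enrichment fold — the isolate sees every planted domain,
    the parental strain only those with ``in_parental=True``.
    """
    if role not in CHIP_ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {CHIP_ROLES}")
    rng = _rng(cfg, "chip", _ROLE_CODE[role], replicate)
    genome_len = sum(ann.chrom_sizes.values())
    base = cfg.chip_depth / genome_len
    track = SignalTrack(
        ann.chrom_sizes,
        sample=SampleMeta(
            name=f"chip_{role}_r{replicate}",
            genotype=role,
            replicate=replicate,
            assay="chip_wce" if role == "wce" else "chip_ip",
        ),
        stranded=False,
    )
    for chrom in ann.chrom_sizes:
        rate = np.full(ann.chrom_sizes[chrom], base)
        if role != "wce":
            for d in truth.domains:
                if d.iv.chrom != chrom:
                    continue
                if role == "parental" and not d.in_parental:
                    continue
                rate[d.iv.start : d.iv.end] *= d.enrichment_fold
        track.values(chrom)[:] = rng.poisson(rate)
    return track


def simulate_parclip(
    ann: GenomeAnnotation,
    cfg: SimulationConfig,
    truth: SimTruth | None = None,
) -> list[ParclipCluster]:
    """Candidate binding-site clusters hitting per-class coverage targets.

    For each transcript, clusters are tiled until the class's target
    coverage fraction of the interval is covered (within 1 nt of rounding).
    True clusters draw read/conversion counts above the filter thresholds;
    a configurable fraction of sub-threshold decoys is added on top.
    """
    rng = _rng(cfg, "parclip")
    targets = (truth.parclip_targets if truth is not None else None) or dict(
        cfg.parclip_class_coverage
    )
    clusters: list[ParclipCluster] = []
    for t in ann.transcripts:
        target = targets.get(t.cls, 0.0)
        if target <= 0:
            continue
        n_cov = int(round(target * t.length))
        if n_cov == 0:
            continue
        k = max(1, math.ceil(n_cov / cfg.parclip_cluster_len))
        slot = t.length / k
        remaining = n_cov
        for j in range(k):
            length = min(cfg.parclip_cluster_len, remaining)
            if length <= 0:
                break
            s = t.start + int(j * slot)
            e = min(s + length, t.end)
            if e <= s:
                continue
            clusters.append(
                ParclipCluster(
                    iv=Interval(t.chrom, s, e, t.strand),
                    read_count=10 + int(rng.poisson(20)),
                    conversion_count=2 + int(rng.poisson(3)),
                )
            )
            remaining -= e - s
    if cfg.parclip_decoy_fraction > 0:
        n_true = len(clusters)
        n_decoy = int(round(
            n_true * cfg.parclip_decoy_fraction / (1 - cfg.parclip_decoy_fraction)
        ))
        eligible = [t for t in ann.transcripts if targets.get(t.cls, 0) > 0]
        for _ in range(n_decoy):
            t = eligible[int(rng.integers(len(eligible)))]
            s = t.start + int(rng.integers(max(t.length - cfg.parclip_cluster_len, 1)))
            e = min(s + cfg.parclip_cluster_len, t.end)
            # sub-threshold: too few reads or too few conversions
            if rng.random() < 0.5:
                reads, conv = int(rng.integers(1, 10)), 2 + int(rng.poisson(2))
            else:
                reads, conv = 10 + int(rng.poisson(10)), int(rng.integers(0, 2))
            clusters.append(
                ParclipCluster(
                    iv=Interval(t.chrom, s, e, t.strand),
                    read_count=reads,
                    conversion_count=conv,
                )
            )
    return clusters


def place_ectopic_domain(
    ann: GenomeAnnotation,
    rng: np.random.Generator,
    size: int,
    fold: float,
    in_parental: bool = False,
    clearance: int = 12_000,
    max_tries: int = 1000,
) -> ChipDomain:
    """Place a domain at least ``clearance`` nt from every curated site and
    from the repeat region (so it is scored as genuinely ectopic)."""
    chroms = sorted(ann.chrom_sizes)
    avoid = list(ann.curated_sites)
    for _ in range(max_tries):
        chrom = chroms[int(rng.integers(len(chroms)))]
        limit = ann.chrom_sizes[chrom] - size - 1000
        if limit <= 1000:
            continue
        s = 1000 + int(rng.integers(limit - 1000))
        iv = Interval(chrom, s, s + size)
        ok = all(
            iv.chrom != a.chrom or iv.distance(a) >= clearance for a in avoid
        )
        if ok:
            return ChipDomain(iv=iv, enrichment_fold=fold, in_parental=in_parental)
    raise ValueError("could not place an ectopic domain with the required clearance")


def write_simulation(
    outdir: str | os.PathLike, cfg: SimulationConfig
) -> dict[str, str]:
    """Run the generator end to end and write BedGraphs, GFF3, BED files,
    a sample sheet and the truth JSON.  Returns the path map."""
    from . import io as pio

    os.makedirs(outdir, exist_ok=True)
    ann = make_toy_genome(cfg)
    truth = plant_truth(ann, cfg)
    paths: dict[str, str] = {}
    sheet_rows = []

    def save(track: SignalTrack, stem: str) -> None:
        strands = ("+", "-") if track.stranded else (".",)
        for strand in strands:
            suffix = {"+": "plus", "-": "minus", ".": "cov"}[strand]
            p = os.path.join(outdir, f"{stem}_{suffix}.bedgraph")
            pio.write_bedgraph(track, p, strand=strand, header=f"seed={cfg.seed}")
            paths[f"{stem}_{suffix}"] = p
            sheet_rows.append(
                {
                    "name": track.sample.name,
                    "genotype": track.sample.genotype,
                    "replicate": track.sample.replicate,
                    "assay": track.sample.assay,
                    "strand": strand,
                    "path": p,
                }
            )

    for genotype in GENOTYPES:
        for rep in range(1, cfg.replicates + 1):
            save(simulate_netseq(ann, cfg, truth, genotype, rep), f"netseq_{genotype}_r{rep}")
    for role in CHIP_ROLES:
        save(simulate_chipseq(ann, cfg, truth, role, 1), f"chip_{role}")

    ann_path = os.path.join(outdir, "annotation.gff3")
    pio.write_annotation_gff3(ann, ann_path)
    paths["annotation"] = ann_path
    frag_path = os.path.join(outdir, "fragments.bed")
    pio.write_intervals_bed(ann.fragments, frag_path)
    paths["fragments"] = frag_path
    cur_path = os.path.join(outdir, "curated_sites.bed")
    pio.write_intervals_bed(ann.curated_sites, cur_path)
    paths["curated_sites"] = cur_path

    clusters = simulate_parclip(ann, cfg, truth)
    pc_path = os.path.join(outdir, "parclip_clusters.bed")
    with open(pc_path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.iv.chrom}\t{c.iv.start}\t{c.iv.end}\tcluster\t0\t{c.iv.strand}"
                f"\t{c.read_count}\t{c.conversion_count}\n"
            )
    paths["parclip_clusters"] = pc_path

    import pandas as pd

    sheet_path = os.path.join(outdir, "samples.tsv")
    pd.DataFrame(sheet_rows).to_csv(sheet_path, sep="\t", index=False)
    paths["sample_sheet"] = sheet_path

    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        fh.write(truth.to_json())
    paths["truth"] = truth_path
    return paths
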