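"""End-to-end study runs on synthetic data with planted truth.

Each ``run_*`` function builds a scenario configuration, simulates the
inputs, runs the corresponding analysis stage and scores recovery of the
planted truth.  The scenarios fix the problem sizes the package uses for
its self-validation: a large repeat region with 400 planted pauses for the
pause/dwell analyses, ~310 genes for the traveling-ratio analysis, and
300-kb genomes for the ChIP domain analyses.
"""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .chipseq import discover_piers, pier_list, prepare_chip_track
from .core import Interval
from .netseq import (
    DwellRecord,
    call_peaks,
    classify_seb1_dependent,
    dwell_compare,
    dwell_time,
    find_clusters,
    fragment_cluster_ratio,
)
from .parclip import class_coverage_summary, filter_clusters
from .simulate import (
    SimulationConfig,
    make_toy_genome,
    place_ectopic_domain,
    plant_truth,
    simulate_chipseq,
    simulate_netseq,
    simulate_parclip,
)
from .stats import ks_two_sample
from .travel import tr_cluster, traveling_ratio_table


def pause_scenario_config(seed: int, n_pauses: int = 400) -> SimulationConfig:
    """Pause-calling scenario: a 190-kb repeat region carrying ``n_pauses``
    planted pauses (half genotype-dependent), few flanking genes."""
    return SimulationConfig(
        seed=seed,
        chrom_sizes={"chrI": 260_000},
        n_genes=8,
        n_ncrna=2,
        repeat_region=Interval("chrI", 60_000, 250_000, name="cenR"),
        n_pauses=n_pauses,
        n_curated_sites=0,
    )


def tr_scenario_config(seed: int, n_genes: int = 310) -> SimulationConfig:
    """Traveling-ratio scenario: ~310 isolated genes in three planted
    pausing-response classes, no repeat region."""
    return SimulationConfig(
        seed=seed,
        chrom_sizes={"chrI": 1_500_000},
        n_genes=n_genes,
        n_ncrna=0,
        repeat_region=None,
        n_pauses=0,
        n_curated_sites=0,
    )


def chip_scenario_config(seed: int, domains=()) -> SimulationConfig:
    """ChIP scenario: a featureless 300-kb genome with curated (decoy)
    sites and optional planted enrichment domains."""
    return SimulationConfig(
        seed=seed,
        chrom_sizes={"chrI": 300_000},
        n_genes=0,
        n_ncrna=0,
        repeat_region=None,
        n_pauses=0,
        n_curated_sites=4,
        chip_domains=tuple(domains),
    )


def run_pause_recovery(seed: int = 0) -> dict[str, Any]:
    """Peak calling, dependence classification, dwell times and fragment
    ratios on the pause scenario, scored against the planted truth."""
    cfg = pause_scenario_config(seed)
    ann = make_toy_genome(cfg)
    truth = plant_truth(ann, cfg)
    rep_region = cfg.repeat_region
    assert rep_region is not None

    tracks = {
        (g, r): simulate_netseq(ann, cfg, truth, g, r)
        for g in ("wt", "mut")
        for r in (1, 2)
    }
    regions = {
        s: Interval(rep_region.chrom, rep_region.start, rep_region.end, s)
        for s in ("+", "-")
    }

    def peaks_of(genotype: str, rep: int):
        out = []
        for s in ("+", "-"):
            out.extend(call_peaks(tracks[(genotype, rep)], regions[s]))
        return out

    wt1, wt2 = peaks_of("wt", 1), peaks_of("wt", 2)
    planted = {(p.chrom, p.strand, p.pos): p for p in truth.pauses}
    called1 = {p.key for p in wt1}
    recall = sum(k in called1 for k in planted) / len(planted)
    false_calls = sum(k not in planted for k in called1)
    region_kb = 2 * rep_region.length / 1000.0  # both strands
    false_per_10kb = false_calls / (region_kb / 10.0)

    labeled = classify_seb1_dependent(
        [wt1, wt2],
        tracks_wt=[tracks[("wt", 1)], tracks[("wt", 2)]],
        tracks_mut=[tracks[("mut", 1)], tracks[("mut", 2)]],
    )
    dep_truth = {k for k, p in planted.items() if p.dependent}
    indep_truth = {k for k, p in planted.items() if not p.dependent}
    called_dep = {p.key for p, flag in labeled if flag}
    evaluated = {p.key for p, _flag in labeled}
    classify_recall = len(dep_truth & called_dep) / len(dep_truth)
    indep_evaluated = indep_truth & evaluated
    classify_false = (
        len(indep_evaluated & called_dep) / len(indep_evaluated)
        if indep_evaluated
        else 0.0
    )

    track_wt1 = tracks[("wt", 1)]
    dep_records = [
        DwellRecord(peak=p, dwell=dwell_time(track_wt1, p), seb1_dependent=True)
        for p, flag in labeled
        if flag and p.key in planted
    ]
    ind_records = [
        DwellRecord(peak=p, dwell=dwell_time(track_wt1, p), seb1_dependent=False)
        for p, flag in labeled
        if not flag and p.key in planted
    ]
    dwell = dwell_compare(dep_records, ind_records)

    clusters_by_sample = {}
    for (g, r), track in tracks.items():
        cl = []
        for s in ("+", "-"):
            pk = call_peaks(track, regions[s])
            cl.extend(find_clusters(pk, track, regions[s]))
        clusters_by_sample[track.sample] = cl
    ratios = fragment_cluster_ratio(
        clusters_by_sample, ann.fragments, numerator_genotype="wt",
        denominator_genotype="mut",
    )

    return {
        "peak_recall": recall,
        "false_peaks_per_10kb": false_per_10kb,
        "classify_recall": classify_recall,
        "classify_false_rate": classify_false,
        "n_dependent_evaluated": len(dep_records),
        "n_independent_evaluated": len(ind_records),
        "dwell_median_dependent": dwell.median_dependent,
        "dwell_median_independent": dwell.median_independent,
        "dwell_ks_p": dwell.ks_pvalue,
        "fragment_ratios": ratios,
    }


def run_tr_recovery(seed: int = 0) -> dict[str, Any]:
    """Traveling ratios and K-means class recovery on the TR scenario."""
    cfg = tr_scenario_config(seed)
    ann = make_toy_genome(cfg)
    truth = plant_truth(ann, cfg)
    tables = []
    for genotype in ("wt", "mut"):
        track = simulate_netseq(ann, cfg, truth, genotype, replicate=1)
        tables.append(traveling_ratio_table(ann, track))
    records = pd.concat(tables, ignore_index=True)
    assign, summary = tr_cluster(records, ("wt", "mut"), k=3, seed=seed)
    truth_labels = [truth.gene_classes[tid] for tid in assign["transcript_id"]]
    ari = float(adjusted_rand_score(truth_labels, assign["cluster"]))

    wt = records[records["genotype"] == "wt"]
    mut = records[records["genotype"] == "mut"]
    ks5 = ks_two_sample(wt["tr5"], mut["tr5"])
    ks3 = ks_two_sample(wt["tr3"], mut["tr3"])
    return {
        "n_transcripts": int(len(wt)),
        "ari": ari,
        "median_tr5_wt": float(wt["tr5"].median()),
        "median_tr5_mut": float(mut["tr5"].median()),
        "median_tr3_wt": float(wt["tr3"].median()),
        "median_tr3_mut": float(mut["tr3"].median()),
        "tr5_ks_p": ks5.pvalue,
        "tr3_ks_p": ks3.pvalue,
        "cluster_summary": summary,
        "assignments": assign,
    }


def _pier_tracks(cfg: SimulationConfig):
    ann = make_toy_genome(cfg)
    truth = plant_truth(ann, cfg)
    ip = prepare_chip_track(simulate_chipseq(ann, cfg, truth, "isolate"))
    wce = prepare_chip_track(simulate_chipseq(ann, cfg, truth, "wce"))
    parental = prepare_chip_track(simulate_chipseq(ann, cfg, truth, "parental"))
    return ann, truth, ip, wce, parental


def run_pier_specificity(seed: int = 0, n_genomes: int = 20) -> dict[str, Any]:
    """Null simulations (no planted domains): counts spurious PIER calls."""
    total = 0
    for i in range(n_genomes):
        cfg = chip_scenario_config(seed * 1000 + i)
        ann, truth, ip, wce, parental = _pier_tracks(cfg)
        total += len(pier_list(discover_piers(ip, wce, parental, ann.curated_sites)))
    return {"n_genomes": n_genomes, "total_piers": total}


def run_pier_recall(seed: int = 0, n_genomes: int = 20) -> dict[str, Any]:
    """One spiked ectopic domain (3-15 kb, 4-6x) per genome; scores recall
    and the worst boundary error of the recovered calls."""
    recovered = 0
    max_boundary_error = 0
    for i in range(n_genomes):
        base = chip_scenario_config(seed * 1000 + i)
        rng = np.random.default_rng(np.random.SeedSequence([base.seed, 99]))
        ann0 = make_toy_genome(base)
        size = int(rng.integers(3000, 15001))
        fold = float(rng.uniform(4.0, 6.0))
        domain = place_ectopic_domain(ann0, rng, size=size, fold=fold)
        cfg = chip_scenario_config(base.seed, domains=[domain])
        ann, truth, ip, wce, parental = _pier_tracks(cfg)
        piers = pier_list(discover_piers(ip, wce, parental, ann.curated_sites))
        hit = [p for p in piers if p.iv.overlaps(domain.iv)]
        if len(hit) == 1 and len(piers) == 1:
            recovered += 1
            err = max(
                abs(hit[0].iv.start - domain.iv.start),
                abs(hit[0].iv.end - domain.iv.end),
            )
            max_boundary_error = max(max_boundary_error, err)
    return {
        "n_genomes": n_genomes,
        "recall": recovered / n_genomes,
        "max_boundary_error": max_boundary_error,
    }


def run_pier_exclusions(seed: int = 0) -> dict[str, Any]:
    """The two exclusion rules: a domain 8 kb from a curated site and a
    domain equally present in the parental strain each yield 0 PIERs."""
    base = chip_scenario_config(seed)
    ann0 = make_toy_genome(base)
    site = ann0.curated_sites[0]
    near_iv = Interval(site.chrom, site.end + 8000, site.end + 8000 + 5000)
    from .simulate import ChipDomain

    near_cfg = chip_scenario_config(seed, domains=[ChipDomain(near_iv, 4.0, False)])
    ann, truth, ip, wce, parental = _pier_tracks(near_cfg)
    near_calls = discover_piers(ip, wce, parental, ann.curated_sites)
    near_piers = pier_list(near_calls)
    near_reasons = {c.exclusion_reason for c in near_calls if c.iv.overlaps(near_iv)}

    rng = np.random.default_rng(np.random.SeedSequence([seed, 98]))
    shared = place_ectopic_domain(ann0, rng, size=6000, fold=4.0, in_parental=True)
    par_cfg = chip_scenario_config(seed, domains=[shared])
    ann, truth, ip, wce, parental = _pier_tracks(par_cfg)
    par_calls = discover_piers(ip, wce, parental, ann.curated_sites)
    par_piers = pier_list(par_calls)
    par_reasons = {c.exclusion_reason for c in par_calls if c.iv.overlaps(shared.iv)}

    return {
        "near_curated_piers": len(near_piers),
        "near_curated_reasons": sorted(near_reasons),
        "parental_piers": len(par_piers),
        "parental_reasons": sorted(par_reasons),
    }


def run_parclip_recovery(seed: int = 0) -> dict[str, Any]:
    """Class coverage fractions on the default toy genome (repeat coverage
    target 12x the coding target)."""
    cfg = SimulationConfig(seed=seed)
    ann = make_toy_genome(cfg)
    truth = plant_truth(ann, cfg)
    clusters = filter_clusters(simulate_parclip(ann, cfg, truth))
    summary, per, ks = class_coverage_summary(clusters, ann)
    by_cls = summary.set_index("cls")["mean_fraction"]
    fold = float(by_cls["repeat"] / by_cls["coding"])
    return {
        "mean_fraction_repeat": float(by_cls["repeat"]),
        "mean_fraction_coding": float(by_cls["coding"]),
        "mean_fraction_ncRNA": float(by_cls.get("ncRNA", np.nan)),
        "repeat_vs_coding_fold": fold,
        "target_fold": cfg.parclip_class_coverage["repeat"]
        / cfg.parclip_class_coverage["coding"],
        "summary": summary,
    }


def run_demo(seed: int = 0, outdir: str = "demo_out") -> dict[str, Any]:
    """Run every recovery scenario (ChIP scenarios at reduced replication)
    and write a truth-vs-called report."""
    os.makedirs(outdir, exist_ok=True)
    pause = run_pause_recovery(seed)
    tr = run_tr_recovery(seed)
    piers_null = run_pier_specificity(seed, n_genomes=3)
    piers_spiked = run_pier_recall(seed, n_genomes=3)
    parclip = run_parclip_recovery(seed)

    pause["fragment_ratios"].to_csv(
        os.path.join(outdir, "fragment_ratios.tsv"), sep="\t", index=False
    )
    tr["cluster_summary"].to_csv(
        os.path.join(outdir, "tr_cluster_summary.tsv"), sep="\t", index=False
    )
    tr["assignments"].to_csv(
        os.path.join(outdir, "tr_assignments.tsv"), sep="\t", index=False
    )
    parclip["summary"].to_csv(
        os.path.join(outdir, "parclip_class_summary.tsv"), sep="\t", index=False
    )

    report = {
        "seed": seed,
        "pause": {k: v for k, v in pause.items() if not isinstance(v, pd.DataFrame)},
        "traveling_ratio": {
            k: v for k, v in tr.items() if not isinstance(v, pd.DataFrame)
        },
        "pier_null": piers_null,
        "pier_spiked": piers_spiked,
        "parclip": {k: v for k, v in parclip.items() if not isinstance(v, pd.DataFrame)},
    }
    with open(os.path.join(outdir, "recovery_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report
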