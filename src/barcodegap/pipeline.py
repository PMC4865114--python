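"""End-to-end orchestration: load -> trim -> purge -> subset -> distances
-> gap -> NJ -> lineages -> diagnostics -> OTUs -> OTU-relabelled re-gap.

``run_pipeline`` executes the whole analysis on one FASTA (plus optional
taxonomy map for subsetting) and writes a machine-readable bundle under a
run directory: per-dataset ``histogram.csv``, ``gap_report.tsv`` and
``pairs.tsv``; ``tree.nwk``, ``lineages.tsv``, ``misid_flags.tsv`` and
``diagnostics.tsv`` for the full dataset; ``otus.tsv`` and the
OTU-relabelled gap report; and a ``report.json`` indexing everything.
Stage failures abort with the stage name attached; partial outputs are
left in place for debugging.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .alignment import (
    AlignedDataset,
    TaxonomyMap,
    purge_imprecise_labels,
    read_fasta_alignment,
    subset_by_group,
    trim_terminal_gap_columns,
)
from .delimitation import cluster_otus, compare_partition_to_labels, regap_with_otus
from .diagnostics import run_diagnostic_screen
from .distances import (
    AnalysisConfig,
    GapReport,
    bin_comparisons,
    build_distance_matrix,
    build_histogram,
    detect_gap,
)
from .errors import EmptyBinError, StageError
from .tree import extract_lineages, flag_misidentifications, midpoint_root, neighbor_joining


@dataclass
class RunReport:
    summary: dict
    config: dict
    gap_reports: dict = field(default_factory=dict)  # dataset name -> dict
    subset_dirs: dict = field(default_factory=dict)
    n_lineages: int = 0
    n_misid_flags: int = 0
    n_diagnostic_reports: int = 0
    otu_summary: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    log_path: str = ""


def summarize_dataset(ds: AlignedDataset) -> tuple:
    """(n_sequences, n_unique_precise_labels, n_genera, alignment length)."""
    labels = {r.label.full.lower() for r in ds.records if r.label.precise}
    genera = {r.label.genus.lower() for r in ds.records}
    return len(ds), len(labels), len(genera), ds.length


def gap_report_to_dict(rep: GapReport) -> dict:
    return {
        "strict_gap": rep.strict_gap,
        "strict_gap_interval": rep.strict_gap_interval,
        "widest_empty_interval": rep.widest_empty_interval,
        "gap_width": rep.gap_width,
        "lower_flank": sorted(rep.lower_flank),
        "upper_flank": sorted(rep.upper_flank),
        "inter_below_low": {
            "count": rep.inter_below_low.count,
            "total": rep.inter_below_low.total,
            "percent": rep.inter_below_low.percent,
        },
        "intra_above_high": {
            "count": rep.intra_above_high.count,
            "total": rep.intra_above_high.total,
            "percent": rep.intra_above_high.percent,
        },
    }


def _write_gap_report_tsv(rep: GapReport, path: Path) -> None:
    flat = gap_report_to_dict(rep)
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in flat.items():
            fh.write(f"{key}\t{json.dumps(value)}\n")


def _analyze_dataset(ds, cfg, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    dm = build_distance_matrix(ds)
    bins = bin_comparisons(dm, ds.labels())
    hist = build_histogram(bins, cfg)
    with open(out_dir / "histogram.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["bin_lo", "bin_hi", "intra_count", "inter_count"]
        )
        writer.writeheader()
        writer.writerows(hist.to_rows())
    with open(out_dir / "pairs.tsv", "w") as fh:
        fh.write("id_a\tid_b\tbin\tdistance\tcomparable_sites\n")
        for name, pairs in (("intra", bins.intraspecific), ("inter", bins.interspecific)):
            for id_a, id_b, d in pairs:
                comp = dm.comparable_sites[dm.index(id_a), dm.index(id_b)]
                fh.write(f"{id_a}\t{id_b}\t{name}\t{d:.6f}\t{comp}\n")
    try:
        rep = detect_gap(bins, cfg)
    except EmptyBinError as exc:
        # single-species (or single-pair-type) dataset: no gap analysis
        (out_dir / "gap_report.tsv").write_text(f"key\tvalue\nerror\t{exc}\n")
        return dm, bins, None
    _write_gap_report_tsv(rep, out_dir / "gap_report.tsv")
    return dm, bins, rep


def run_pipeline(
    fasta,
    taxonomy=None,
    cfg: AnalysisConfig = AnalysisConfig(),
    subsets: tuple = (),
    out_dir="barcodegap_run",
    max_terminal_gap_fraction: float = 0.0,
    lineage_cutoff: float = 0.01,
    misid_max_dist: float = 0.01,
    min_group_size: int = 1,
) -> RunReport:
    """Run the full barcoding analysis; see the module docstring."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    log_fh = open(log_path, "w")
    t0 = time.time()

    def log(stage, **info):
        stamp = f"{time.time() - t0:8.2f}s"
        log_fh.write(f"{stamp}  {stage}  {json.dumps(info)}\n")
        log_fh.flush()

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            log(name, error=str(exc))
            log_fh.close()
            raise StageError(name, exc) from exc
        return result

    ds = stage("load", read_fasta_alignment, fasta)
    log("load", n_records=len(ds), length=ds.length)
    ds = stage("trim", trim_terminal_gap_columns, ds, max_terminal_gap_fraction)
    log("trim", length=ds.length)
    ds = stage("purge", purge_imprecise_labels, ds)
    log("purge", n_records=len(ds))

    n_seq, n_labels, n_genera, length = summarize_dataset(ds)
    report = RunReport(
        summary={
            "n_sequences": n_seq,
            "n_labels": n_labels,
            "n_genera": n_genera,
            "alignment_length": length,
        },
        config={**asdict(cfg), "lineage_cutoff": lineage_cutoff,
                "misid_max_dist": misid_max_dist, "min_group_size": min_group_size},
        log_path=str(log_path),
    )

    datasets = {"full": ds}
    if subsets:
        tmap = stage("taxonomy", TaxonomyMap.from_tsv, taxonomy)
        for level, name in subsets:
            key = f"{level}_{name}"
            datasets[key] = stage("subset", subset_by_group, ds, tmap, level, name)
            log("subset", dataset=key, n_records=len(datasets[key]))

    dm_full = None
    for key, sub_ds in datasets.items():
        sub_dir = out_dir / key
        dm, bins, rep = stage("gap_analysis", _analyze_dataset, sub_ds, cfg, sub_dir)
        report.gap_reports[key] = (
            gap_report_to_dict(rep) if rep is not None
            else {"error": "gap analysis undefined: one comparison bin is empty"}
        )
        report.subset_dirs[key] = str(sub_dir)
        log("gap_analysis", dataset=key,
            strict_gap=rep.strict_gap if rep is not None else None)
        if key == "full":
            dm_full = dm

    labels = ds.labels()
    tree = stage("nj_tree", neighbor_joining, dm_full)
    tree = stage("midpoint_root", midpoint_root, tree)
    tree.write(str(out_dir / "tree.nwk"))
    report.artifacts["tree"] = str(out_dir / "tree.nwk")

    lineages = stage("lineages", extract_lineages, tree, dm_full, labels, lineage_cutoff)
    with open(out_dir / "lineages.tsv", "w") as fh:
        fh.write("clade_number\tmember_ids\tmajority_label\ttie\tmax_internal_distance\n")
        for lin in lineages:
            fh.write(
                f"{lin.clade_number}\t{','.join(lin.member_ids)}\t"
                f"{lin.majority_label.full}\t{int(lin.tie)}\t"
                f"{lin.max_internal_distance:.6f}\n"
            )
    report.n_lineages = len(lineages)
    report.artifacts["lineages"] = str(out_dir / "lineages.tsv")
    log("lineages", n=len(lineages))

    flags = stage("misid_flags", flag_misidentifications, lineages, dm_full, misid_max_dist)
    with open(out_dir / "misid_flags.tsv", "w") as fh:
        fh.write("sequence_id\town_label\tclade_majority_label\tmin_distance_to_majority\n")
        for flag in flags:
            fh.write(
                f"{flag.sequence_id}\t{flag.own_label.full}\t"
                f"{flag.clade_majority_label.full}\t"
                f"{flag.min_distance_to_majority:.6f}\n"
            )
    report.n_misid_flags = len(flags)
    report.artifacts["misid_flags"] = str(out_dir / "misid_flags.tsv")
    log("misid_flags", n=len(flags))

    diag = stage("diagnostics", run_diagnostic_screen, lineages, ds, min_group_size)
    with open(out_dir / "diagnostics.tsv", "w") as fh:
        fh.write("clade_number\tscope\tgroup_size\tattributes\n")
        for rep_d in diag:
            fh.write(
                f"{rep_d.clade_number}\t{rep_d.scope}\t{rep_d.group_size}\t"
                f"{rep_d.attribute_string()}\n"
            )
    report.n_diagnostic_reports = len(diag)
    report.artifacts["diagnostics"] = str(out_dir / "diagnostics.tsv")
    log("diagnostics", n=len(diag))

    partition = stage("otu_clustering", cluster_otus, dm_full, cfg.species_rule_threshold)
    with open(out_dir / "otus.tsv", "w") as fh:
        fh.write("id\totu\n")
        for rec_id in dm_full.ids:
            fh.write(f"{rec_id}\t{partition.assignment[rec_id]}\n")
    comparison = compare_partition_to_labels(partition, labels)
    regap = stage("otu_regap", regap_with_otus, dm_full, partition, cfg)
    _write_gap_report_tsv(regap, out_dir / "gap_report_otu.tsv")
    report.otu_summary = {
        "threshold": partition.threshold,
        "n_otus": comparison.n_otus,
        "n_labels": comparison.n_labels,
        "n_split_labels": comparison.n_split_labels,
        "n_lumped_otus": comparison.n_lumped_otus,
        "regap": gap_report_to_dict(regap),
    }
    report.artifacts["otus"] = str(out_dir / "otus.tsv")
    log("otu_delimitation", n_otus=comparison.n_otus, regap_strict=regap.strict_gap)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=2)
    report.artifacts["report"] = str(out_dir / "report.json")
    log("done")
    log_fh.close()
    return report
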