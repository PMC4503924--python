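"""End-to-end orchestration: demux -> per-dataset read prep -> OTUs -> reports.

The pipeline mirrors the processing schema the package implements: pairs are
demultiplexed into datasets; datasets with an expected amplicon length of at
most 550 bp take the overlap-join path (with the quality-threshold sweep),
longer ones the scaffold path; each dataset is then dereplicated,
singleton-filtered, chimera-checked, clustered, and mapped into an OTU
table. Optional contaminant classification runs when reference FASTA files
are configured. The run report reconciles counts across every stage and is
byte-identical across runs with the same config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .contam import classify_table, summarize_contamination
from .demux import demultiplex
from .otu import cluster_greedy, dereplicate, map_reads, remove_singletons
from .readprep import (
    DEFAULT_SWEEP_THRESHOLDS,
    build_scaffold,
    filter_contig_length,
    long_path_prepare,
    sweep_join,
)
from .seqio import read_fasta, read_fastq, read_mapping, write_fasta, ReadPair

log = logging.getLogger("ampflow")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML-loadable)."""

    r1: str
    r2: str
    mapping: str
    out_dir: str
    max_barcode_mm: int = 1
    max_primer_mm: int = 1
    check_head: bool = False
    sweep_thresholds: tuple = DEFAULT_SWEEP_THRESHOLDS
    min_overlap: int = 6
    max_mismatch_frac: float = 0.08
    read_len: int = 300
    chimera_check: bool = True
    mock_refs: str | None = None
    nonmock_refs: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        d["sweep_thresholds"] = list(self.sweep_thresholds)
        return d


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full pipeline; returns (and writes) the run report.

    Stage outputs land under ``out_dir`` (``demux/``, ``prep/<dataset>/``,
    ``otu/<dataset>/``); a ``MANIFEST.json`` marks progress so partial runs
    are identifiable. Raises with the failing stage named.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for path_attr in ("r1", "r2", "mapping"):
        if not Path(getattr(config, path_attr)).exists():
            raise FileNotFoundError(f"{path_attr} file not found: {getattr(config, path_attr)}")
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    manifest: dict[str, Any] = {"version": __version__, "complete": False, "stages": []}

    def _save_manifest() -> None:
        with open(out_dir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    report: dict[str, Any] = {"stages": {}}
    try:
        stage = "demux"
        log.info("stage %s: reading %s / %s", stage, config.r1, config.r2)
        libraries, datasets = read_mapping(config.mapping)
        pairs = (
            ReadPair(f, r) for f, r in zip(read_fastq(config.r1), read_fastq(config.r2))
        )
        stats, by_dataset = demultiplex(
            pairs,
            libraries,
            datasets,
            out_dir / "demux",
            config.max_barcode_mm,
            config.max_primer_mm,
            config.check_head,
        )
        report["stages"]["demux"] = {
            "total_pairs": stats.total_pairs,
            "assigned_pairs": stats.assigned_pairs,
            "ambiguous_pairs": stats.ambiguous_pairs,
            "unassigned_pairs": stats.unassigned_pairs,
            "per_library": dict(sorted(stats.per_library.items())),
        }
        manifest["stages"].append(stage)
        _save_manifest()

        ds_by_id = {d.dataset_id: d for d in datasets}
        mock_refs = read_fasta(config.mock_refs) if config.mock_refs else None
        nonmock_refs = read_fasta(config.nonmock_refs) if config.nonmock_refs else []

        for ds_id, assignments in by_dataset.items():
            ds = ds_by_id[ds_id]
            stage = f"prep:{ds_id}"
            tagged = [(a.library_id, a.trimmed_pair) for a in assignments]
            prep_dir = out_dir / "prep" / ds_id
            prep_dir.mkdir(parents=True, exist_ok=True)
            if ds.path == "short":
                sweep, contigs = sweep_join(
                    tagged, config.sweep_thresholds, config.min_overlap, config.max_mismatch_frac
                )
                kept = filter_contig_length(contigs, ds.expected_len)
                with open(prep_dir / "sweep.tsv", "w") as fh:
                    fh.write("threshold\tcontigs\tchosen\n")
                    for q, n in zip(sweep.thresholds, sweep.contig_counts):
                        fh.write(f"{q}\t{n}\t{int(q == sweep.chosen_threshold)}\n")
                prep_report = {
                    "path": "short",
                    "input_pairs": len(tagged),
                    "contigs": len(contigs),
                    "kept_after_length_filter": len(kept),
                    "chosen_threshold": sweep.chosen_threshold,
                }
            else:
                uniform = long_path_prepare(tagged, config.read_len)
                kept = [build_scaffold(p.forward, p.reverse, lib) for lib, p in uniform]
                prep_report = {
                    "path": "long",
                    "input_pairs": len(tagged),
                    "kept_after_length_filter": len(kept),
                    "scaffolds": len(kept),
                }
            write_fasta(
                ((f"{c.library_id}:{i}", c.sequence) for i, c in enumerate(kept)),
                prep_dir / "sequences.fasta",
            )
            report["stages"][stage] = prep_report
            manifest["stages"].append(stage)
            _save_manifest()

            stage = f"otu:{ds_id}"
            otu_dir = out_dir / "otu" / ds_id
            otu_dir.mkdir(parents=True, exist_ok=True)
            otu_report: dict[str, Any] = {"input_sequences": len(kept)}
            if kept:
                uniques = dereplicate(kept)
                retained = remove_singletons(uniques)
                otus, chimeras = cluster_greedy(
                    retained, ds.otu_radius_pct, chimera_check=config.chimera_check
                )
                otu_report.update(
                    {
                        "unique_sequences": len(uniques),
                        "non_singletons": len(retained),
                        "otus": len(otus),
                        "chimeras_discarded": len(chimeras),
                    }
                )
                with open(otu_dir / "chimeras.tsv", "w") as fh:
                    fh.write("sequence\tabundance\n")
                    for ch in chimeras:
                        fh.write(f"{ch.sequence}\t{ch.abundance}\n")
                if otus:
                    lib_ids = sorted({l.library_id for l in libraries if l.dataset_id == ds_id})
                    table = map_reads(kept, otus, ds.map_identity, library_ids=lib_ids)
                    table.check({lib: sum(1 for c in kept if c.library_id == lib) for lib in lib_ids})
                    write_fasta(
                        ((o.otu_id, o.centroid) for o in otus), otu_dir / "centroids.fasta"
                    )
                    table.to_tsv(otu_dir / "otu_table.tsv")
                    otu_report["mapped_reads"] = int(table.counts.to_numpy().sum())
                    otu_report["unmapped_reads"] = int(table.unmapped.sum())
                    if mock_refs:
                        stage = f"classify:{ds_id}"
                        calls = classify_table(table, mock_refs, nonmock_refs)
                        summary = summarize_contamination(table, calls)
                        summary.to_csv(otu_dir / "contamination.tsv", sep="\t")
                        with open(otu_dir / "calls.tsv", "w") as fh:
                            fh.write(
                                "otu_id\tverdict\tbest_mock_id\tbest_nonmock_id\tbest_nonmock_label\n"
                            )
                            for c in calls:
                                fh.write(
                                    f"{c.otu_id}\t{c.verdict}\t{c.best_mock_id:.4f}"
                                    f"\t{c.best_nonmock_id:.4f}\t{c.best_nonmock_label}\n"
                                )
                        otu_report["contaminant_otus"] = sum(
                            1 for c in calls if c.verdict == "contaminant"
                        )
            report["stages"][f"otu:{ds_id}"] = otu_report
            manifest["stages"].append(f"otu:{ds_id}")
            _save_manifest()
    except Exception as exc:
        manifest["failed_stage"] = stage
        _save_manifest()
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    manifest["complete"] = True
    _save_manifest()
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
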