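"""End-to-end orchestration: align -> screen -> structure -> integrity -> report.

``run_pipeline`` executes the stages in order, records per-stage status, and
always emits a report for whatever completed; optional stages (integrity,
qPCR, dot plot) are skipped cleanly when their inputs are absent.  The
report is a plain nested dict serialized as JSON (lossless round trip) or a
TSV bundle with one file per result family.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import tgarray
from tgarray.align import TargetRegistry, align_reads, index_targets
from tgarray.integrity import GeneModel, gene_integrity, propose_gap_intervals
from tgarray.qpcr import SampleDesign, copies_per_allele, delta_delta_ct
from tgarray.screen import (classify_reads, copy_number_from_depth,
                            count_marker_matches, run_stats)
from tgarray.structure import (call_junctions, detect_contaminant,
                               detect_inversions, minimal_tiling_path)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All pipeline parameters with their defaults.

    Sequence inputs are passed in-memory (the CLI loads files into these
    fields).  ``genome_size`` is the denominator of fold-coverage; at desk
    scale it is the summed haplotype length, at full scale a genome size.
    """

    reads: list = field(default_factory=list)          # (id, seq) or SimRead
    registry: Optional[TargetRegistry] = None
    gene_models: list[GeneModel] = field(default_factory=list)
    qpcr_wells: list = field(default_factory=list)
    qpcr_design: Optional[SampleDesign] = None
    qpcr_calibrator_sample: str = "cal"
    qpcr_test_sample: str = "test"
    genome_size: int = 0
    seed: int = 0
    k: int = 15
    min_seed_chain: int = 3
    min_segment_len: int = 200
    min_identity: float = 0.6
    min_marker_cov: float = 0.5
    max_junction_gap: int = 100
    cluster_radius: int = 50
    tiling_min_overlap: int = 1000


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all applicable stages; deterministic for a fixed config."""
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package": "tgarray", "version": tgarray.__version__,
            "seed": config.seed,
            "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                           if isinstance(v, (int, float, str))},
        },
        "stages": {},
    }
    if config.registry is None or not config.reads:
        report["stages"]["align"] = "skipped: no reads or targets"
        return report

    reads = [(r.read_id, r.sequence) if hasattr(r, "read_id") else tuple(r)
             for r in config.reads]

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
            report["stages"][name] = "ok"
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        except Exception as e:  # recorded, downstream dependents skip
            report["stages"][name] = f"error: {e}"
            logger.warning("stage %s failed: %s", name, e)
            return None

    index = stage("index", lambda: index_targets(config.registry, config.k))
    segments = None
    if index is not None:
        segments = stage("align", lambda: align_reads(
            reads, index, min_seed_chain=config.min_seed_chain,
            min_segment_len=config.min_segment_len,
            min_identity=config.min_identity))

    genome_size = config.genome_size or sum(
        len(e.sequence) for e in config.registry.entries.values())
    stats = stage("run_stats", lambda: run_stats(reads, genome_size))
    if stats is not None:
        report["run_stats"] = stats.to_dict()

    if segments is None:
        return report

    classifications = stage("screen", lambda: classify_reads(
        segments, config.registry, config.min_marker_cov, read_seqs=dict(reads)))
    if classifications is not None:
        reads_with, total_matches = count_marker_matches(classifications)
        report["marker_counts"] = {"reads_with_marker": reads_with,
                                   "total_matches": total_matches}
        estimates = []
        if stats is not None and stats.coverage > 0:
            estimates.append(copy_number_from_depth(total_matches, stats.coverage).to_dict())
        report["copy_number_estimates"] = estimates

    calls = stage("junctions", lambda: call_junctions(
        segments, config.registry, config.max_junction_gap, config.cluster_radius,
        read_seqs=dict(reads)))
    if calls is not None:
        report["integration_calls"] = [c.to_dict() for c in calls]

    inversions = stage("inversions", lambda: detect_inversions(segments, config.registry))
    if inversions is not None:
        report["inversions"] = [dataclasses.asdict(e) for e in inversions]

    if config.registry.ids_with_role("contaminant"):
        cont = stage("contaminant", lambda: detect_contaminant(segments, config.registry))
        if cont is not None:
            report["contaminant_calls"] = [dataclasses.asdict(c) for c in cont]
    else:
        report["stages"]["contaminant"] = "skipped: no contaminant target"

    if classifications is not None:
        seq_of = dict(reads)
        marker_hits = {}
        for c in classifications:
            if c.marker_match_count:
                ivs = [(s.read_start, s.read_end) for s in segments[c.read_id]
                       if config.registry.role_of(s.target_id) == "marker"]
                marker_hits[c.read_id] = ivs
        anchor = None
        if calls:
            for c in calls:
                for rid in c.support_left + c.support_right:
                    if marker_hits.get(rid):
                        anchor = rid
                        break
                if anchor:
                    break
        if marker_hits:
            from tgarray.structure import read_landmarks
            lm = read_landmarks(segments, config.registry)
            tiling = stage("tiling", lambda: minimal_tiling_path(
                {r: seq_of[r] for r in marker_hits}, marker_hits,
                anchor_read=anchor, landmarks=lm,
                min_overlap=config.tiling_min_overlap, k=config.k))
            if tiling is not None:
                report["tiling_path"] = dataclasses.asdict(tiling)
        else:
            report["stages"]["tiling"] = "skipped: no marker-bearing reads"

    if config.gene_models:
        integ = calls[0] if calls else None
        res = stage("integrity", lambda: gene_integrity(
            config.gene_models, segments, config.registry, integ))
        if res is not None:
            report["gene_integrity"] = [dataclasses.asdict(r) for r in res]
            report["pcr_gap_intervals"] = propose_gap_intervals(res)
    else:
        report["stages"]["integrity"] = "skipped: no gene models"

    if config.qpcr_wells and config.qpcr_design is not None:
        def _qpcr():
            rq = delta_delta_ct(config.qpcr_wells, config.qpcr_test_sample,
                                config.qpcr_calibrator_sample)
            return copies_per_allele(rq, config.qpcr_design)
        est = stage("qpcr", _qpcr)
        if est is not None:
            report.setdefault("copy_number_estimates", []).append(est.to_dict())
    else:
        report["stages"]["qpcr"] = "skipped: no qPCR input"

    return report


def write_report(report: dict, out_dir, fmt: str = "json") -> list[Path]:
    """Serialize the report; ``json`` (one file) or ``tsv`` bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt == "json":
        p = out_dir / "report.json"
        with open(p, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        written.append(p)
    elif fmt == "tsv":
        import pandas as pd
        for key in ("integration_calls", "inversions", "contaminant_calls",
                    "gene_integrity", "copy_number_estimates"):
            rows = report.get(key)
            if rows:
                p = out_dir / f"{key}.tsv"
                pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
                written.append(p)
        p = out_dir / "summary.json"
        with open(p, "w") as fh:
            json.dump({k: v for k, v in report.items()
                       if not isinstance(v, list)}, fh, indent=1, sort_keys=True)
        written.append(p)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return written
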