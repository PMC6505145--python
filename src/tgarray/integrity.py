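"""Integrity of genes neighboring an integration site.

A gene passes the strictest check when a single read's host-aligned span
encompasses its entire protein-coding sequence; residual intervals uncovered
by any read are emitted as the regions a PCR assay must span.  A gene whose
CDS span intersects the called integration interval is flagged disrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from tgarray.align import ROLE_HOST, AlignmentSegment, TargetRegistry
from tgarray.structure import IntegrationCall

Interval = tuple[int, int]  # 0-based half-open


@dataclass
class GeneModel:
    name: str
    chrom: str
    strand: str
    cds_intervals: list[Interval]

    def __post_init__(self) -> None:
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS intervals in {self.name}")
        self.cds_intervals = ivs

    @property
    def cds_span(self) -> Interval:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]


@dataclass
class GeneIntegrityResult:
    gene: str
    encompassed: bool
    encompassing_read_ids: list[str] = field(default_factory=list)
    uncovered_intervals: list[Interval] = field(default_factory=list)
    disrupted: bool = False
    error: Optional[str] = None


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(span: Interval, covered: Sequence[Interval]) -> list[Interval]:
    """``span`` minus the union of ``covered``."""
    s, e = span
    out: list[Interval] = []
    pos = s
    for cs, ce in merge_intervals(covered):
        if ce <= pos or cs >= e:
            continue
        if cs > pos:
            out.append((pos, cs))
        pos = max(pos, ce)
    if pos < e:
        out.append((pos, e))
    return out


def read_host_spans(
    segments_by_read: dict[str, list[AlignmentSegment]],
    registry: TargetRegistry,
    chrom: str,
    max_internal_gap: int = 1000,
) -> dict[str, list[Interval]]:
    """Per-read merged host-aligned spans on ``chrom``.

    Noisy long-read alignments fragment; gaps up to ``max_internal_gap`` bp
    between a read's host segments are bridged, larger gaps split the span.
    """
    spans: dict[str, list[Interval]] = {}
    for rid, segs in segments_by_read.items():
        ivs = sorted((s.target_start, s.target_end) for s in segs
                     if s.target_id == chrom and registry.role_of(s.target_id) == ROLE_HOST)
        merged: list[Interval] = []
        for s, e in ivs:
            if merged and s - merged[-1][1] <= max_internal_gap:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        if merged:
            spans[rid] = merged
    return spans


def gene_integrity(
    gene_models: Sequence[GeneModel],
    segments_by_read: dict[str, list[AlignmentSegment]],
    registry: TargetRegistry,
    integration: Optional[IntegrationCall] = None,
    max_internal_gap: int = 1000,
) -> list[GeneIntegrityResult]:
    """Check each gene's CDS span against read host spans.

    ``encompassed`` needs one read whose merged span contains the whole CDS
    span; ``uncovered_intervals`` is the CDS span minus the union of all
    reads' spans (two deliberately different criteria, both reported).
    """
    host_ids = set(registry.ids_with_role(ROLE_HOST))
    spans_by_chrom: dict[str, dict[str, list[Interval]]] = {}
    results: list[GeneIntegrityResult] = []
    for g in gene_models:
        if g.chrom not in host_ids:
            results.append(GeneIntegrityResult(
                g.name, False, error=f"unknown contig {g.chrom!r}"))
            continue
        if g.chrom not in spans_by_chrom:
            spans_by_chrom[g.chrom] = read_host_spans(
                segments_by_read, registry, g.chrom, max_internal_gap)
        spans = spans_by_chrom[g.chrom]
        gs, ge = g.cds_span
        encompassing = sorted(
            rid for rid, ivs in spans.items()
            if any(s <= gs and ge <= e for s, e in ivs))
        all_ivs = [iv for ivs in spans.values() for iv in ivs]
        uncovered = subtract_intervals((gs, ge), all_ivs)
        disrupted = False
        if integration is not None and integration.chrom == g.chrom:
            lb = integration.left_boundary
            rb = integration.right_boundary
            if lb is not None and rb is not None:
                deleted = (lb, rb - 1)  # 0-based half-open deleted host bases
                disrupted = (deleted[0] < ge and deleted[1] > gs) or (gs < lb < ge)
            elif lb is not None:
                disrupted = gs < lb < ge
            elif rb is not None:
                disrupted = gs < rb - 1 < ge
        results.append(GeneIntegrityResult(
            g.name, encompassed=bool(encompassing),
            encompassing_read_ids=encompassing,
            uncovered_intervals=uncovered, disrupted=disrupted))
    return results


def propose_gap_intervals(
    results: Sequence[GeneIntegrityResult],
    flank: int = 300,
    contig_len: Optional[int] = None,
) -> list[Interval]:
    """Uncovered intervals extended by ``flank`` bp and merged: the regions
    a follow-up PCR assay must span."""
    ivs = []
    for r in results:
        for s, e in r.uncovered_intervals:
            lo = max(0, s - flank)
            hi = e + flank if contig_len is None else min(contig_len, e + flank)
            ivs.append((lo, hi))
    return merge_intervals(ivs)


# ---------------------------------------------------------------------------
# gene-model file input

def read_gene_models_bed12(path) -> list[GeneModel]:
    """BED12: blocks intersected with [thickStart, thickEnd) give the CDS."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 fields, got {len(f)}")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick = (int(f[6]), int(f[7]))
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            cds = []
            for bs, sz in zip(starts, sizes):
                s = max(start + bs, thick[0])
                e = min(start + bs + sz, thick[1])
                if s < e:
                    cds.append((s, e))
            if cds:
                out.append(GeneModel(name, chrom, strand, cds))
    return out


def read_gene_models_gff3(path) -> list[GeneModel]:
    """GFF3 via gffutils: CDS features grouped by their gene ancestor."""
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out = []
    for gene in db.features_of_type("gene"):
        cds = [(c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")]
        if cds:
            out.append(GeneModel(gene.id, gene.seqid, gene.strand,
                                 merge_intervals(cds)))
    return out


def read_gene_models(path) -> list[GeneModel]:
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        return read_gene_models_gff3(p)
    return read_gene_models_bed12(p)
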