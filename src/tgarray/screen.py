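"""Run statistics, marker-bearing read screening, and depth-based copy number.

The depth estimator mirrors the whole-genome arithmetic used to size tandem
transgene arrays: every alignment of a read to the marker sequence is one
sampling of one array copy, so at fold-coverage ``c`` an array of ``C``
copies yields ``C x c`` marker matches in expectation, and
``total_matches / c`` estimates ``C``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from tgarray.align import (ROLE_CONTAMINANT, ROLE_HOST, ROLE_MARKER,
                           ROLE_TRANSGENE, AlignmentSegment, TargetRegistry)


@dataclass
class RunStats:
    """Whole-run summary: read count, yield, N50, fold-coverage."""

    n_reads: int
    total_bases: int
    n50: int
    genome_size: int
    coverage: float

    @classmethod
    def from_lengths(cls, lengths: Sequence[int], genome_size: int) -> "RunStats":
        if genome_size <= 0:
            raise ValueError("genome_size must be > 0")
        if len(lengths) == 0:
            return cls(0, 0, 0, genome_size, 0.0)
        total = int(sum(lengths))
        return cls(len(lengths), total, n50(lengths), genome_size, total / genome_size)

    @property
    def coverage_1dp(self) -> float:
        """Fold-coverage to one decimal, the precision used in reporting."""
        return round(self.coverage, 1)

    def to_dict(self) -> dict:
        return {"n_reads": self.n_reads, "total_bases": self.total_bases,
                "n50": self.n50, "genome_size": self.genome_size,
                "coverage": self.coverage_1dp}


@dataclass
class ReadClassification:
    read_id: str
    marker_match_count: int = 0
    has_host: bool = False
    has_transgene: bool = False
    has_contaminant: bool = False

    @property
    def chimeric(self) -> bool:
        """Host and transgene sequence on one read: junction evidence."""
        return self.has_host and self.has_transgene


@dataclass
class CopyNumberEstimate:
    """Copy estimate tagged by method: depth | tiling_lower_bound | qpcr."""

    method: str
    value: float
    dispersion: Optional[float] = None
    n_support: int = 0

    @property
    def rounded(self) -> int:
        return int(round(self.value))

    def to_dict(self) -> dict:
        return {"method": self.method, "value": self.value,
                "dispersion": self.dispersion, "n_support": self.n_support}


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that reads of length >= L hold at least half the bases."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if (arr <= 0).any():
        raise ValueError("read lengths must be positive")
    half = arr.sum() / 2
    idx = int(np.searchsorted(np.cumsum(arr), half, side="left"))
    return int(arr[idx])


def run_stats(reads: Iterable, genome_size: int) -> RunStats:
    """RunStats from read records ((id, seq) pairs or .sequence objects)."""
    lengths = [len(r.sequence if hasattr(r, "sequence") else r[1]) for r in reads]
    return RunStats.from_lengths(lengths, genome_size)


def classify_reads(
    segments_by_read: dict[str, list[AlignmentSegment]],
    registry: TargetRegistry,
    min_marker_cov: float = 0.5,
    read_seqs: Optional[dict[str, str]] = None,
) -> list[ReadClassification]:
    """Per-read role flags and distinct marker-match counts.

    A marker segment counts as a match when it covers at least
    ``min_marker_cov`` of the marker target; two marker hits on one read are
    distinct when their read intervals overlap by less than 50% of the
    shorter interval (guards against one copy split into two segments).

    When ``read_seqs`` is given, marker segments whose span sits near the
    counting threshold are re-measured by gapped end extension — on noisy
    reads the fast segment ends erode at indels, which would otherwise bias
    the match count (and hence the depth copy estimate) low.
    """
    from tgarray.align import refine_target_span

    marker_ids = set(registry.ids_with_role(ROLE_MARKER))
    marker_lens = {m: len(registry.sequence(m)) for m in marker_ids}
    out = []
    for read_id, segs in segments_by_read.items():
        c = ReadClassification(read_id)
        marker_ivs: list[tuple[int, int]] = []
        for s in segs:
            role = registry.role_of(s.target_id)
            if role == ROLE_HOST:
                c.has_host = True
            elif role == ROLE_TRANSGENE:
                c.has_transgene = True
            elif role == ROLE_CONTAMINANT:
                c.has_contaminant = True
            elif role == ROLE_MARKER:
                span = s.target_end - s.target_start
                thr = min_marker_cov * marker_lens[s.target_id]
                if read_seqs is not None and thr - 100 <= span < thr + 40:
                    ts, te = refine_target_span(
                        s, read_seqs[read_id], registry.sequence(s.target_id))
                    span = te - ts
                if span >= thr:
                    marker_ivs.append((s.read_start, s.read_end))
        marker_ivs.sort()
        kept: list[tuple[int, int]] = []
        for iv in marker_ivs:
            distinct = all(
                (min(iv[1], kv[1]) - max(iv[0], kv[0]))
                < 0.5 * min(iv[1] - iv[0], kv[1] - kv[0])
                for kv in kept)
            if distinct:
                kept.append(iv)
        c.marker_match_count = len(kept)
        out.append(c)
    return out


def count_marker_matches(classifications: Iterable[ReadClassification]) -> tuple[int, int]:
    """(number of reads with >=1 marker match, total marker matches)."""
    reads_with = total = 0
    for c in classifications:
        if c.marker_match_count >= 1:
            reads_with += 1
        total += c.marker_match_count
    return reads_with, total


def copy_number_from_depth(total_matches: int, coverage: float) -> CopyNumberEstimate:
    """Copies per allele from marker matches and fold-coverage.

    ``value = total_matches / coverage`` with a Poisson dispersion
    ``sqrt(total_matches)/coverage``.  No zygosity correction is applied:
    dividing by whole-genome coverage treats the transgene allele as present
    once per haploid genome equivalent (see docs/methods.md).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if total_matches < 0:
        raise ValueError("total_matches must be >= 0")
    return CopyNumberEstimate(
        method="depth",
        value=total_matches / coverage,
        dispersion=math.sqrt(total_matches) / coverage,
        n_support=total_matches,
    )
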