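"""Strand-aware local alignment of long reads against a small target registry.

The aligner is a k-mer seed-and-chain design: canonical k-mers of every
target are indexed; read seeds are grouped by (target, strand, diagonal
band) and the longest co-linear chain in each band becomes a candidate
segment, extended exactly at its ends and scored by edit distance (edlib).
It trades base-level alignment paths for speed and determinism — downstream
callers only need segment intervals, strand and identity, the same semantics
a long-read mapper's PAF rows carry.  ``read_paf`` ingests such external
output interchangeably.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

import edlib
import numpy as np

from tgarray.seqs import check_alphabet, encode, revcomp

logger = logging.getLogger(__name__)

ROLE_HOST = "host"
ROLE_TRANSGENE = "transgene"
ROLE_MARKER = "marker"
ROLE_CONTAMINANT = "contaminant"


@dataclass(frozen=True)
class AlignmentSegment:
    """One local alignment between a read interval and a target interval.

    Coordinates are 0-based half-open, read coordinates always on the read's
    forward orientation.  ``identity = n_match / block_len``.
    """

    read_id: str
    read_start: int
    read_end: int
    target_id: str
    target_start: int
    target_end: int
    strand: str  # '+' or '-'
    n_match: int
    block_len: int

    def __post_init__(self) -> None:
        if not (self.read_start < self.read_end and self.target_start < self.target_end):
            raise ValueError("empty alignment interval")
        if self.n_match > self.block_len:
            raise ValueError("n_match exceeds block_len")

    @property
    def identity(self) -> float:
        return self.n_match / self.block_len


@dataclass
class TargetEntry:
    sequence: str
    role: str


@dataclass
class TargetRegistry:
    """Named alignment targets with their biological roles.

    Typical registry: the host contig, the transgene unit, the marker
    subsequence screened for copy counting, and an optional contaminant
    genome segment.
    """

    entries: dict[str, TargetEntry] = field(default_factory=dict)
    marker_interval: Optional[tuple[int, int]] = None  # marker location on the unit

    def add(self, target_id: str, sequence: str, role: str) -> None:
        if target_id in self.entries:
            raise ValueError(f"duplicate target id {target_id!r}")
        self.entries[target_id] = TargetEntry(sequence.upper(), role)

    def role_of(self, target_id: str) -> str:
        return self.entries[target_id].role

    def sequence(self, target_id: str) -> str:
        return self.entries[target_id].sequence

    def ids_with_role(self, role: str) -> list[str]:
        return [t for t, e in self.entries.items() if e.role == role]

    @classmethod
    def build(cls, host: str, unit=None, contaminant: Optional[str] = None,
              host_id: str = "hostseq") -> "TargetRegistry":
        """Standard registry from a host contig and a TransgeneUnit."""
        reg = cls()
        reg.add(host_id, host, ROLE_HOST)
        if unit is not None:
            reg.add("transgene", unit.sequence, ROLE_TRANSGENE)
            reg.add("marker", unit.marker_sequence, ROLE_MARKER)
            reg.marker_interval = unit.marker_interval
        if contaminant is not None:
            reg.add("contaminant", contaminant, ROLE_CONTAMINANT)
        return reg


# ---------------------------------------------------------------------------
# k-mer machinery

def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(positions, canonical codes, forward-is-canonical) for all valid windows."""
    L = codes.size
    n = L - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, np.empty(0, dtype=bool)
    b = codes.astype(np.int64)
    invalid = codes == 255
    b[invalid] = 0
    fwd = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = fwd * 4 + b[j:j + n]
    rev = np.zeros(n, dtype=np.int64)
    for j in range(k - 1, -1, -1):
        rev = rev * 4 + (3 - b[j:j + n])
    invc = np.concatenate(([0], np.cumsum(invalid)))
    ok = (invc[k:] - invc[:n]) == 0
    pos = np.flatnonzero(ok)
    canon = np.minimum(fwd[ok], rev[ok])
    orient = fwd[ok] <= rev[ok]
    return pos, canon, orient


def _multi_arange(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    base = np.repeat(starts, counts)
    offs = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(counts) - counts, counts)
    return base + offs


@dataclass
class SeedIndex:
    """Sorted canonical k-mer index over a registry."""

    k: int
    registry: TargetRegistry
    target_ids: list[str]
    codes: np.ndarray   # sorted canonical k-mer codes
    pos: np.ndarray     # target positions
    tid: np.ndarray     # index into target_ids
    orient: np.ndarray  # True if the target's forward k-mer is canonical


def index_targets(registry: TargetRegistry, k: int = 15) -> SeedIndex:
    """Index every canonical k-mer position of every registry target.

    k-mers containing N are skipped.
    """
    if not registry.entries:
        raise ValueError("empty target registry")
    if not 8 <= k <= 21:
        raise ValueError(f"k={k} outside supported range [8, 21]")
    target_ids = list(registry.entries)
    parts = []
    for t, name in enumerate(target_ids):
        seq = registry.entries[name].sequence
        pos, canon, orient = _kmer_codes(encode(seq), k)
        parts.append((canon, pos, np.full(pos.size, t, dtype=np.int32), orient))
    codes = np.concatenate([p[0] for p in parts])
    if codes.size == 0:
        warnings.warn(f"k={k} exceeds every target length; index is empty")
    pos = np.concatenate([p[1] for p in parts])
    tid = np.concatenate([p[2] for p in parts])
    orient = np.concatenate([p[3] for p in parts])
    order = np.argsort(codes, kind="stable")
    return SeedIndex(k, registry, target_ids,
                     codes[order], pos[order], tid[order], orient[order])


def _lis_chain(tpos: np.ndarray) -> list[int]:
    """Indices of a longest strictly increasing subsequence of ``tpos``.

    Input order is chain order (sorted by read position); ties on equal
    values are excluded (strictness) so one read position claims one seed.
    """
    tails: list[int] = []        # tpos value ending each pile
    tails_idx: list[int] = []
    parent = np.full(tpos.size, -1, dtype=np.int64)
    for i, v in enumerate(tpos):
        j = bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        elif v < tails[j]:
            tails[j] = v
            tails_idx[j] = i
        else:
            continue
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    out: list[int] = []
    i = tails_idx[-1]
    while i != -1:
        out.append(i)
        i = parent[i]
    return out[::-1]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _xdrop(read_seq: str, tseq: str, r0: int, t0: int, rdir: int, tdir: int,
           comp: bool, drop: int = 6) -> int:
    """Ungapped X-drop extension from (r0, t0) exclusive, stepping rdir/tdir.

    Scores +1 per match, -2 per mismatch; stops when the running score falls
    ``drop`` below its maximum and returns the number of steps up to the
    maximum (so segment ends stay at the last net-positive position, which
    pins junction boundaries tightly even on noisy reads).
    """
    score = best = 0
    steps = best_steps = 0
    r, t = r0 + rdir, t0 + tdir
    n_r, n_t = len(read_seq), len(tseq)
    while 0 <= r < n_r and 0 <= t < n_t:
        tb = tseq[t]
        if comp:
            tb = _COMP[tb]
        score += 1 if read_seq[r] == tb else -2
        steps += 1
        if score > best:
            best, best_steps = score, steps
        elif best - score >= drop:
            break
        r += rdir
        t += tdir
    return best_steps



def align_read(
    read_seq: str,
    index: SeedIndex,
    min_seed_chain: int = 3,
    min_segment_len: int = 200,
    min_identity: float = 0.6,
    read_id: str = "read",
    band: int = 300,
    max_hits_per_kmer: int = 64,
    resolve_same_target: bool = True,
) -> list[AlignmentSegment]:
    """Local segments of one read against all indexed targets.

    Seeds sharing a target, strand and diagonal band are chained (longest
    co-linear subset); chains are extended exactly at both ends, scored by
    edit distance, and filtered on length and identity.  Within one target,
    a segment overlapping a better-scoring kept segment by >=50% of the
    shorter read interval is dropped; overlaps across different targets are
    expected (e.g. marker inside transgene unit) and kept.
    """
    read_seq = read_seq.upper()
    check_alphabet(read_seq)
    codes = encode(read_seq)
    pos_r, canon_r, orient_r = _kmer_codes(codes, index.k)
    if pos_r.size == 0 or index.codes.size == 0:
        return []
    left = np.searchsorted(index.codes, canon_r, side="left")
    right = np.searchsorted(index.codes, canon_r, side="right")
    counts = right - left
    sel = (counts > 0) & (counts <= max_hits_per_kmer)
    if not sel.any():
        return []
    flat = _multi_arange(left[sel], counts[sel])
    rpos = np.repeat(pos_r[sel], counts[sel])
    r_or = np.repeat(orient_r[sel], counts[sel])
    tpos = index.pos[flat]
    tid = index.tid[flat]
    t_or = index.orient[flat]
    plus = r_or == t_or
    diag = np.where(plus, tpos - rpos, tpos + rpos)

    order = np.lexsort((rpos, diag, plus, tid))
    tid, plus, diag, rpos, tpos = tid[order], plus[order], diag[order], rpos[order], tpos[order]
    brk = np.flatnonzero((np.diff(tid) != 0) | (np.diff(plus) != 0)
                         | (np.abs(np.diff(diag)) > band)) + 1
    bounds = np.concatenate(([0], brk, [tid.size]))

    k = index.k
    segments: list[AlignmentSegment] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        n_seeds = hi - lo
        if n_seeds < min_seed_chain:
            continue
        c_rpos, c_tpos = rpos[lo:hi], tpos[lo:hi]
        is_plus = bool(plus[lo])
        sub = np.lexsort((c_tpos, c_rpos))
        c_rpos, c_tpos = c_rpos[sub], c_tpos[sub]
        chain = _lis_chain(c_tpos if is_plus else -c_tpos)
        if len(chain) < min_seed_chain:
            continue
        rs = int(c_rpos[chain[0]])
        re_ = int(c_rpos[chain[-1]]) + k
        tname = index.target_ids[int(tid[lo])]
        tseq = index.registry.entries[tname].sequence
        if is_plus:
            ts = int(c_tpos[chain[0]])
            te = int(c_tpos[chain[-1]]) + k
            ext = _xdrop(read_seq, tseq, rs, ts, -1, -1, comp=False)
            rs -= ext
            ts -= ext
            ext = _xdrop(read_seq, tseq, re_ - 1, te - 1, +1, +1, comp=False)
            re_ += ext
            te += ext
        else:
            ts = int(c_tpos[chain[-1]])
            te = int(c_tpos[chain[0]]) + k
            ext = _xdrop(read_seq, tseq, rs, te - 1, -1, +1, comp=True)
            rs -= ext
            te += ext
            ext = _xdrop(read_seq, tseq, re_ - 1, ts, +1, -1, comp=True)
            re_ += ext
            ts -= ext
        if re_ - rs < min_segment_len:
            continue
        frag = read_seq[rs:re_] if is_plus else revcomp(read_seq[rs:re_])
        dist = edlib.align(frag, tseq[ts:te], mode="NW", task="distance")["editDistance"]
        block_len = max(re_ - rs, te - ts)
        n_match = block_len - dist
        if n_match / block_len < min_identity:
            continue
        segments.append(AlignmentSegment(read_id, rs, re_, tname, ts, te,
                                         "+" if is_plus else "-", n_match, block_len))

    # same-target overlap resolution: best segments win (callers wanting
    # every chain, e.g. read-overlap detection, disable this)
    segments.sort(key=lambda s: (-s.n_match, s.read_start))
    if resolve_same_target:
        kept: list[AlignmentSegment] = []
        for s in segments:
            ok = True
            for t in kept:
                if t.target_id != s.target_id:
                    continue
                ov = min(s.read_end, t.read_end) - max(s.read_start, t.read_start)
                if ov > 0.5 * min(s.read_end - s.read_start, t.read_end - t.read_start):
                    ok = False
                    break
            if ok:
                kept.append(s)
        segments = kept
    segments.sort(key=lambda s: (s.read_start, s.read_end, s.target_id))
    return segments


def extend_gapped(a: str, b: str, match: int = 2, mismatch: int = -3,
                  gap: int = -4, band: int = 16) -> int:
    """Best-scoring gapped extension of ``a`` vs ``b`` from their starts.

    Banded Needleman-style extension with free end; returns how far along
    ``b`` the maximum-score cell reaches.  Complements the fast ungapped
    X-drop used during segment building: applied at a segment end it
    recovers the bases that end erodes at read indels.
    """
    n, m = len(a), len(b)
    neg = -(10 ** 9)
    prev = [0] + [gap * j for j in range(1, m + 1)]
    best, best_j = 0, 0
    for i in range(1, n + 1):
        cur = [gap * i] + [neg] * m
        lo, hi = max(1, i - band), min(m, i + band)
        ca = a[i - 1]
        for j in range(lo, hi + 1):
            s = prev[j - 1] + (match if ca == b[j - 1] else mismatch)
            t = prev[j] + gap
            u = cur[j - 1] + gap
            v = s if s >= t else t
            if u > v:
                v = u
            cur[j] = v
            if v > best:
                best, best_j = v, j
        prev = cur
    return best_j


def refine_target_span(seg: AlignmentSegment, read_seq: str, tseq: str,
                       window: int = 100) -> tuple[int, int]:
    """Target interval after gapped extension of both segment ends.

    Never shrinks the interval; used where span accuracy matters (e.g. the
    marker-coverage counting rule).
    """
    rs, re_, ts, te = seg.read_start, seg.read_end, seg.target_start, seg.target_end
    rc = str.maketrans("ACGTN", "TGCAN")
    if seg.strand == "+":
        te += extend_gapped(read_seq[re_:re_ + window], tseq[te:te + window + 20])
        ts -= extend_gapped(read_seq[max(0, rs - window):rs][::-1],
                            tseq[max(0, ts - window - 20):ts][::-1])
    else:
        te += extend_gapped(read_seq[max(0, rs - window):rs][::-1].translate(rc),
                            tseq[te:te + window + 20])
        ts -= extend_gapped(read_seq[re_:re_ + window].translate(rc),
                            tseq[max(0, ts - window - 20):ts][::-1])
    return ts, te


def align_reads(reads: Iterable, index: SeedIndex, **kwargs) -> dict[str, list[AlignmentSegment]]:
    """Align many reads; accepts (id, seq) pairs or objects with .read_id/.sequence."""
    out: dict[str, list[AlignmentSegment]] = {}
    for r in reads:
        rid, seq = (r.read_id, r.sequence) if hasattr(r, "read_id") else r
        out[rid] = align_read(seq, index, read_id=rid, **kwargs)
    return out


# ---------------------------------------------------------------------------
# PAF interchange

def read_paf(stream: TextIO) -> list[AlignmentSegment]:
    """Parse minimap2-style PAF (12+ tab-separated fields) into segments.

    Malformed lines are skipped with a logged warning; if every non-empty
    line is malformed the stream is rejected.
    """
    segments: list[AlignmentSegment] = []
    n_lines = n_bad = 0
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        n_lines += 1
        f = line.split("\t")
        try:
            if len(f) < 12 or f[4] not in "+-":
                raise ValueError("need 12+ fields and a +/- strand")
            segments.append(AlignmentSegment(
                read_id=f[0], read_start=int(f[2]), read_end=int(f[3]),
                target_id=f[5], target_start=int(f[7]), target_end=int(f[8]),
                strand=f[4], n_match=int(f[9]), block_len=int(f[10])))
        except (ValueError, IndexError) as e:
            n_bad += 1
            logger.warning("skipping malformed PAF line %d: %s", lineno, e)
    if n_lines and n_bad == n_lines:
        raise ValueError("no parseable PAF lines in stream")
    return segments


def write_paf(segments: Iterable[AlignmentSegment], stream: TextIO,
              read_lengths: Optional[dict[str, int]] = None,
              target_lengths: Optional[dict[str, int]] = None) -> None:
    """Write segments as 12-column PAF (lengths fall back to interval ends)."""
    for s in segments:
        qlen = (read_lengths or {}).get(s.read_id, s.read_end)
        tlen = (target_lengths or {}).get(s.target_id, s.target_end)
        stream.write("\t".join(map(str, [
            s.read_id, qlen, s.read_start, s.read_end, s.strand,
            s.target_id, tlen, s.target_start, s.target_end,
            s.n_match, s.block_len, 60])) + "\n")
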