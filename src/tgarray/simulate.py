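"""Synthetic transgene locus and noisy long-read simulator with ground truth.

The generator reproduces the architecture typical of pronuclear-injection
transgenics: a host contig into which a tandem array of construct copies has
integrated, deleting a short stretch of host sequence at the insertion point.
Some array copies may be inverted, and a segment of foreign (cloning-host)
DNA may be co-integrated between copies.  Every simulated locus and read
carries a full truth record so downstream callers can be scored exactly.

Reads follow a log-normal length law (heavy right tail, as in nanopore runs)
with i.i.d. per-base substitution/insertion/deletion errors.  All randomness
flows from a single integer seed through one ``numpy`` generator.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from tgarray.seqs import BASES, decode, encode, random_seq, revcomp


@dataclass(frozen=True)
class TransgeneUnit:
    """One monomer of the tandem array.

    ``marker_interval`` locates the screened marker subsequence (the EGFP-like
    reporter CDS) within the unit, 0-based half-open.
    """

    sequence: str
    marker_interval: tuple[int, int]

    def __post_init__(self) -> None:
        s, e = self.marker_interval
        if not (0 <= s < e <= len(self.sequence)):
            raise ValueError(f"marker interval {self.marker_interval} outside unit [0, {len(self.sequence)})")
        if len(self.sequence) < 3 * (e - s):
            raise ValueError("unit must be at least 3x the marker length")

    @property
    def unit_length(self) -> int:
        return len(self.sequence)

    @property
    def marker_sequence(self) -> str:
        s, e = self.marker_interval
        return self.sequence[s:e]


@dataclass
class ReadTruth:
    """True provenance of one simulated read."""

    read_id: str
    haplotype: int
    start: int  # 0-based on the source haplotype
    end: int
    strand: str  # '+' or '-'


@dataclass
class TruthRecord:
    """Ground truth of a simulated integrated locus.

    Boundary convention (shared with the structure module): ``left_boundary``
    is the 1-based coordinate of the last retained host base left of the
    array, ``right_boundary`` the 1-based coordinate of the first retained
    host base to its right, so ``deletion_len == right - left - 1``.
    """

    integration_chrom: str
    left_boundary: int
    right_boundary: int
    deletion_len: int
    copy_number: int
    inverted_copy_indices: set[int]
    contaminant_interval: Optional[tuple[int, int]]  # (bp offset within array, length)
    unit_length: int
    host_length: int
    contaminant_length: int = 0
    per_read_truth: list[ReadTruth] = field(default_factory=list)

    @property
    def haplotype_length(self) -> int:
        return (self.host_length - self.deletion_len
                + self.copy_number * self.unit_length + self.contaminant_length)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inverted_copy_indices"] = sorted(self.inverted_copy_indices)
        return d


@dataclass(frozen=True)
class ReadSimParams:
    """Read-simulation knobs.

    Defaults give nanopore-like noise (~11% total error) and a length law
    whose implied N50 is ~3 kb — the desk-scale analogue of ultra-long runs;
    at full scale set ``length_log_mean`` for N50 ≈ 28 kb.  For a log-normal
    law the base-weighted (length-biased) median, i.e. the expected N50, is
    exp(mu + sigma^2).
    """

    coverage_target: float = 2.0
    length_log_mean: float = math.log(3000) - 0.5 ** 2
    length_log_sd: float = 0.5
    sub_rate: float = 0.05
    ins_rate: float = 0.025
    del_rate: float = 0.035
    min_read_len: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.2:
                raise ValueError(f"{name}={r} outside [0, 0.2]")
        if self.coverage_target <= 0:
            raise ValueError("coverage_target must be > 0")

    @property
    def implied_n50(self) -> float:
        return math.exp(self.length_log_mean + self.length_log_sd ** 2)


def lognormal_params_for_n50(n50: float, sigma: float = 0.5) -> tuple[float, float]:
    """(mu, sigma) of a log-normal length law whose expected N50 is ``n50``."""
    return math.log(n50) - sigma ** 2, sigma


@dataclass
class SimRead:
    read_id: str
    sequence: str
    quality: str


def make_locus(
    seed: int,
    host_len: int,
    unit: TransgeneUnit,
    copy_number: int,
    inverted_copy_indices: Sequence[int] = (),
    deletion_len: int = 0,
    integration_pos: Optional[int] = None,
    contaminant: Optional[tuple[str, int]] = None,
    chrom: str = "hostseq",
) -> tuple[str, str, TruthRecord]:
    """Build a random host contig and the integrated haplotype.

    ``integration_pos`` is the 1-based host coordinate of the last retained
    base before the array (defaults to the host midpoint).  ``contaminant``
    is an optional ``(sequence, offset)`` pair, the offset in bp from the
    array start at which the foreign segment is spliced in (it must fall on
    a copy boundary or inside the array span).

    Returns ``(host_sequence, integrated_haplotype, TruthRecord)``.
    """
    if copy_number < 1:
        raise ValueError("copy_number must be >= 1")
    if unit.unit_length == 0:
        raise ValueError("empty transgene unit")
    if deletion_len < 0:
        raise ValueError("deletion_len must be >= 0")
    inv = set(int(i) for i in inverted_copy_indices)
    if inv and not inv <= set(range(copy_number)):
        raise ValueError(f"inverted copy indices {sorted(inv)} outside [0, {copy_number})")
    if integration_pos is None:
        integration_pos = host_len // 2
    if not (0 < integration_pos and integration_pos + deletion_len <= host_len):
        raise ValueError(
            f"integration_pos={integration_pos} + deletion_len={deletion_len} "
            f"exceeds host length {host_len}")

    rng = np.random.default_rng(seed)
    host = random_seq(rng, host_len)

    copies = [revcomp(unit.sequence) if i in inv else unit.sequence
              for i in range(copy_number)]
    array = "".join(copies)
    cont_iv = None
    cont_len = 0
    if contaminant is not None:
        cont_seq, offset = contaminant
        if not (0 <= offset <= len(array)):
            raise ValueError(f"contaminant offset {offset} outside array [0, {len(array)}]")
        array = array[:offset] + cont_seq + array[offset:]
        cont_iv = (offset, len(cont_seq))
        cont_len = len(cont_seq)

    # keep the junctions identifiable: if the array's terminal base equals
    # the adjacent host base it replaces, the exact breakpoint is ambiguous
    # (junction micro-homology) and no caller could recover it uniquely —
    # adjust one base so the simulated truth is well defined
    bases = "ACGT"
    if integration_pos < host_len and array[0] == host[integration_pos]:
        array = bases[(bases.index(host[integration_pos]) + 1) % 4] + array[1:]
    prev_idx = integration_pos + deletion_len - 1
    if prev_idx >= 0 and array[-1] == host[prev_idx]:
        array = array[:-1] + bases[(bases.index(host[prev_idx]) + 1) % 4]

    haplotype = host[:integration_pos] + array + host[integration_pos + deletion_len:]
    truth = TruthRecord(
        integration_chrom=chrom,
        left_boundary=integration_pos,
        right_boundary=integration_pos + deletion_len + 1,
        deletion_len=deletion_len,
        copy_number=copy_number,
        inverted_copy_indices=inv,
        contaminant_interval=cont_iv,
        unit_length=unit.unit_length,
        host_length=host_len,
        contaminant_length=cont_len,
    )
    assert len(haplotype) == truth.haplotype_length
    return host, haplotype, truth


def random_unit(rng: np.random.Generator, unit_len: int = 3000,
                marker_len: int = 720, marker_offset: int = 1000) -> TransgeneUnit:
    """A random transgene monomer with an embedded marker interval."""
    return TransgeneUnit(random_seq(rng, unit_len), (marker_offset, marker_offset + marker_len))


def _mutate(seq_codes: np.ndarray, rng: np.random.Generator,
            sub: float, ins: float, del_: float) -> np.ndarray:
    """Apply i.i.d. per-base errors to a 2-bit-coded sequence."""
    n = seq_codes.size
    if n == 0 or (sub == 0 and ins == 0 and del_ == 0):
        return seq_codes
    u = rng.random(n)
    keep = u >= del_
    do_sub = (u >= del_) & (u < del_ + sub)
    out = seq_codes.copy()
    # substitution: shift by 1-3 mod 4 guarantees a different base
    shifts = rng.integers(1, 4, size=int(do_sub.sum()), dtype=np.uint8)
    out[do_sub] = (out[do_sub] + shifts) % 4
    out = out[keep]
    # insertions after surviving bases
    do_ins = rng.random(out.size) < ins
    n_ins = int(do_ins.sum())
    if n_ins:
        ins_bases = rng.integers(0, 4, size=n_ins, dtype=np.uint8)
        pos = np.flatnonzero(do_ins) + 1
        out = np.insert(out, pos, ins_bases)
    return out


def simulate_reads(
    haplotypes: Sequence[tuple[str, float]],
    params: ReadSimParams,
) -> tuple[list[SimRead], list[ReadTruth]]:
    """Sample noisy reads from weighted haplotypes until the coverage target.

    Read start positions are uniform, strands equiprobable, lengths log-normal
    (truncated to the haplotype).  The final read is clamped so that total
    sampled bases land within 5% of ``coverage_target x total length``.
    Deterministic for a fixed ``params.seed``.
    """
    if not haplotypes:
        raise ValueError("at least one haplotype required")
    seqs = [s for s, _ in haplotypes]
    if any(len(s) == 0 for s in seqs):
        raise ValueError("zero-length haplotype")
    weights = np.array([w for _, w in haplotypes], dtype=float)
    weights /= weights.sum()
    codes = [encode(s) for s in seqs]
    rc_codes = [(3 - c[::-1]) % 4 for c in codes]  # valid: simulator emits ACGT only

    rng = np.random.default_rng(params.seed)
    total_target = params.coverage_target * sum(len(s) for s in seqs)
    total_err = params.sub_rate + params.ins_rate + params.del_rate
    q = 40 if total_err == 0 else max(2, min(40, round(-10 * math.log10(total_err))))
    qchar = chr(q + 33)

    reads: list[SimRead] = []
    truths: list[ReadTruth] = []
    total = 0
    i = 0
    while total < total_target:
        hap = int(rng.choice(len(seqs), p=weights))
        L = len(seqs[hap])
        rl = int(rng.lognormal(params.length_log_mean, params.length_log_sd))
        rl = max(params.min_read_len, min(rl, L))
        remaining = total_target - total
        if remaining < rl:  # clamp the last read so total lands near target
            rl = min(L, max(params.min_read_len, int(remaining)))
        # fragments may overhang the molecule ends (clipped), which keeps the
        # expected coverage exactly uniform at total_bases / haplotype length
        s0 = int(rng.integers(-(rl - 1), L))
        start, end = max(0, s0), min(L, s0 + rl)
        if end - start < max(50, params.min_read_len // 4):
            continue
        rl = end - start
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            frag = codes[hap][start:start + rl]
        else:
            frag = rc_codes[hap][L - (start + rl):L - start]
        frag = _mutate(frag, rng, params.sub_rate, params.ins_rate, params.del_rate)
        rid = f"read{i:06d}"
        reads.append(SimRead(rid, decode(frag), qchar * frag.size))
        truths.append(ReadTruth(rid, hap, start, start + rl, strand))
        total += frag.size
        i += 1
    return reads, truths


# ---------------------------------------------------------------------------
# writers

def write_fasta(path, records: Sequence[tuple[str, str]]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    SeqIO.write((SeqRecord(Seq(s), id=n, description="") for n, s in records), str(path), "fasta")


def write_fastq(path, reads: Sequence[SimRead]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def write_truth(path_json, truth: TruthRecord, path_bed=None) -> None:
    with open(path_json, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    if path_bed is not None:
        # BED is 0-based half-open: the interval of host sequence replaced by
        # the array is [left_boundary, right_boundary - 1)
        with open(path_bed, "w") as fh:
            fh.write(f"{truth.integration_chrom}\t{truth.left_boundary}\t"
                     f"{truth.right_boundary - 1}\tintegration\n")
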