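"""Junction calling, inversions, contaminant, and the tiling lower bound."""

import io

import numpy as np
import pytest

from tgarray.align import AlignmentSegment, TargetRegistry
from tgarray.simulate import random_seq
from tgarray.structure import (call_junctions, deletion_length,
                               detect_contaminant, detect_inversions,
                               minimal_tiling_path, primer_windows,
                               read_landmarks, write_breakpoints_vcf)

from conftest import CONT_OFFSET, CONT_LEN, COPIES, UNIT_LEN


def _seg(read_id, rs, re, target, ts, te, strand="+"):
    return AlignmentSegment(read_id, rs, re, target, ts, te, strand,
                            n_match=re - rs, block_len=re - rs)


class TestDeletionLength:
    def test_reported_boundaries_give_686bp_deletion(self):
        """The retained flanks at Chr9:124,115,870 / 124,116,557 delete 686 bp."""
        assert deletion_length(124_115_870, 124_116_557) == 686

    @pytest.mark.parametrize("left,right,expected", [(100, 101, 0), (100, 102, 1)])
    def test_adjacent_and_near_adjacent(self, left, right, expected):
        assert deletion_length(left, right) == expected

    def test_inverted_boundaries_rejected(self):
        with pytest.raises(ValueError):
            deletion_length(200, 200)
        with pytest.raises(ValueError):
            deletion_length(200, 100)


def best_call(calls):
    paired = [c for c in calls if c.deletion_len is not None]
    if not paired:
        return None
    return max(paired, key=lambda c: len(c.support_left) + len(c.support_right))


class TestCallJunctions:
    def test_error_free_simulation_recovers_truth_exactly(
            self, locus, clean_reads, clean_segments, registry):
        _, _, truth, _ = locus
        reads, _ = clean_reads
        seqs = {r.read_id: r.sequence for r in reads}
        call = best_call(call_junctions(clean_segments, registry, read_seqs=seqs))
        assert call is not None
        assert call.chrom == truth.integration_chrom
        assert call.left_boundary == truth.left_boundary
        assert call.right_boundary == truth.right_boundary
        assert call.deletion_len == truth.deletion_len
        assert call.support_left and call.support_right

    def test_host_only_reads_give_no_calls(self, registry):
        segs = {"r": [_seg("r", 0, 500, "hostseq", 100, 600),
                      _seg("r", 500, 900, "hostseq", 700, 1100)]}
        assert call_junctions(segs, registry) == []

    def test_left_boundary_orientation_reported_on_genome_scale(self, registry):
        # read sampled on '-' strand: transgene before host on the read,
        # host segment '-' with its low target end facing the junction
        segs = {"r": [_seg("r", 0, 500, "transgene", 0, 500, "-"),
                      _seg("r", 505, 1000, "hostseq", 9000, 9495, "-")]}
        (call,) = call_junctions(segs, registry)
        assert call.left_boundary == 9495
        assert call.left_adjacent_strand == "+"  # same flip as the host segment


class TestInversions:
    def test_uniform_strand_chain_has_no_events(self, registry):
        segs = {"r": [_seg("r", 0, 300, "transgene", 0, 300),
                      _seg("r", 300, 600, "transgene", 300, 600),
                      _seg("r", 600, 900, "transgene", 600, 900)]}
        assert detect_inversions(segs, registry) == []

    def test_single_flip_yields_one_event(self, registry):
        segs = {"r": [_seg("r", 0, 300, "transgene", 0, 300, "+"),
                      _seg("r", 320, 600, "transgene", 0, 280, "-")]}
        (ev,) = detect_inversions(segs, registry)
        assert ev.flip == "+-" and ev.read_position == 310

    def test_simulated_inverted_copy_found_in_spanning_reads(
            self, locus, clean_reads, clean_segments, registry):
        """Every error-free read spanning a flip shows the event within 100 bp."""
        _, _, truth, _ = locus
        reads, read_truth = clean_reads
        inv = sorted(truth.inverted_copy_indices)[0]
        arr0 = truth.left_boundary
        # copy boundaries flanking the inverted copy, in haplotype coordinates
        flip_pos = []
        for edge in (inv, inv + 1):
            off = edge * UNIT_LEN + (CONT_LEN if edge * UNIT_LEN > CONT_OFFSET else 0)
            flip_pos.append(arr0 + off)
        events = detect_inversions(clean_segments, registry)
        ev_by_read = {}
        for e in events:
            ev_by_read.setdefault(e.read_id, []).append(e.read_position)
        margin = 400  # segments this short are below the reporting threshold
        for t in read_truth:
            for fp in flip_pos:
                if t.start + margin <= fp <= t.end - margin:
                    got = ev_by_read.get(t.read_id, [])
                    if t.strand == "+":
                        expected = fp - t.start
                    else:
                        expected = t.end - fp
                    assert any(abs(g - expected) <= 100 for g in got), \
                        f"{t.read_id} misses flip at {fp}"


class TestContaminant:
    def test_fully_spanned_insert_is_bounded_with_exact_length(self, registry):
        clen = CONT_LEN
        segs = {"r": [
            _seg("r", 0, 500, "transgene", 2500, 3000),
            _seg("r", 500, 500 + clen, "contaminant", 0, clen),
            _seg("r", 500 + clen, 1000 + clen, "transgene", 0, 500),
        ]}
        (call,) = detect_contaminant(segs, registry)
        assert call.observed_length == clen
        assert call.bounded_by_reads

    def test_read_terminating_inside_gives_lower_bound(self, registry):
        segs = {"r": [_seg("r", 0, 600, "transgene", 2400, 3000),
                      _seg("r", 600, 1400, "contaminant", 0, 800)]}
        (call,) = detect_contaminant(segs, registry)
        assert call.observed_length == 800
        assert not call.bounded_by_reads

    def test_no_contaminant_segments_empty(self, registry):
        assert detect_contaminant({"r": []}, registry) == []

    def test_registry_without_contaminant_target_rejected(self, unit):
        reg = TargetRegistry.build("ACGT" * 300, unit)
        with pytest.raises(ValueError):
            detect_contaminant({}, reg)


def _tiling_oracle(read_positions, marker_positions, marker_len, min_overlap):
    """Exhaustive oracle for <=10 reads with known true placements: smallest
    chain of pairwise-overlapping reads maximizing covered full copies."""
    import itertools
    ids = list(read_positions)
    best = (0, 0)  # (copies, -path_len)
    for r in range(1, len(ids) + 1):
        for sub in itertools.combinations(ids, r):
            ivs = sorted(read_positions[i] for i in sub)
            ok = all(ivs[i][1] - ivs[i + 1][0] >= min_overlap
                     for i in range(len(ivs) - 1))
            if not ok:
                continue
            copies = sum(
                1 for m in marker_positions
                if any(s <= m and m + marker_len <= e for s, e in ivs))
            if copies > best[0] or (copies == best[0] and -r > best[1]):
                best = (copies, -r)
    return best[0], -best[1]


class TestTilingPath:
    def _array_reads(self, unit, host):
        """Three reads tiling host-left + 5-copy array + host-right with
        ~1 kb overlaps; copy 2 inverted so every overlap holds a landmark."""
        from tgarray.seqs import revcomp
        copies = [unit.sequence] * 5
        copies[2] = revcomp(unit.sequence)
        arr = "".join(copies)
        hap = host[:5000] + arr + host[5000:]
        # strand flips sit at haplotype 11000 and 14000; every consecutive
        # overlap contains one, so placement is unambiguous
        reads = {
            "a": hap[1000:12000],   # host | copies 0-1 | into inverted copy 2
            "b": hap[10000:17500],  # spans both flips, copies 2-3
            "c": hap[13000:23000],  # copies 3-4 | host
        }
        positions = {"a": (1000, 12000), "b": (10000, 17500), "c": (13000, 23000)}
        return hap, reads, positions

    def test_three_reads_tile_five_copies(self, unit):
        rng = np.random.default_rng(33)
        host = random_seq(rng, 10000)
        hap, reads, positions = self._array_reads(unit, host)
        reg = TargetRegistry.build(host, unit)
        from tgarray.align import align_reads, index_targets
        idx = index_targets(reg, k=15)
        segs = align_reads(reads.items(), idx)
        marker_hits = {r: [(s.read_start, s.read_end) for s in ss
                           if s.target_id == "marker"]
                       for r, ss in segs.items()}
        lm = read_landmarks(segs, reg)
        tp = minimal_tiling_path(reads, marker_hits, anchor_read="a",
                                 landmarks=lm, min_overlap=1000)
        marker_abs = [5000 + i * UNIT_LEN +
                      (unit.marker_interval[0] if i != 2
                       else UNIT_LEN - unit.marker_interval[1])
                      for i in range(5)]
        oracle_copies, oracle_len = _tiling_oracle(
            positions, marker_abs, unit.marker_interval[1] - unit.marker_interval[0],
            1000)
        assert oracle_copies == 5 and oracle_len == 3
        assert tp.lower_bound_copies == 5
        assert len(tp.read_ids) == 3

    def test_single_read_bound_without_overlaps(self, unit):
        read = unit.sequence * 2
        marker_hits = {"solo": [(1000, 1720), (4000, 4720)]}
        tp = minimal_tiling_path({"solo": read}, marker_hits, min_overlap=1000)
        assert tp.lower_bound_copies == 2
        assert tp.read_ids == ["solo"]

    def test_no_marker_reads_rejected(self):
        with pytest.raises(ValueError):
            minimal_tiling_path({"r": "ACGT" * 100}, {"r": []})

    def test_bound_sound_and_tight_on_fixture(
            self, locus, clean_reads, clean_segments, registry):
        _, _, truth, _ = locus
        reads, _ = clean_reads
        seqs = {r.read_id: r.sequence for r in reads}
        from tgarray.screen import classify_reads
        cls = classify_reads(clean_segments, registry, read_seqs=seqs)
        mh = {c.read_id: [(s.read_start, s.read_end)
                          for s in clean_segments[c.read_id]
                          if s.target_id == "marker"]
              for c in cls if c.marker_match_count}
        calls = call_junctions(clean_segments, registry, read_seqs=seqs)
        anchor = next((rid for c in calls
                       for rid in c.support_left + c.support_right
                       if mh.get(rid)), None)
        lm = read_landmarks(clean_segments, registry)
        tp = minimal_tiling_path({r: seqs[r] for r in mh}, mh,
                                 anchor_read=anchor, landmarks=lm)
        assert tp.lower_bound_copies <= truth.copy_number
        assert tp.lower_bound_copies == truth.copy_number  # fully tiled, error-free
        assert max(tp.per_read_marker_counts.values()) <= tp.lower_bound_copies


class TestReporting:
    def test_primer_windows_flank_both_boundaries(self, registry):
        from tgarray.structure import IntegrationCall
        call = IntegrationCall("hostseq", 25000, 25687, 686)
        (l, r) = primer_windows(call, host_len=30000, window=500)
        assert l == ("hostseq", 24500, 25000, "left_flank")
        assert r == ("hostseq", 25686, 26186, "right_flank")

    def test_vcf_has_two_boundary_records_per_call(self):
        from tgarray.structure import IntegrationCall
        buf = io.StringIO()
        write_breakpoints_vcf([IntegrationCall("chr9", 124115870, 124116557, 686)], buf)
        lines = [l for l in buf.getvalue().splitlines() if not l.startswith("#")]
        assert len(lines) == 2
        assert "SVLEN=-686" in lines[0]
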