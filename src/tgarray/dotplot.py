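"""Windowed nucleotide dot plots and diagonal-run segmentation.

A dot is recorded at (x, y) when the length-``window`` subsequence of X
starting at x equals the corresponding window of Y (forward orientation) or
its reverse complement (reverse orientation).  Tandem copies appear as
parallel diagonals, inversions as orientation flips between runs.  Defaults
(window 15, step 1, exact match) follow common practice for visualizing
transgene array structure.
"""

from __future__ import annotations

from dataclasses import dataclass

from tgarray.seqs import revcomp

FORWARD = "forward"
REVERSE = "reverse"


@dataclass
class DotMatches:
    window: int
    step: int
    matches: list[tuple[int, int, str]]  # (x, y, orientation)

    def by_orientation(self, orientation: str) -> list[tuple[int, int]]:
        return [(x, y) for x, y, o in self.matches if o == orientation]


def _hamming_le(a: str, b: str, limit: int) -> bool:
    d = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            d += 1
            if d > limit:
                return False
    return True


def dot_matches(seq_x: str, seq_y: str, window: int = 15, step: int = 1,
                max_mismatch: int = 0) -> DotMatches:
    """All window matches of X vs Y in both orientations.

    Exact matching (``max_mismatch=0``) is hashed, O(len X + len Y) expected;
    fuzzy matching falls back to an all-pairs scan and is intended for short
    sequences only.
    """
    seq_x, seq_y = seq_x.upper(), seq_y.upper()
    if window > len(seq_x) or window > len(seq_y):
        raise ValueError(f"window {window} exceeds a sequence length")
    xs = range(0, len(seq_x) - window + 1, step)
    ys = range(0, len(seq_y) - window + 1, step)
    matches: list[tuple[int, int, str]] = []
    if max_mismatch == 0:
        fwd: dict[str, list[int]] = {}
        rev: dict[str, list[int]] = {}
        for y in ys:
            w = seq_y[y:y + window]
            fwd.setdefault(w, []).append(y)
            rev.setdefault(revcomp(w), []).append(y)
        for x in xs:
            w = seq_x[x:x + window]
            for y in fwd.get(w, ()):
                matches.append((x, y, FORWARD))
            for y in rev.get(w, ()):
                matches.append((x, y, REVERSE))
    else:
        for x in xs:
            wx = seq_x[x:x + window]
            for y in ys:
                wy = seq_y[y:y + window]
                if _hamming_le(wx, wy, max_mismatch):
                    matches.append((x, y, FORWARD))
                if _hamming_le(wx, revcomp(wy), max_mismatch):
                    matches.append((x, y, REVERSE))
    matches.sort()
    return DotMatches(window, step, matches)


@dataclass
class DiagonalRun:
    orientation: str
    start: tuple[int, int]
    end: tuple[int, int]
    length: int  # number of matches in the run


def segment_diagonals(matches: DotMatches, min_run: int = 1) -> list[DiagonalRun]:
    """Maximal constant-orientation runs advancing by (step, +/-step).

    Forward runs advance (step, step); reverse runs (step, -step).  Runs
    shorter than ``min_run`` matches are dropped; output sorted by x.
    """
    step = matches.step
    runs: list[DiagonalRun] = []
    for orientation, sign in ((FORWARD, 1), (REVERSE, -1)):
        pts = matches.by_orientation(orientation)
        # group by diagonal invariant: y - x (forward) or y + x (reverse)
        groups: dict[int, list[tuple[int, int]]] = {}
        for x, y in pts:
            groups.setdefault(y - sign * x, []).append((x, y))
        for pts_d in groups.values():
            pts_d.sort()
            start = prev = pts_d[0]
            n = 1
            for p in pts_d[1:]:
                if p[0] - prev[0] == step and p[1] - prev[1] == sign * step:
                    n += 1
                else:
                    if n >= min_run:
                        runs.append(DiagonalRun(orientation, start, prev, n))
                    start, n = p, 1
                prev = p
            if n >= min_run:
                runs.append(DiagonalRun(orientation, start, prev, n))
    runs.sort(key=lambda r: (r.start, r.orientation))
    return runs


def write_matches_tsv(matches: DotMatches, stream) -> None:
    stream.write("x\ty\torientation\n")
    for x, y, o in matches.matches:
        stream.write(f"{x}\t{y}\t{o}\n")


def plot(matches: DotMatches, path, xlabel: str = "sequence X",
         ylabel: str = "sequence Y") -> None:
    """Render matches as a dot plot (forward black, reverse red)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 6))
    for orientation, color in ((FORWARD, "k"), (REVERSE, "r")):
        pts = matches.by_orientation(orientation)
        if pts:
            ax.scatter(*zip(*pts), s=1, c=color, label=orientation, linewidths=0)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(markerscale=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
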