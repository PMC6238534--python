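"""Mapping fragment 3' ends to ribosomal P-site codons.

The protective footprint of a stalled ribosome places the RNase R cleavage
site a fixed distance downstream of the P-site codon, so the fragment-end
distribution carries a tri-nucleotide periodicity and the cleavage offset
can be calibrated from reads in which the ribosome paused with a UAG stop
codon in the A-site (the one stop the NNS design can produce).

Offset convention (shared with the simulator): distance from the last
nucleotide of the P-site codon to the protected 3' end, inclusive, so a
jitter-free fragment from a ribosome at codon *p* ends at ``3*p + offset``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .process import ProcessedRead


@dataclass
class EndDistribution:
    """Histogram of fragment 3'-end positions and the mod-3 phase split."""

    histogram: dict[int, int]
    phase_fractions: tuple[float, float, float]

    @property
    def n_reads(self) -> int:
        return sum(self.histogram.values())

    def dominant_phase(self) -> int:
        return max(range(3), key=lambda k: self.phase_fractions[k])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("end_pos\tcount\n")
            for pos in sorted(self.histogram):
                fh.write(f"{pos}\t{self.histogram[pos]}\n")


@dataclass
class OffsetEstimate:
    """Modal cleavage offset with its per-candidate support table."""

    offset: int
    support: dict[int, int]
    n_reads_used: int

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("candidate_offset\tcount\n")
            for cand in sorted(self.support):
                fh.write(f"{cand}\t{self.support[cand]}\n")


def end_distribution(reads: Iterable[ProcessedRead | int]) -> EndDistribution:
    """Exact fragment-end histogram plus the end_pos mod 3 phase fractions."""
    hist: Counter[int] = Counter()
    for r in reads:
        hist[r if isinstance(r, int) else r.end_pos] += 1
    total = sum(hist.values())
    if total == 0:
        raise ValueError("end_distribution requires at least one read")
    phases = [0, 0, 0]
    for pos, n in hist.items():
        phases[pos % 3] += n
    return EndDistribution(dict(hist), tuple(p / total for p in phases))


def estimate_offset(
    reads: Iterable[ProcessedRead],
    *,
    min_codon: int = 3,
) -> OffsetEstimate:
    """Estimate the cleavage offset from in-frame UAG codons.

    For every read and every in-frame TAG at codon q ≥ ``min_codon`` (so the
    X1 residue of the motif frame exists), the candidate offset is
    ``end_pos − 3·(q−1)``: the distance from the last nucleotide of the
    putative P-site codon q−1 to the fragment end.  The estimate is the
    modal candidate; ties break toward the larger offset, since cleavage
    jitter only shortens fragments.
    """
    support: Counter[int] = Counter()
    n_used = 0
    for pr in reads:
        seq = pr.nt_sequence
        end = pr.end_pos
        found = False
        q = min_codon
        while 3 * q <= end:
            if seq[3 * q - 3 : 3 * q] == "TAG":
                cand = end - 3 * (q - 1)
                if cand >= 0:
                    support[cand] += 1
                    found = True
            q += 1
        if found:
            n_used += 1
    if not support:
        raise ValueError(
            "no reads with in-frame UAG codons; use a fixed offset instead"
        )
    best = max(support.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return OffsetEstimate(best, dict(support), n_used)


def assign_psite(read: ProcessedRead | int, offset: int) -> int | None:
    """P-site codon index for a fragment end, or None if unassignable.

    Uses ``p = ceil((end_pos − offset) / 3)``: the ceiling absorbs the −1/−2
    cleavage jitter so all three jittered ends of one stall event map to the
    same codon.  Returns None when p < 1 (fragment too short — initiation-
    complex territory is p = 1, which callers exclude from motif counting).
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    end = read if isinstance(read, int) else read.end_pos
    d = end - offset
    p = -(-d // 3)  # ceil for ints
    if p < 1:
        return None
    return p
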