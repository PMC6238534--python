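"""Trimming and filtering of merged inverse-toeprinting reads.

A raw merged read is flank5 + protected fragment + 3' linker.  Trimming
anchors the 5' flank as a prefix and the 3' flank as a suffix, each with a
tolerated Hamming distance (substitutions only — the flanks are fixed-length
constant sequences), leaving a fragment that starts at the A of the start
codon and ends at the RNase R cleavage position.

Filters then run in a fixed first-fail order so rejection bookkeeping is
deterministic: poly-A contamination, missing start codon, base quality
inside the region of interest, and finally the fragment-end window that
restricts analysis to the tri-nucleotide-periodic size range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._genetics import FLANK3_DEFAULT, FLANK5_DEFAULT
from .simulate import ConfigurationError

#: rejection reasons in evaluation order
REJECT_REASONS = (
    "flank5_mismatch",
    "flank3_mismatch",
    "polyA",
    "no_start",
    "low_quality",
    "outside_roi",
)

#: default quality / fragment-end window (nt from the start codon) for
#: samples selected from the NNS15 library
DEFAULT_ROI = (24, 47)


@dataclass
class ProcessedRead:
    """A trimmed read: sequence from the A of ATG to the cleavage position."""

    id: str
    nt_sequence: str
    qualities: str  # Phred+33, same length as nt_sequence

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.nt_sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")

    @property
    def end_pos(self) -> int:
        """1-based coordinate of the 3' end relative to the start codon."""
        return len(self.nt_sequence)

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qualities]


@dataclass
class FilterReport:
    """Per-reason rejection counts; reasons + passes sum to the input total."""

    counts: dict = field(default_factory=lambda: {r: 0 for r in REJECT_REASONS})
    n_pass: int = 0

    @property
    def n_total(self) -> int:
        return self.n_pass + sum(self.counts.values())

    def reject(self, reason: str) -> None:
        self.counts[reason] += 1

    def as_dict(self) -> dict:
        d = dict(self.counts)
        d["pass"] = self.n_pass
        d["total"] = self.n_total
        return d

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for k, v in self.as_dict().items():
                fh.write(f"{k}\t{v}\n")


def hamming_within(a: str, b: str, cap: int) -> bool:
    """True iff the Hamming distance between equal-length ``a``/``b`` ≤ cap."""
    if a == b:
        return True
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > cap:
                return False
    return True


def trim_flanks(
    read_id: str,
    seq: str,
    qual: str | None = None,
    *,
    flank5: str = FLANK5_DEFAULT,
    flank3: str = FLANK3_DEFAULT,
    max_mismatch: int = 2,
) -> tuple[ProcessedRead | None, str | None]:
    """Strip prefix-anchored flank5 and suffix-anchored flank3.

    Returns ``(processed_read, None)`` on success or ``(None, reason)``.
    An interior shorter than one codon rejects as a flank3 mismatch.
    """
    if not flank5 or not flank3:
        raise ConfigurationError("flanks must be non-empty")
    n5, n3 = len(flank5), len(flank3)
    if len(seq) < n5 + 3:
        return None, "flank5_mismatch"
    if not hamming_within(seq[:n5], flank5, max_mismatch):
        return None, "flank5_mismatch"
    if len(seq) < n5 + n3 + 3:
        return None, "flank3_mismatch"
    if not hamming_within(seq[-n3:], flank3, max_mismatch):
        return None, "flank3_mismatch"
    core = seq[n5 : len(seq) - n3]
    cq = qual[n5 : len(seq) - n3] if qual is not None else "V" * len(core)
    return ProcessedRead(read_id, core, cq), None


def filter_read(
    pr: ProcessedRead,
    *,
    quality_window: tuple[int, int] = DEFAULT_ROI,
    min_q: int = 30,
    polya_count: int = 18,
    polya_window: int = 22,
) -> str | None:
    """First-failing rejection reason, or None if the read passes.

    Order: (1) ≥ ``polya_count`` 'A' within the first ``polya_window`` nt;
    (2) the read does not begin with ATG; (3) any base inside
    ``quality_window ∩ [1, end_pos]`` below ``min_q``.
    """
    lo, hi = quality_window
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"invalid quality window {quality_window!r}")
    seq = pr.nt_sequence
    if seq[:polya_window].count("A") >= polya_count:
        return "polyA"
    if not seq.startswith("ATG"):
        return "no_start"
    hi = min(hi, pr.end_pos)
    if lo <= hi:
        window = pr.qualities[lo - 1 : hi]
        if window and min(window) < chr(min_q + 33):
            return "low_quality"
    return None


def select_roi(pr: ProcessedRead | int, window: tuple[int, int] = DEFAULT_ROI) -> bool:
    """True iff the fragment 3' end lies inside the inclusive window."""
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"invalid end window {window!r}")
    end = pr if isinstance(pr, int) else pr.end_pos
    return lo <= end <= hi


def process_reads(
    records: Iterable[tuple[str, str, str]],
    *,
    flank5: str = FLANK5_DEFAULT,
    flank3: str = FLANK3_DEFAULT,
    max_mismatch: int = 2,
    quality_window: tuple[int, int] = DEFAULT_ROI,
    min_q: int = 30,
    polya_count: int = 18,
    polya_window: int = 22,
    end_window: tuple[int, int] | None = DEFAULT_ROI,
    report: FilterReport | None = None,
) -> Iterator[ProcessedRead]:
    """Trim and filter a stream of raw (id, seq, qual) records.

    Yields passing :class:`ProcessedRead` objects lazily; if a ``report`` is
    supplied it is filled in as the stream is consumed.  ``end_window=None``
    disables the fragment-end selection (input-library and focused-library
    samples, whose reads are not size-restricted).
    """
    if report is None:
        report = FilterReport()
    for rid, seq, qual in records:
        pr, reason = trim_flanks(
            rid, seq, qual, flank5=flank5, flank3=flank3, max_mismatch=max_mismatch
        )
        if pr is None:
            report.reject(reason)
            continue
        reason = filter_read(
            pr,
            quality_window=quality_window,
            min_q=min_q,
            polya_count=polya_count,
            polya_window=polya_window,
        )
        if reason is not None:
            report.reject(reason)
            continue
        if end_window is not None and not select_roi(pr, end_window):
            report.reject("outside_roi")
            continue
        report.n_pass += 1
        yield pr


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream (id, seq, qual) tuples from a Phred+33 FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper(), qual


def read_processed_fastq(path) -> Iterator[ProcessedRead]:
    """Stream already-trimmed reads back as :class:`ProcessedRead`."""
    for rid, seq, qual in read_fastq(path):
        yield ProcessedRead(rid, seq, qual)


def process_fastq(
    in_path,
    out_path=None,
    **params,
) -> FilterReport:
    """Trim + filter a FASTQ file, optionally writing the trimmed FASTQ."""
    report = FilterReport()
    stream = process_reads(read_fastq(in_path), report=report, **params)
    if out_path is None:
        for _ in stream:
            pass
    else:
        with open(out_path, "w") as fh:
            for pr in stream:
                fh.write(f"@{pr.id}\n{pr.nt_sequence}\n+\n{pr.qualities}\n")
    return report
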