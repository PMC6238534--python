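"""Genetic-code tables and small sequence helpers shared across the package.

Codon → amino-acid maps are built from Biopython's standard bacterial table;
stops are mapped to ``'*'``.  The NNS degenerate alphabet (aNy/aNy/Strong,
i.e. third base G or C) encodes all 20 amino acids while excluding the UGA
and UAA stop codons by construction — UAG remains possible, which is what
makes stop-codon pausing usable as a cleavage-offset calibration signal.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon (DNA alphabet) -> one-letter amino acid, stops as '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

STOP_CODONS = frozenset(_STANDARD.stop_codons)  # {'TAA', 'TAG', 'TGA'}
STOP_SYMBOL = "*"

#: the 20 amino acids, alphabetical one-letter codes
AA20: tuple[str, ...] = tuple(sorted(set(_STANDARD.forward_table.values())))

#: the 32 NNS codons; note TAG is present, TGA/TAA are not
NNS_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "GC"
)

#: 5' flank upstream of the start codon (ribosome binding site region)
FLANK5_DEFAULT = "GTATAAGGAGGAAAAAAT"
#: 3' linker flank ligated downstream of the RNase R cleavage site
#: (NNS and ErmBL libraries)
FLANK3_DEFAULT = "GCGATCTCGGTGTGATG"
#: 3' linker flank used for the other (known arrest sequence) samples
FLANK3_ALT = "GGTATCTCGGTGTGACTG"


def codons_of(seq: str) -> list[str]:
    """In-frame codons of ``seq`` starting at position 1 (trailing partial
    codon discarded)."""
    n = len(seq) - len(seq) % 3
    return [seq[i : i + 3] for i in range(0, n, 3)]


def translate_nt(seq: str, n_codons: int | None = None) -> str:
    """Translate ``seq`` in frame from its first nucleotide.

    Stops render as ``'*'``; codons containing non-ACGT characters render as
    ``'X'``.  ``n_codons`` limits translation to the first *n* codons.
    """
    table = CODON_TO_AA
    stop = len(seq) - len(seq) % 3
    if n_codons is not None:
        stop = min(stop, 3 * n_codons)
    return "".join(table.get(seq[i : i + 3], "X") for i in range(0, stop, 3))
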