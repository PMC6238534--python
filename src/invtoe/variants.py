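"""Focused-library (arrest-peptide variant) analysis.

For a mutagenized library built around one wild-type arrest peptide, reads
are translated over a fixed window matching the wild-type length (indels
are out of model — the library is substitution-mutagenized), grouped into
peptide variants, and compared across conditions:

* per-variant enrichment of a selected sample over the input library,
* selection of variants that discriminate between two conditions (enriched
  in one but not the other, with enough combined reads to trust the call),
* per-(position, residue) over/under-representation between two read sets,
  a simple log-ratio statistic with a descriptive binomial p-value.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from ._genetics import AA20, STOP_SYMBOL, translate_nt
from .process import ProcessedRead

log = logging.getLogger(__name__)


def _peptide_windows(
    reads: Iterable[ProcessedRead | str], n_codons: int
) -> Iterable[tuple[str, str]]:
    """Yield (peptide, nucleotide window) pairs for reads covering the window."""
    width = 3 * n_codons
    for r in reads:
        seq = r if isinstance(r, str) else r.nt_sequence
        if len(seq) < width:
            yield None, None
            continue
        window = seq[:width]
        pep = translate_nt(window)
        if STOP_SYMBOL in pep or "X" in pep:
            yield None, None
            continue
        yield pep, window


def call_variants(
    reads_by_sample: Mapping[str, Iterable[ProcessedRead | str]],
    wt_peptide: str,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Group reads into peptide variants against a wild type.

    Reads are translated over the first ``len(wt_peptide)`` codons; reads
    too short for the window or containing a stop are excluded (counts per
    sample returned alongside).  The result has one row per distinct
    peptide with per-sample read counts, the substitution count ``n_mut``
    vs the wild type, and the number of distinct underlying nucleotide
    sequences ``n_nt_variants``.
    """
    W = len(wt_peptide)
    counts: dict[str, dict[str, int]] = {}
    nt_seqs: dict[str, set[str]] = {}
    excluded = {}
    samples = list(reads_by_sample)
    for sample in samples:
        dropped = 0
        for pep, window in _peptide_windows(reads_by_sample[sample], W):
            if pep is None:
                dropped += 1
                continue
            row = counts.setdefault(pep, dict.fromkeys(samples, 0))
            row[sample] += 1
            nt_seqs.setdefault(pep, set()).add(window)
        excluded[sample] = dropped
        if dropped:
            log.info("%s: %d reads excluded from variant calling", sample, dropped)

    peptides = sorted(counts)
    df = pd.DataFrame(
        [counts[p] for p in peptides], index=pd.Index(peptides, name="peptide")
    )
    df["n_mut"] = [
        sum(a != b for a, b in zip(p, wt_peptide)) for p in peptides
    ]
    df["n_nt_variants"] = [len(nt_seqs[p]) for p in peptides]
    order = df[samples].sum(axis=1).sort_values(ascending=False).index
    return df.loc[order], excluded


def variant_enrichment(
    variants: pd.DataFrame, selected: str, input_library: str
) -> pd.Series:
    """Per-variant fold change of a selected sample over the input library.

    FC = (count_sel / total_sel) / (count_in / total_in).  Variants absent
    from the input have undefined FC (NaN, flagged by the caller); variants
    absent from the selected sample get FC = 0.
    """
    tot_sel = variants[selected].sum()
    tot_in = variants[input_library].sum()
    if tot_sel == 0 or tot_in == 0:
        raise ValueError("zero-total sample in variant enrichment")
    f_sel = variants[selected] / tot_sel
    f_in = variants[input_library] / tot_in
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (f_sel / f_in).where(f_in > 0)
    return fc.rename(f"FC_{selected}")


def select_discriminating(
    fc_a: pd.Series,
    fc_b: pd.Series,
    combined_counts: pd.Series,
    *,
    min_combined: int = 150,
    fc_min: float = 2.0,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Variants enriched in exactly one of two conditions.

    Keeps variants with ``combined_counts ≥ min_combined`` whose fold
    change reaches ``fc_min`` in one condition XOR the other ("enriched in
    the presence of one antibiotic but not the other"), and reports which
    condition selects each.  Symmetric under swapping the conditions.
    """
    idx = fc_a.index.union(fc_b.index)
    a = fc_a.reindex(idx)
    b = fc_b.reindex(idx)
    n = combined_counts.reindex(idx, fill_value=0)
    hit_a = (a >= fc_min).fillna(False)
    hit_b = (b >= fc_min).fillna(False)
    keep = (n >= min_combined) & (hit_a ^ hit_b)
    out = pd.DataFrame(
        {
            f"FC_{label_a}": a[keep],
            f"FC_{label_b}": b[keep],
            "combined_reads": n[keep].astype(int),
            "selected_for": np.where(hit_a[keep], label_a, label_b),
        }
    )
    return out.sort_values("combined_reads", ascending=False)


def position_enrichment(
    fg_reads: Iterable[ProcessedRead | str],
    bg_reads: Iterable[ProcessedRead | str],
    length: int,
) -> pd.DataFrame:
    """Per-(position, residue) log2 frequency ratio between two read sets.

    Both read sets are translated over ``length`` codons; per position the
    residue frequencies of each set sum to 1.  The statistic is
    log2((f_fg + ε) / (f_bg + ε)) with ε = 1/(n_bg + 20), plus an
    uncorrected two-sided binomial p-value per cell — descriptive only.
    """

    def tally(reads):
        mats = np.zeros((length, len(AA20)), dtype=np.int64)
        aa_index = {a: i for i, a in enumerate(AA20)}
        n = 0
        for pep, _ in _peptide_windows(reads, length):
            if pep is None:
                continue
            n += 1
            for pos, aa in enumerate(pep):
                mats[pos, aa_index[aa]] += 1
        return mats, n

    fg_counts, n_fg = tally(fg_reads)
    bg_counts, n_bg = tally(bg_reads)
    if n_fg == 0 or n_bg == 0:
        raise ValueError("empty read set in position enrichment")
    eps = 1.0 / (n_bg + 20)
    f_fg = fg_counts / n_fg
    f_bg = bg_counts / n_bg
    log2r = np.log2((f_fg + eps) / (f_bg + eps))

    rows = []
    for pos in range(length):
        for j, aa in enumerate(AA20):
            p_null = min(max(f_bg[pos, j], 1e-12), 1 - 1e-12)
            pval = binomtest(int(fg_counts[pos, j]), n_fg, p_null).pvalue
            rows.append(
                (
                    pos + 1,
                    aa,
                    int(fg_counts[pos, j]),
                    int(bg_counts[pos, j]),
                    f_fg[pos, j],
                    f_bg[pos, j],
                    log2r[pos, j],
                    pval,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "position",
            "residue",
            "count_fg",
            "count_bg",
            "f_fg",
            "f_bg",
            "log2_ratio",
            "p_value",
        ],
    ).set_index(["position", "residue"])
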