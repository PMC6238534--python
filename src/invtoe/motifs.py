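"""Motif counting, pause strengths, replicate error models and enrichment.

The central objects are per-sample :class:`MotifTable` counts over 3-symbol
motifs X1X2(X3), where X2 occupies the ribosomal P-site and X3 the A-site.
For every read whose fragment end maps to P-site codon p ≥ 2:

* the *terminal* motif (aa[p−1], aa[p], A-site symbol) gains one stall
  count nP — a UAG codon in the A-site renders ``'*'``;
* every interior motif (aa[i−1], aa[i], aa[i+1]), 2 ≤ i < p, gains one
  bypass count nB, at most once per read (the ribosome translated through
  it on its way to the stall site).

From these counts:

* motif frequency        F  = nP / n_total          (n_total = all processed reads)
* pause strength         PS = nP / (nP + nB)        (fraction of encounters
                                                     that end in a stall)
* fold change            FC = mean(F_fg) / mean(F_bg) between conditions,
  with the inter-replicate error propagated as
  dFC = sqrt((dF_bg/F_bg)² + (dF_fg/F_fg)²) · FC.

A binomial partition model quantifies how much of the replicate-to-replicate
scatter is pure counting noise, which motivates the "well-measured"
threshold on combined read counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._genetics import AA20, CODON_TO_AA, STOP_CODONS, STOP_SYMBOL, translate_nt
from .mapping import assign_psite
from .process import ProcessedRead

log = logging.getLogger(__name__)

CODON_SEP = "-"


def sense_motifs() -> list[str]:
    """All X1X2(X3) motifs over the 20 amino acids (no stop in any slot)."""
    return [a + b + c for a in AA20 for b in AA20 for c in AA20]


def is_sense_motif(motif: str, kind: str = "aa3") -> bool:
    if kind == "aa3":
        return STOP_SYMBOL not in motif and "X" not in motif
    return not any(c in STOP_CODONS for c in motif.split(CODON_SEP))


# ---------------------------------------------------------------------------
# per-sample count tables


@dataclass
class MotifTable:
    """Stall (nP) and bypass (nB) counts per motif for one sample.

    ``n_total`` counts *all* processed reads, including those with p < 2
    that contribute no terminal motif, so Σ F over terminal motifs equals
    the fraction of reads carrying an assignable stall.
    """

    kind: str = "aa3"
    nP: Counter = field(default_factory=Counter)
    nB: Counter = field(default_factory=Counter)
    n_total: int = 0

    def frequencies(self) -> pd.Series:
        """Motif frequency F = nP / n_total."""
        if self.n_total == 0:
            raise ValueError("empty table: n_total == 0")
        return pd.Series(self.nP, dtype=float).sort_index() / self.n_total

    def motifs(self) -> set[str]:
        return set(self.nP) | set(self.nB)

    def merged(self, other: "MotifTable") -> "MotifTable":
        """Pooled counts of two samples (e.g. replicates for PS, Fig-style)."""
        if other.kind != self.kind:
            raise ValueError("cannot merge tables of different kinds")
        return MotifTable(
            self.kind,
            self.nP + other.nP,
            self.nB + other.nB,
            self.n_total + other.n_total,
        )

    def to_frame(self) -> pd.DataFrame:
        motifs = sorted(self.motifs())
        nP = [self.nP.get(m, 0) for m in motifs]
        nB = [self.nB.get(m, 0) for m in motifs]
        df = pd.DataFrame({"nP": nP, "nB": nB}, index=pd.Index(motifs, name="motif"))
        df["F"] = df["nP"] / self.n_total if self.n_total else np.nan
        return df

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\tn_total={self.n_total}\n")
            self.to_frame().to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "MotifTable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# kind="):
                raise ValueError(f"{path}: not a motif table (missing header)")
            kind_part, total_part = header[2:].strip().split("\t")
            kind = kind_part.split("=", 1)[1]
            n_total = int(total_part.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t", index_col="motif")
        return cls(
            kind,
            Counter({m: int(v) for m, v in df["nP"].items() if v}),
            Counter({m: int(v) for m, v in df["nB"].items() if v}),
            n_total,
        )


def translate_protected(
    pr: ProcessedRead, offset: int
) -> tuple[str, int] | None:
    """Peptide of the protected region through the A-site, plus the P-site.

    The protected nucleotides downstream of the A-site codon are discarded;
    codons 1..p+1 are translated, a stop codon in the A-site rendering
    ``'*'``.  Returns None (read excluded from motif counting, but still in
    n_total) when the P-site is unassignable, the A-site codon is
    incomplete, or an internal stop shows the frame is unusable.
    """
    p = assign_psite(pr.end_pos, offset)
    if p is None or p < 1:
        return None
    if 3 * (p + 1) > pr.end_pos:
        return None  # partial A-site codon
    pep = translate_nt(pr.nt_sequence, p + 1)
    if STOP_SYMBOL in pep[:-1] or "X" in pep:
        log.debug("read %s: internal stop/ambiguity in protected region", pr.id)
        return None
    return pep, p


def read_motifs(units: Sequence[str], p: int, *, joined: bool = True):
    """Terminal motif and bypassed interior motifs of one protected read.

    ``units`` are the per-codon symbols (amino acids or codon strings) for
    positions 1..p+1 including the A-site.  Interior windows run over
    P-site positions 2 ≤ i < p.
    """
    sep = "" if joined and len(units[0]) == 1 else CODON_SEP
    terminal = sep.join(units[p - 2 : p + 1])
    bypassed = [sep.join(units[i - 2 : i + 1]) for i in range(2, p)]
    return terminal, bypassed


def count_motifs(
    reads: Iterable[ProcessedRead],
    offset: int,
    *,
    kind: str = "aa3",
    bypass_mode: str = "read",
    table: MotifTable | None = None,
) -> MotifTable:
    """Count terminal (nP) and bypassed (nB) motifs over a read stream.

    ``bypass_mode="read"`` increments a motif's nB at most once per read
    (number of *reads* that translated through it); ``"occurrence"`` counts
    every interior occurrence, for sensitivity analysis.
    """
    if kind not in ("aa3", "codon3"):
        raise ValueError(f"unknown motif kind {kind!r}")
    if bypass_mode not in ("read", "occurrence"):
        raise ValueError(f"unknown bypass_mode {bypass_mode!r}")
    if table is None:
        table = MotifTable(kind=kind)
    nP, nB = table.nP, table.nB
    for pr in reads:
        table.n_total += 1
        prot = translate_protected(pr, offset)
        if prot is None:
            continue
        pep, p = prot
        if p < 2:
            continue
        if kind == "aa3":
            units: Sequence[str] = pep
        else:
            seq = pr.nt_sequence
            units = [seq[3 * i : 3 * i + 3] for i in range(p + 1)]
        terminal, bypassed = read_motifs(units, p)
        nP[terminal] += 1
        if bypass_mode == "read":
            bypassed = set(bypassed)
        for m in bypassed:
            nB[m] += 1
    return table


def count_motifs_library(
    reads: Iterable[ProcessedRead],
    *,
    n_codons: int | None = None,
    kind: str = "aa3",
    table: MotifTable | None = None,
) -> MotifTable:
    """Motif occurrence counts for an *input library* sample.

    Library reads are full-length templates, not toeprints, so there is no
    stall site: every 3-symbol window is counted (into nP, so that
    ``frequencies`` gives the per-read occurrence frequency used as the
    enrichment background).  Windows with a stop anywhere but the A-site
    slot are skipped.
    """
    if table is None:
        table = MotifTable(kind=kind)
    nP = table.nP
    for pr in reads:
        table.n_total += 1
        seq = pr.nt_sequence
        limit = len(seq) // 3 if n_codons is None else min(n_codons, len(seq) // 3)
        if kind == "aa3":
            pep = translate_nt(seq, limit)
            stop_at = pep.find(STOP_SYMBOL)
            usable = len(pep) if stop_at < 0 else stop_at + 1
            for i in range(2, usable):  # window (i-1, i, i+1), 1-based i
                w = pep[i - 2 : i + 1]
                if "X" in w or STOP_SYMBOL in w[:2]:
                    continue
                nP[w] += 1
        else:
            cods = [seq[3 * i : 3 * i + 3] for i in range(limit)]
            for i in range(2, len(cods)):
                w = cods[i - 2 : i + 1]
                if any(c in STOP_CODONS for c in w[:2]) or not all(
                    c in CODON_TO_AA for c in w
                ):
                    continue
                nP[CODON_SEP.join(w)] += 1
    return table


# ---------------------------------------------------------------------------
# pause strength


def pause_strength(table: MotifTable, *, include_stop: bool = False) -> pd.DataFrame:
    """Per-motif pause strength PS = nP / (nP + nB).

    A value of 1 means ribosomes never bypass the motif; 0.2 means 80 % of
    encountering ribosomes translated through it and stalled downstream.
    Motifs never encountered (nP + nB = 0) are undefined and omitted.
    ``'*'``-A-site motifs are excluded from the sense ranking by default —
    stop pausing is a cleavage-calibration signal, not a peptide motif.
    """
    motifs = sorted(table.motifs())
    if not include_stop:
        motifs = [m for m in motifs if is_sense_motif(m, table.kind)]
    nP = np.array([table.nP.get(m, 0) for m in motifs], dtype=float)
    nB = np.array([table.nB.get(m, 0) for m in motifs], dtype=float)
    enc = nP + nB
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = np.where(enc > 0, nP / np.where(enc > 0, enc, 1), np.nan)
    df = pd.DataFrame(
        {"nP": nP.astype(int), "nB": nB.astype(int), "PS": ps},
        index=pd.Index(motifs, name="motif"),
    )
    return df[enc > 0]


# ---------------------------------------------------------------------------
# counting-noise model


@dataclass
class PartitionErrorModel:
    """Observed vs binomial-partition SD of the replicate-1 fraction, binned
    by total read count, plus the total at which the predicted SD first
    drops below the chosen bound."""

    table: pd.DataFrame  # bin_center, n_motifs, observed_sd, predicted_sd
    threshold: float | None
    p_replicate: float
    sd_bound: float = 0.05


def partition_sd(
    total: int, n_motifs: int, p: float = 0.5, rng=None
) -> float:
    """SD across ``n_motifs`` motifs of the replicate-1 fraction when a fixed
    two-replicate ``total`` is split by a Binomial(total, p) draw.

    Closed form: sqrt(p(1−p)/total); the Monte-Carlo version is what the
    replicate-scatter diagnostic plots.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fracs = rng.binomial(total, p, size=n_motifs) / total
    return float(np.std(fracs))


def partition_error_model(
    table_a: MotifTable,
    table_b: MotifTable,
    *,
    bin_edges: Sequence[float] | None = None,
    n_sim: int = 200,
    seed=None,
    sd_bound: float = 0.05,
) -> PartitionErrorModel:
    """Compare observed replicate scatter with pure counting noise.

    For every motif the replicate-A fraction nA/(nA+nB-counts) is computed
    and binned by the two-replicate total; the observed SD per bin is set
    against the SD of ``n_sim`` random binomial partitions of the same
    totals with success probability proportional to the replicate sizes.
    """
    motifs = sorted(table_a.motifs() | table_b.motifs())
    a = np.array([table_a.nP.get(m, 0) for m in motifs], dtype=float)
    b = np.array([table_b.nP.get(m, 0) for m in motifs], dtype=float)
    totals = a + b
    keep = totals > 0
    a, totals = a[keep], totals[keep]
    if totals.size == 0:
        raise ValueError("no motifs with nonzero counts")
    p_hat = float(a.sum() / totals.sum())
    fracs = a / totals

    if bin_edges is None:
        hi = max(totals.max(), 4.0)
        bin_edges = np.unique(np.round(np.geomspace(1.5, hi * 1.01, 12)))
    bin_edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(totals, bin_edges)
    rng = np.random.default_rng(seed)

    rows = []
    for k in range(1, len(bin_edges)):
        sel = which == k
        n_in = int(sel.sum())
        if n_in < 2:
            log.warning("partition model: bin %d has <2 motifs; skipped", k)
            continue
        t_in = totals[sel].astype(int)
        center = float(np.exp(np.mean(np.log(t_in))))
        observed = float(np.std(fracs[sel]))
        draws = rng.binomial(np.tile(t_in, n_sim), p_hat) / np.tile(t_in, n_sim)
        predicted = float(np.std(draws))
        rows.append((center, n_in, observed, predicted))
    df = pd.DataFrame(
        rows, columns=["bin_center", "n_motifs", "observed_sd", "predicted_sd"]
    )
    below = df[df["predicted_sd"] < sd_bound]
    threshold = float(below["bin_center"].iloc[0]) if len(below) else None
    return PartitionErrorModel(df, threshold, p_hat, sd_bound)


# ---------------------------------------------------------------------------
# enrichment between conditions


def log2_to_fold(x: float) -> float:
    """Fold change corresponding to a log2 ratio (2**x)."""
    return float(2.0**x)


def fold_to_log2(f: float) -> float:
    return float(np.log2(f))


def _freq(table: MotifTable, pseudo: float | None) -> pd.Series:
    s = pd.Series(table.nP, dtype=float)
    if pseudo:
        s = s + pseudo
    return s / table.n_total


def fold_change(
    fg: Sequence[MotifTable],
    bg: Sequence[MotifTable],
    *,
    min_counts: int = 150,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Per-motif enrichment of ``fg`` over ``bg`` with propagated errors.

    Replicate frequencies are averaged; the inter-replicate absolute
    difference dF feeds the propagated fold-change error
    dFC = sqrt((dF_bg/F_bg)² + (dF_fg/F_fg)²) · FC.  ``well_measured``
    requires a combined stall count across all fg+bg replicates strictly
    above ``min_counts``.  Motifs absent from the background have undefined
    FC (NaN) unless a ``pseudo`` count is supplied (default off).  With a
    single replicate on either side dF and dFC are NaN.
    """
    if not fg or not bg:
        raise ValueError("need at least one table per condition")
    motifs = sorted(set().union(*(t.motifs() for t in list(fg) + list(bg))))
    idx = pd.Index(motifs, name="motif")

    def side(tables):
        F = [_freq(t, pseudo).reindex(idx, fill_value=pseudo or 0.0) for t in tables]
        mean = sum(F) / len(F)
        if len(F) >= 2:
            stacked = pd.concat(F, axis=1)
            dF = stacked.max(axis=1) - stacked.min(axis=1)
        else:
            log.warning("single-replicate condition: dF undefined")
            dF = pd.Series(np.nan, index=idx)
        counts = sum(
            pd.Series(t.nP, dtype=float).reindex(idx, fill_value=0.0) for t in tables
        )
        return mean, dF, counts

    F_fg, dF_fg, c_fg = side(fg)
    F_bg, dF_bg, c_bg = side(bg)

    with np.errstate(divide="ignore", invalid="ignore"):
        FC = (F_fg / F_bg).where(F_bg > 0)
        rel_fg = (dF_fg / F_fg).where(F_fg > 0)
        rel_bg = (dF_bg / F_bg).where(F_bg > 0)
        dFC = np.sqrt(rel_bg**2 + rel_fg**2) * FC
        log2FC = np.log2(FC.where(FC > 0))

    counts = c_fg + c_bg
    return pd.DataFrame(
        {
            "F_fg_mean": F_fg,
            "F_bg_mean": F_bg,
            "dF_fg": dF_fg,
            "dF_bg": dF_bg,
            "FC": FC,
            "dFC": dFC,
            "log2FC": log2FC,
            "n_reads": counts.astype(int),
            "well_measured": counts > min_counts,
        }
    )


def classify_motifs(
    ps_fg: pd.Series | pd.DataFrame,
    ps_bg: pd.Series | pd.DataFrame,
    enrich: pd.DataFrame,
    *,
    ps_min: float = 0.25,
    ps_ratio: float = 1.5,
    log2fc_min: float = 0.5,
) -> pd.Series:
    """Label well-measured motifs as intrinsic, drug_dependent or none.

    ``intrinsic``: pause strength without drug ≥ ``ps_min`` (pausing needs
    no drug).  ``drug_dependent``: PS with drug ≥ ``ps_min`` AND at least
    ``ps_ratio``-fold above the drug-free PS AND log2 enrichment ≥
    ``log2fc_min``.  Intrinsic takes precedence.  Motifs never encountered
    in the background count as PS 0 for the ratio test.
    """
    if isinstance(ps_fg, pd.DataFrame):
        ps_fg = ps_fg["PS"]
    if isinstance(ps_bg, pd.DataFrame):
        ps_bg = ps_bg["PS"]
    idx = enrich.index[enrich["well_measured"]]
    psf = ps_fg.reindex(idx)
    psb = ps_bg.reindex(idx)
    lfc = enrich.loc[idx, "log2FC"]
    labels = pd.Series("none", index=idx, name="class")
    intrinsic = psb >= ps_min
    drug = (
        (psf >= ps_min)
        & (psf >= ps_ratio * psb.fillna(0.0))
        & (lfc >= log2fc_min)
        & ~intrinsic.fillna(False)
    )
    labels[intrinsic.fillna(False)] = "intrinsic"
    labels[drug.fillna(False)] = "drug_dependent"
    return labels


# ---------------------------------------------------------------------------
# codon-usage control


def read_codon_usage(path) -> dict[str, float]:
    """Read a codon → usage-frequency TSV (two columns, optional header)."""
    usage: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 2 or parts[0].lower() == "codon":
                continue
            usage[parts[0].upper().replace("U", "T")] = float(parts[1])
    return usage


def usage_correlation(
    enrich: pd.DataFrame,
    usage: Mapping[str, float],
) -> pd.DataFrame:
    """Pearson correlation of 3-codon motif enrichment with codon usage.

    For well-measured motifs, log2FC is correlated against the usage
    frequency of the first, second and third codon separately — a control
    showing whether apparent enrichment merely tracks codon abundance.
    ``usage`` must cover all 61 sense codons; a zero-variance usage vector
    gives an undefined (NaN) coefficient.
    """
    sense = {c for c in CODON_TO_AA if c not in STOP_CODONS}
    missing = sense - set(usage)
    if missing:
        raise ValueError(f"usage table missing {len(missing)} sense codons")
    rows = enrich[enrich["well_measured"] & np.isfinite(enrich["log2FC"])]
    out = []
    for pos in range(3):
        x, y = [], []
        for motif, lfc in rows["log2FC"].items():
            cods = motif.split(CODON_SEP)
            if len(cods) != 3:
                raise ValueError(f"{motif!r} is not a 3-codon motif")
            if cods[pos] in usage:
                x.append(usage[cods[pos]])
                y.append(lfc)
        x, y = np.asarray(x), np.asarray(y)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            log.warning("usage correlation position %d undefined", pos + 1)
            r = np.nan
        else:
            r = float(sps.pearsonr(x, y).statistic)
        out.append((pos + 1, r, r**2 if np.isfinite(r) else np.nan, len(x)))
    return pd.DataFrame(out, columns=["codon_position", "r", "r2", "n"]).set_index(
        "codon_position"
    )
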