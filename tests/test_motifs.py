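"""Motif counting, pause strength, replicate noise model, enrichment."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invtoe._genetics import AA20
from invtoe.motifs import (
    MotifTable,
    classify_motifs,
    count_motifs,
    count_motifs_library,
    fold_change,
    partition_error_model,
    partition_sd,
    pause_strength,
    read_motifs,
    translate_protected,
    usage_correlation,
)
from invtoe.process import ProcessedRead

from conftest import processed


def _toeprint(codons, pad_to_offset=17):
    """A ProcessedRead whose fragment end encodes the last codon as P-site."""
    seq = "".join(codons)
    p = len(codons) - 1  # last supplied codon is the A-site
    core = seq + "GCTGCTGCTGCTGCTGC"[: 3 * p + pad_to_offset - len(seq)]
    return processed(core)


class TestTranslateProtected:
    def test_direct_translation(self):
        pr = _toeprint(["ATG", "CCG", "CCG", "GAT"])
        assert translate_protected(pr, 17) == ("MPPD", 3)

    def test_uag_a_site_renders_star(self):
        pr = _toeprint(["ATG", "CCG", "CCG", "TAG"])
        assert translate_protected(pr, 17) == ("MPP*", 3)

    def test_short_fragment_excluded(self):
        assert translate_protected(processed("ATGCCGCC"), 17) is None


class TestCountMotifs:
    def test_definition_unrolled(self):
        """Peptide M-A-P with A-site P: nP[AP(P)] and nB[MA(P)] each once."""
        table = count_motifs([_toeprint(["ATG", "GCT", "CCG", "CCA"])], 17)
        assert table.nP == Counter({"APP": 1})
        assert table.nB == Counter({"MAP": 1})
        assert table.n_total == 1

    def test_read_level_bypass_counted_once(self):
        """M-P-P-G-P-P with A-site D: PP(D) stalls, interior PP(G) bypassed;
        repeated interior occurrences of one motif count once per read."""
        table = count_motifs(
            [_toeprint(["ATG", "CCG", "CCA", "GGT", "CCG", "CCA", "GAT"])], 17
        )
        assert table.nP == Counter({"PPD": 1})
        assert table.nB == Counter({"MPP": 1, "PPG": 1, "PGP": 1, "GPP": 1})

    def test_occurrence_mode_counts_repeats(self):
        table = count_motifs(
            [_toeprint(["ATG", "CCG", "CCA", "CCG", "CCA", "CCG", "GAT"])],
            17,
            bypass_mode="occurrence",
        )
        assert table.nB["PPP"] == 3

    @given(
        st.text(alphabet=AA20, min_size=3, max_size=12).map(lambda s: "M" + s)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_window_enumeration_oracle(self, pep):
        """read_motifs agrees with a brute-force window enumeration."""
        p = len(pep) - 1
        terminal, bypassed = read_motifs(pep, p)
        expect_term = pep[p - 2] + pep[p - 1] + pep[p]
        expect_bypass = [
            pep[i - 2] + pep[i - 1] + pep[i] for i in range(2, p)
        ]
        assert terminal == expect_term
        assert bypassed == expect_bypass

    def test_total_includes_short_reads(self):
        reads = [_toeprint(["ATG", "GCT", "CCG", "CCA"]), processed("ATGGC")]
        table = count_motifs(reads, 17)
        assert table.n_total == 2
        assert sum(table.nP.values()) == 1

    def test_codon_kind(self):
        table = count_motifs([_toeprint(["ATG", "GCT", "CCG", "CCA"])], 17, kind="codon3")
        assert table.nP == Counter({"GCT-CCG-CCA": 1})
        assert table.nB == Counter({"ATG-GCT-CCG": 1})

    def test_library_mode_counts_all_windows(self):
        table = count_motifs_library([processed("ATG" + "GCT" * 4)])
        assert table.nP == Counter({"MAA": 1, "AAA": 2})
        assert table.n_total == 1


class TestPauseStrength:
    def test_semantics(self):
        """nP=20, nB=80 gives PS 0.2 — 80% of encounters bypassed."""
        t = MotifTable(nP=Counter({"PPD": 20}), nB=Counter({"PPD": 80}), n_total=1000)
        ps = pause_strength(t)
        assert ps.loc["PPD", "PS"] == pytest.approx(0.2)

    def test_never_bypassed(self):
        t = MotifTable(nP=Counter({"PPP": 5}), n_total=10)
        assert pause_strength(t).loc["PPP", "PS"] == 1.0

    def test_stop_motifs_excluded_from_sense_ranking(self):
        t = MotifTable(nP=Counter({"PP*": 5, "PPD": 1}), n_total=10)
        ps = pause_strength(t)
        assert "PP*" not in ps.index
        assert "PP*" in pause_strength(t, include_stop=True).index


class TestPartitionModel:
    def test_closed_form_sd_at_150(self, rng):
        """Binomial partitioning of 150-read totals: SD ≈ 0.5/sqrt(150)."""
        sd = partition_sd(150, 20_000, rng=rng)
        assert sd == pytest.approx(0.5 / math.sqrt(150), abs=0.002)

    def test_sd_decreases_with_total(self, rng):
        sds = [partition_sd(t, 20_000, rng=rng) for t in (50, 150, 500, 5000)]
        assert sds == sorted(sds, reverse=True)

    def test_observed_matches_predicted_for_pure_counting_noise(self, rng):
        """Replicates that differ only by a binomial split show scatter fully
        explained by the partition model."""
        totals = np.unique(rng.integers(5, 2000, size=4000))
        a_counts = rng.binomial(totals, 0.5)
        motifs = [f"m{i}" for i in range(len(totals))]
        ta = MotifTable(nP=Counter(dict(zip(motifs, a_counts.tolist()))), n_total=10**6)
        tb = MotifTable(
            nP=Counter(dict(zip(motifs, (totals - a_counts).tolist()))), n_total=10**6
        )
        model = partition_error_model(ta, tb, n_sim=200, seed=0)
        big = model.table[model.table["n_motifs"] >= 50]
        assert len(big) >= 3
        assert np.all(
            np.abs(big["observed_sd"] - big["predicted_sd"])
            < 0.35 * big["predicted_sd"] + 0.01
        )
        assert model.threshold is not None


def _table(freqs, n_total=1_000_000):
    counts = {m: int(round(f * n_total)) for m, f in freqs.items()}
    return MotifTable(nP=Counter(counts), n_total=n_total)


class TestFoldChange:
    def test_no_replicate_scatter_means_no_error(self):
        fg = [_table({"AAA": 2e-4})] * 2
        bg = [_table({"AAA": 1e-4})] * 2
        df = fold_change(fg, bg)
        assert df.loc["AAA", "FC"] == pytest.approx(2.0)
        assert df.loc["AAA", "dFC"] == 0.0

    def test_degenerate_background_error(self):
        fg = [_table({"AAA": 2e-4}), _table({"AAA": 3e-4})]
        bg = [_table({"AAA": 1e-4})] * 2
        df = fold_change(fg, bg)
        F_fg, dF_fg, FC = 2.5e-4, 1e-4, 2.5
        assert df.loc["AAA", "dFC"] == pytest.approx((dF_fg / F_fg) * FC)

    def test_identical_conditions_give_unit_fold_change(self):
        tables = [_table({"AAA": 2e-4, "CCC": 5e-5})] * 2
        df = fold_change(tables, tables)
        assert np.allclose(df["FC"], 1.0)

    def test_absent_from_background_is_flagged_undefined(self):
        fg = [_table({"AAA": 2e-4})] * 2
        bg = [_table({"CCC": 2e-4})] * 2
        df = fold_change(fg, bg)
        assert np.isnan(df.loc["AAA", "FC"])
        assert df.loc["CCC", "FC"] == 0.0

    def test_well_measured_uses_combined_counts(self):
        fg = [_table({"AAA": 40 / 1e6})] * 2
        bg = [_table({"AAA": 40 / 1e6})] * 2
        assert not fold_change(fg, bg, min_counts=160).loc["AAA", "well_measured"]
        assert fold_change(fg, bg, min_counts=159).loc["AAA", "well_measured"]

    @given(
        st.lists(
            st.tuples(*[st.integers(min_value=1, max_value=2000)] * 4),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_error_propagation_formula(self, rows):
        """dFC matches an independent evaluation of
        sqrt((dF_bg/F_bg)^2 + (dF_fg/F_fg)^2) * F_fg/F_bg."""
        n_total = 10**6
        motifs = [f"m{i}" for i in range(len(rows))]
        cols = list(zip(*rows))
        tables = [
            _table({m: c / n_total for m, c in zip(motifs, col)}, n_total)
            for col in cols
        ]
        df = fold_change(tables[:2], tables[2:], min_counts=0)
        for m, (f1, f2, b1, b2) in zip(motifs, rows):
            F_fg, F_bg = (f1 + f2) / 2 / n_total, (b1 + b2) / 2 / n_total
            dF_fg, dF_bg = abs(f1 - f2) / n_total, abs(b1 - b2) / n_total
            expect = math.sqrt((dF_bg / F_bg) ** 2 + (dF_fg / F_fg) ** 2) * F_fg / F_bg
            assert df.loc[m, "dFC"] == pytest.approx(expect, rel=1e-12, abs=1e-15)


class TestClassification:
    def _enrich(self, log2fc):
        return pd.DataFrame(
            {"log2FC": [log2fc], "well_measured": [True]},
            index=pd.Index(["APP"], name="motif"),
        )

    def _ps(self, value):
        return pd.Series([value], index=["APP"], name="PS")

    def test_drug_dependent(self):
        labels = classify_motifs(self._ps(0.30), self._ps(0.10), self._enrich(0.6))
        assert labels["APP"] == "drug_dependent"

    def test_below_pause_cutoff_is_none(self):
        labels = classify_motifs(self._ps(0.24), self._ps(0.10), self._enrich(5.0))
        assert labels["APP"] == "none"

    def test_intrinsic(self):
        labels = classify_motifs(self._ps(0.50), self._ps(0.40), self._enrich(0.0))
        assert labels["APP"] == "intrinsic"


class TestUsageCorrelation:
    def _usage(self, rng):
        from invtoe._genetics import CODON_TO_AA, STOP_CODONS

        sense = sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
        vals = rng.random(len(sense))
        return dict(zip(sense, vals / vals.sum()))

    def _enrich_from_usage(self, usage, rng, position):
        sense = sorted(usage)
        motifs, lfc = [], []
        for _ in range(200):
            cods = [sense[rng.integers(len(sense))] for _ in range(3)]
            motifs.append("-".join(cods))
            lfc.append(usage[cods[position]])
        return pd.DataFrame(
            {"log2FC": lfc, "well_measured": True},
            index=pd.Index(motifs, name="motif"),
        )

    def test_perfect_correlation_with_chosen_position(self, rng):
        usage = self._usage(rng)
        enrich = self._enrich_from_usage(usage, rng, position=1)
        out = usage_correlation(enrich, usage)
        assert out.loc[2, "r"] == pytest.approx(1.0)
        assert abs(out.loc[1, "r"]) < 0.5

    def test_constant_usage_undefined(self, rng):
        usage = {c: 1 / 61 for c in self._usage(rng)}
        enrich = self._enrich_from_usage(self._usage(rng), rng, 0)
        out = usage_correlation(enrich, usage)
        assert np.isnan(out.loc[1, "r"])

    def test_missing_codons_rejected(self, rng):
        usage = self._usage(rng)
        usage.pop("GCT")
        with pytest.raises(ValueError, match="missing"):
            usage_correlation(self._enrich_from_usage(self._usage(rng), rng, 0), usage)
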