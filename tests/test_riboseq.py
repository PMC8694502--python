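"""A-site assignment, metagene distribution, pause scores and class contrasts."""

import numpy as np
import pandas as pd
import pytest

import m7gkit as m
from m7gkit.riboseq import (
    DEFAULT_OFFSETS,
    CodonCounts,
    assign_a_site,
    codon_occupancy,
    correlate_abundance_occupancy,
    metagene_distribution,
    occupancy_change,
)
from m7gkit.simulate import Transcript
from m7gkit.trna import CodonClass, CodonClassMap, SENSE_CODONS, ValidationError


def _toy_transcript(n_codons=40, cds_start=10, tid="t1"):
    rng = np.random.default_rng(0)
    body = "".join(rng.choice(["GCT", "GCC", "AAA", "TTC"], size=n_codons))
    seq = "A" * cds_start + body + "A" * 60
    return Transcript(id=tid, sequence=seq, cds_start=cds_start, cds_end=cds_start + 3 * n_codons)


def _uniform_class_map(m7g=(), wobble=()):
    class_of = {}
    for c in SENSE_CODONS:
        if c in m7g:
            class_of[c] = CodonClass.M7G_DECODED
        elif c in wobble:
            class_of[c] = CodonClass.WOBBLE_ONLY
        else:
            class_of[c] = CodonClass.NON_M7G
    return CodonClassMap(class_of=class_of)


class TestAssign:
    def test_direct_arithmetic(self):
        t = _toy_transcript(n_codons=40, cds_start=10)
        fps = pd.DataFrame({"transcript": ["t1"], "start": [100], "length": [28]})
        counts, st = assign_a_site(fps, [t])
        # A-site nt = 100 + 15 = 115 -> codon (115 - 10) // 3 = 35
        assert counts["t1"].counts[35] == 1
        assert counts["t1"].counts.sum() == 1
        assert st.conserved and st.n_cds == 1

    def test_unlisted_length_discarded(self):
        t = _toy_transcript()
        fps = pd.DataFrame({"transcript": ["t1", "t1"], "start": [30, 30], "length": [24, 28]})
        counts, st = assign_a_site(fps, [t])
        assert st.n_discarded_length == 1
        assert st.conserved

    def test_unknown_transcript_skipped_with_count(self):
        t = _toy_transcript()
        fps = pd.DataFrame({"transcript": ["nope"], "start": [30], "length": [28]})
        _, st = assign_a_site(fps, [t])
        assert st.n_unknown_transcript == 1 and st.conserved

    def test_simulated_footprints_assign_to_planted_codons(self, small_sim):
        cfg, txs, cm = small_sim["cfg"], small_sim["transcripts"], small_sim["class_map"]
        fps, _, _ = m.simulate_ribo_rna(txs, cm, cfg, "CTRL")
        counts, st = assign_a_site(fps, txs)
        assert st.conserved
        # generator and analyser share the offset table: every CDS-planted
        # footprint lands on a codon, giving exactly the planted CDS fraction
        assert st.n_cds / st.n_input == pytest.approx(cfg.cds_fraction, abs=0.01)


class TestMetagene:
    def test_all_cds(self):
        t = _toy_transcript()
        fps = pd.DataFrame({"transcript": ["t1"] * 3, "start": [20, 30, 40], "length": [28] * 3})
        prof = metagene_distribution(fps, [t])
        assert prof.cds == 1.0
        assert prof.utr5 + prof.cds + prof.utr3 == pytest.approx(1.0)

    def test_generator_default_fraction(self, small_sim):
        cfg, txs, cm = small_sim["cfg"], small_sim["transcripts"], small_sim["class_map"]
        fps, _, _ = m.simulate_ribo_rna(txs, cm, cfg, "KO")
        prof = metagene_distribution(fps, txs)
        assert abs(prof.cds - 0.85) <= 0.03

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            metagene_distribution(pd.DataFrame(columns=["transcript", "start", "length"]), [])


class TestPauseScores:
    def _counts(self, codons, counts):
        return {"t1": CodonCounts(codons=list(codons), counts=np.array(counts, dtype=float))}

    def test_uniform_counts_score_one(self):
        tab = codon_occupancy(
            self._counts(["GCT", "GCC", "AAA", "TTC"], [3, 3, 3, 3]),
            _uniform_class_map(),
            min_transcript_rpf=1,
            min_occurrences=1,
        )
        assert np.allclose(tab["mean_a"], 1.0)

    def test_pause_vector_direct_arithmetic(self):
        tab = codon_occupancy(
            self._counts(["GCT", "GCC", "AAA", "TTC"], [2, 2, 6, 2]),
            _uniform_class_map(),
            min_transcript_rpf=1,
            min_occurrences=1,
        )
        assert tab.loc["GCT", "mean_a"] == pytest.approx(2 / 3)
        assert tab.loc["GCC", "mean_a"] == pytest.approx(2 / 3)
        assert tab.loc["AAA", "mean_a"] == pytest.approx(2.0)
        assert tab.loc["TTC", "mean_a"] == pytest.approx(2 / 3)

    def test_scores_average_one_per_transcript(self, small_sim):
        cfg, txs, cm = small_sim["cfg"], small_sim["transcripts"], small_sim["class_map"]
        fps, _, _ = m.simulate_ribo_rna(txs, cm, cfg, "CTRL")
        counts, _ = assign_a_site(fps, txs)
        for cc in counts.values():
            if cc.counts.sum() >= 64:
                assert np.isclose((cc.counts / cc.counts.mean()).mean(), 1.0)

    def test_position_free_statistic_under_permutation(self):
        codons = ["GCT", "GCC", "AAA", "TTC"]
        counts = [2.0, 4.0, 6.0, 8.0]
        perm = [2, 0, 3, 1]
        a = codon_occupancy(self._counts(codons, counts), _uniform_class_map(), 1, 1)
        b = codon_occupancy(
            self._counts([codons[i] for i in perm], [counts[i] for i in perm]),
            _uniform_class_map(),
            1,
            1,
        )
        # the A-site statistic is position-free; A+1 depends on neighbours
        pd.testing.assert_frame_equal(
            a[["mean_a", "median_a", "n_a"]], b[["mean_a", "median_a", "n_a"]]
        )

    def test_a_plus_one_attribution_shifts_by_one_codon(self):
        # a pause on AAA (index 2) shows up at TTC (index 3) in the A+1 table
        tab = codon_occupancy(
            self._counts(["GCT", "GCC", "AAA", "TTC"], [2, 2, 6, 2]),
            _uniform_class_map(),
            1,
            1,
        )
        assert tab.loc["TTC", "mean_a1"] == pytest.approx(2.0)
        assert tab.loc["AAA", "mean_a1"] == pytest.approx(2 / 3)

    def test_min_occurrence_filter_nans_sparse_codons(self):
        tab = codon_occupancy(
            self._counts(["GCT", "GCC", "GCT", "TTC"], [1, 2, 3, 2]),
            _uniform_class_map(),
            min_transcript_rpf=1,
            min_occurrences=2,
        )
        assert np.isnan(tab.loc["GCC", "mean_a"])
        assert not np.isnan(tab.loc["GCT", "mean_a"])

    def test_no_qualifying_transcript_is_an_error(self):
        with pytest.raises(ValidationError):
            codon_occupancy(self._counts(["GCT"], [1.0]), _uniform_class_map(), 100, 1)


class TestOccupancyChange:
    def _table(self, scale=1.0):
        counts = {
            f"t{i}": CodonCounts(
                codons=list(np.random.default_rng(i).choice(SENSE_CODONS, 120)),
                counts=np.random.default_rng(100 + i).poisson(10, 120).astype(float) * scale,
            )
            for i in range(12)
        }
        return codon_occupancy(counts, _uniform_class_map(m7g=("GCT", "AAA")), 10, 5)

    def test_identical_conditions_give_unit_ratios(self):
        tab = self._table()
        codon_df, tests = occupancy_change(tab, tab)
        assert np.allclose(codon_df["ratio_a"].dropna(), 1.0)
        assert (tests["qvalue"] > 0.05).all()

    def test_uniform_scaling_leaves_ratios_unchanged(self):
        codon_df, _ = occupancy_change(self._table(scale=2.0), self._table(scale=1.0))
        assert np.allclose(codon_df["ratio_a"].dropna(), 1.0)

    def test_planted_pause_detected_at_a_site_only(self, small_sim):
        cfg, txs, cm = small_sim["cfg"], small_sim["transcripts"], small_sim["class_map"]
        tabs = {}
        for cond in ("CTRL", "KO"):
            fps, _, _ = m.simulate_ribo_rna(txs, cm, cfg, cond)
            counts, _ = assign_a_site(fps, txs)
            # toy scale: ~10 occurrences per minority codon
            tabs[cond] = codon_occupancy(counts, cm, 32, 5)
        codon_df, tests = occupancy_change(tabs["KO"], tabs["CTRL"])
        m7g = codon_df[codon_df["codon_class"] == "M7G_DECODED"]["ratio_a"].dropna()
        non = codon_df[codon_df["codon_class"] == "NON_M7G"]["ratio_a"].dropna()
        m7g_a1 = codon_df[codon_df["codon_class"] == "M7G_DECODED"]["ratio_a1"].dropna()
        assert m7g.median() > non.median() + 0.3
        # the A+1 control is flat (wide tolerance: ~10 occurrences/codon here)
        assert abs(m7g_a1.median() - 1.0) < 0.25
        # with only 5 m7G codons at toy scale the rank-sum has little power;
        # the A-site contrast must still dominate the A+1 control
        p_a = tests.loc[tests["site"] == "A", "pvalue"].iloc[0]
        p_a1 = tests.loc[tests["site"] == "A+1", "pvalue"].iloc[0]
        assert p_a < p_a1


class TestCorrelation:
    def test_degenerate_inputs_flagged(self, decoding, reference_truth):
        table, cm = decoding
        _, truth = reference_truth
        m7g_codons = cm.codons_in(CodonClass.M7G_DECODED)
        ratios = pd.DataFrame(
            {"codon_class": ["M7G_DECODED"] * len(m7g_codons), "ratio_a": 1.0},
            index=pd.Index(m7g_codons, name="codon"),
        )
        trna = pd.DataFrame({"log2fc": 0.0}, index=sorted(truth.m7g_ids))
        rep = correlate_abundance_occupancy(trna, ratios, table, truth.m7g_ids)
        assert rep.degenerate and np.isnan(rep.rho)

    def test_no_pairs_is_an_error(self, decoding):
        table, _ = decoding
        ratios = pd.DataFrame(columns=["codon_class", "ratio_a"])
        with pytest.raises(ValidationError):
            correlate_abundance_occupancy(
                pd.DataFrame({"log2fc": []}), ratios, table, frozenset()
            )
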