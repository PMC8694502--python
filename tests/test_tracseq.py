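"""Small-RNA alignment, cleavage scoring, site calling, motif and abundance."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import m7gkit as m
from m7gkit.tracseq import (
    EndCountProfile,
    LibraryProfile,
    M7GSiteCall,
    align_small_rna,
    call_sites,
    compute_cleavage_score,
    extract_motif,
    quantify_trna_abundance,
    species_read_counts,
)
from m7gkit.trna import TRNASpecies, ValidationError


def _sp(sid, seq, site=None, m7g=False):
    return TRNASpecies(
        id=sid,
        amino_acid="Ala",
        anticodon="AGC",
        sequence=seq,
        variable_loop_site=site if site is not None else len(seq) // 2,
        is_m7g=m7g,
    )


SEQ_A = "ATTCAGCCATTACCGTTGACCAGTCATCTAAGCAT"
SEQ_B = "CCGGATTCAACGGGTTAAGCCTTGGCAACTCGATA"


class TestAlign:
    def test_full_length_read(self):
        ref = [_sp("a", SEQ_A), _sp("b", SEQ_B)]
        prof = align_small_rna([SEQ_A], ref)
        assert prof.starts["a"][0] == 1
        assert prof.ends["a"][len(SEQ_A) - 1] == 1
        assert prof.coverage["a"].min() == 1
        assert prof.starts["b"].sum() == 0

    def test_multimapper_gets_fractional_weight(self):
        ref = [_sp("a", SEQ_A), _sp("a2", SEQ_A[:-1] + "G")]  # share a long prefix
        read = SEQ_A[:20]
        prof = align_small_rna([read], ref)
        assert prof.starts["a"][0] == pytest.approx(0.5)
        assert prof.starts["a2"][0] == pytest.approx(0.5)

    def test_one_mismatch_rescue(self):
        ref = [_sp("a", SEQ_A)]
        read = "G" + SEQ_A[1:20]
        prof = align_small_rna([read], ref)
        assert prof.n_unaligned == 0
        assert prof.starts["a"][0] == 1
        two_mm = "GG" + SEQ_A[2:20]
        assert align_small_rna([two_mm], ref).n_unaligned == 1

    def test_weight_conservation_on_simulated_library(self, small_cfg):
        species, truth = m.simulate_trna_reference(small_cfg)
        treated, _ = m.simulate_tracseq_reads(species, truth, small_cfg)
        prof = align_small_rna(treated, species)
        assert prof.assigned_weight + prof.n_unaligned == pytest.approx(len(treated))

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            align_small_rna(["ACGT"], [])


def _profile_pair(L, treated_arrays, input_arrays):
    def lib(label, arrays):
        s, e, c = arrays
        return LibraryProfile(
            label=label,
            starts={"x": np.array(s, dtype=float)},
            ends={"x": np.array(e, dtype=float)},
            coverage={"x": np.array(c, dtype=float)},
            n_reads=int(sum(s)),
            n_unaligned=0,
        )

    return EndCountProfile(
        treated=lib("treated", treated_arrays),
        input=lib("input", input_arrays),
        lengths={"x": L},
    )


class TestCleavageScore:
    def test_score_formula_direct_evaluation(self):
        # treated f=0.8 (evidence 80, read-through 20); input f=0.02
        z = [0.0] * 5
        prof = _profile_pair(
            5,
            ([0, 0, 0, 0, 0], [0, 80, 0, 0, 0], [100, 100, 20, 100, 100]),
            ([0, 0, 0, 0, 0], [0, 2, 0, 0, 0], [100, 100, 98, 100, 100]),
        )
        track = compute_cleavage_score(prof, alpha=0.01, min_cov=10)
        assert track.f_treated["x"][2] == pytest.approx(0.8)
        assert track.f_input["x"][2] == pytest.approx(0.02)
        assert track.score["x"][2] == pytest.approx(np.log2(0.81 / 0.03), abs=1e-9)
        assert track.score["x"][2] == pytest.approx(4.7549, abs=1e-3)

    def test_identical_libraries_score_zero(self):
        arrays = ([5, 0, 3, 0, 0], [0, 4, 0, 0, 9], [50, 50, 40, 50, 50])
        track = compute_cleavage_score(_profile_pair(5, arrays, arrays), min_cov=5)
        assert np.allclose(track.score["x"][~track.masked["x"]], 0.0)

    def test_no_treated_evidence_means_nonpositive_scores(self):
        prof = _profile_pair(
            5,
            ([0] * 5, [0] * 5, [100] * 5),
            ([0, 0, 6, 0, 0], [0, 6, 0, 0, 0], [100] * 5),
        )
        track = compute_cleavage_score(prof)
        assert (track.score["x"] <= 0).all()

    def test_swapping_libraries_negates_scores(self, rng):
        s = rng.integers(0, 30, 8).astype(float)
        e = rng.integers(0, 30, 8).astype(float)
        c = rng.integers(40, 90, 8).astype(float)
        s2 = rng.integers(0, 30, 8).astype(float)
        e2 = rng.integers(0, 30, 8).astype(float)
        c2 = rng.integers(40, 90, 8).astype(float)
        fwd = compute_cleavage_score(_profile_pair(8, (s, e, c), (s2, e2, c2)))
        rev = compute_cleavage_score(_profile_pair(8, (s2, e2, c2), (s, e, c)))
        ok = ~fwd.masked["x"]
        assert np.allclose(fwd.score["x"][ok], -rev.score["x"][ok])

    def test_low_coverage_positions_masked(self):
        prof = _profile_pair(3, ([0] * 3, [0] * 3, [5] * 3), ([0] * 3, [0] * 3, [100] * 3))
        track = compute_cleavage_score(prof, min_cov=20)
        assert track.masked["x"].all()


class TestCallSites:
    def _sim_calls(self, cfg):
        species, truth = m.simulate_trna_reference(cfg)
        treated, inputlib = m.simulate_tracseq_reads(species, truth, cfg)
        prof = EndCountProfile(
            treated=align_small_rna(treated, species),
            input=align_small_rna(inputlib, species),
            lengths={sp.id: len(sp.sequence) for sp in species},
        )
        return species, truth, compute_cleavage_score(prof)

    def test_empty_track_yields_no_calls(self):
        track = compute_cleavage_score(
            _profile_pair(4, ([0] * 4, [0] * 4, [0] * 4), ([0] * 4, [0] * 4, [0] * 4))
        )
        assert call_sites(track, [_sp("x", "GGGG", site=1)]) == []

    def test_non_g_positions_never_called(self):
        # strong treated evidence at position 2, but the base there is T
        prof = _profile_pair(
            5,
            ([0, 0, 0, 90, 0], [0, 90, 0, 0, 0], [100, 100, 10, 100, 100]),
            ([0] * 5, [0] * 5, [100] * 5),
        )
        track = compute_cleavage_score(prof)
        assert call_sites(track, [_sp("x", "AATAA", site=2)]) == []

    def test_raising_thresholds_never_adds_calls(self, small_cfg):
        species, truth = m.simulate_trna_reference(small_cfg)
        treated, inputlib = m.simulate_tracseq_reads(species, truth, small_cfg)
        prof = EndCountProfile(
            treated=align_small_rna(treated, species),
            input=align_small_rna(inputlib, species),
            lengths={sp.id: len(sp.sequence) for sp in species},
        )
        track = compute_cleavage_score(prof, min_cov=20)
        prev = {(c.species_id, c.position) for c in call_sites(track, species, threshold=1.0)}
        for thr in (2.0, 4.0):
            calls = {(c.species_id, c.position) for c in call_sites(track, species, threshold=thr)}
            assert calls <= prev
            prev = calls
        # stricter coverage masking is monotone too
        loose = {(c.species_id, c.position) for c in call_sites(track, species)}
        track_hi = compute_cleavage_score(prof, min_cov=200)
        strict = {(c.species_id, c.position) for c in call_sites(track_hi, species)}
        assert strict <= loose

    def test_length_mismatch_rejected(self):
        prof = _profile_pair(4, ([0] * 4, [0] * 4, [50] * 4), ([0] * 4, [0] * 4, [50] * 4))
        track = compute_cleavage_score(prof)
        with pytest.raises(ValidationError, match="mismatch"):
            call_sites(track, [_sp("x", "GGGGG", site=1)])


class TestMotif:
    def _call(self, ctx):
        return M7GSiteCall(
            species_id=f"s{ctx}", position=45, score=5.0, coverage=100, q_value=0.0, context=ctx
        )

    def test_uniform_contexts_give_exact_consensus(self):
        cons, pfm = extract_motif([self._call("AAGGT")] * 4)
        assert cons == "AAGGT"
        assert np.allclose(pfm.sum(axis=0), 1.0)

    def test_mixed_purine_start_gives_iupac_r(self):
        calls = [self._call("AAGGT"), self._call("GAGGT")]
        cons, pfm = extract_motif(calls * 3)
        assert cons == "RAGGT"
        cons_rna, _ = extract_motif(calls * 3, rna=True)
        assert cons_rna == "RAGGU"
        assert np.allclose(pfm.sum(axis=0), 1.0)

    def test_no_calls_is_an_error(self):
        with pytest.raises(ValidationError):
            extract_motif([])


class TestAbundance:
    def test_identical_libraries_unchanged(self):
        counts = pd.DataFrame(
            {"rep1": [100, 220, 310], "rep2": [104, 212, 305]},
            index=pd.Index(["a", "b", "c"], name="species"),
        )
        tab = quantify_trna_abundance(counts, counts)
        assert np.allclose(tab["log2fc"], 0.0)
        assert not tab["downregulated"].any()

    def test_cpm_normalisation_sums_to_million(self, small_cfg):
        species, truth = m.simulate_trna_reference(small_cfg)
        ko = m.simulate_trna_counts(species, truth, small_cfg, "KO")
        cpm = ko / ko.sum(axis=0) * 1e6
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_planted_fold_change_recovered(self, default_cfg, reference_truth):
        species, truth = reference_truth
        ko = m.simulate_trna_counts(species, truth, default_cfg, "KO")
        ctrl = m.simulate_trna_counts(species, truth, default_cfg, "CTRL")
        tab = quantify_trna_abundance(ko, ctrl)
        m7g = sorted(truth.m7g_ids)
        assert abs(tab.loc[m7g, "log2fc"].mean() - (-1.0)) <= 0.2

    def test_zero_total_library_rejected(self):
        counts = pd.DataFrame({"rep1": [0, 0]}, index=["a", "b"])
        ok = pd.DataFrame({"rep1": [5, 5]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            quantify_trna_abundance(counts, ok)

    def test_species_read_counts_reduces_profile(self):
        ref = [_sp("a", SEQ_A), _sp("b", SEQ_B)]
        prof = align_small_rna([SEQ_A, SEQ_A, SEQ_B], ref)
        counts = species_read_counts(prof)
        assert counts["a"] == 2 and counts["b"] == 1
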