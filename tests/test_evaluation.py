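"""Truth calling against reference profiles and metric computation."""

import itertools

import numpy as np
import pytest

from snacs.core_io import DemuxCall, GenotypeMatrix, ValidationError, MULTIPLET, NO_CALL, FILTERED
from snacs.evaluation import (AMBIGUOUS, SINGLET, ReferenceProfiles, TruthCall,
                              build_reference_profiles, score_demux,
                              truth_call_cell, truth_calls_for_matrix)
from snacs.synthesis import SimConfig, simulate_multiplexed


def _ref_matrix(sample, profile, n_cells=300, rare_extra=None):
    """Single-sample reference: profile replicated, optional rare variant."""
    vals = np.tile(profile, (n_cells, 1)).astype(float)
    if rare_extra is not None:
        snp, frac = rare_extra
        vals[: int(frac * n_cells), snp] = 1.0
    return GenotypeMatrix([f"{sample}_{i}" for i in range(n_cells)],
                          [f"s{j}" for j in range(len(profile))], vals)


class TestReferenceProfiles:
    def test_prevalence_rule(self):
        # s3 mutated in 1% of A cells -> present; s4 in 0.3% -> absent
        A = _ref_matrix("A", [1, 0, 0, 0, 0], rare_extra=(3, 0.01))
        A.values[: int(0.003 * 300), 4] = 1.0
        B = _ref_matrix("B", [0, 1, 0, 0, 0])
        refs = build_reference_profiles({"A": A, "B": B})
        a = dict(zip(refs.snp_ids, refs.profile("A")))
        assert a["s3"] and not a["s4"]

    def test_ungenotyped_snp_excluded(self):
        A = _ref_matrix("A", [1, 0, 0])
        B = _ref_matrix("B", [0, 1, 0])
        B.values[:, 2] = np.nan         # s2 never genotyped in B
        refs = build_reference_profiles({"A": A, "B": B})
        assert "s2" not in refs.snp_ids

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            build_reference_profiles({"A": _ref_matrix("A", [1, 0])})


class TestTruthCallCell:
    @pytest.fixture
    def refs(self):
        # A: s0,s1; B: s2,s3; C: s1,s4  over 6 shared SNPs
        present = np.array([
            [1, 1, 0, 0, 0, 0],
            [0, 0, 1, 1, 0, 0],
            [0, 1, 0, 0, 1, 0],
        ], dtype=bool)
        return ReferenceProfiles(["A", "B", "C"],
                                 [f"s{j}" for j in range(6)], present)

    def test_exact_profile_is_singlet(self, refs):
        g = {f"s{j}": v for j, v in enumerate([1, 1, 0, 0, 0, 0])}
        t = truth_call_cell(g, refs)
        assert t.kind == SINGLET and t.sample == "A"

    def test_union_of_two_profiles_is_multiplet(self, refs):
        g = {f"s{j}": v for j, v in enumerate([1, 1, 1, 1, 0, 0])}
        assert truth_call_cell(g, refs).kind == MULTIPLET

    def test_positive_snp_outside_references_is_ambiguous(self, refs):
        g = {f"s{j}": 0.0 for j in range(6)}
        g["s0"] = 1.0
        g["s99"] = 1.0                   # mutated, never genotyped in refs
        assert truth_call_cell(g, refs).kind == AMBIGUOUS

    def test_profile_matching_nothing_is_ambiguous(self, refs):
        g = {f"s{j}": v for j, v in enumerate([1, 0, 1, 0, 1, 0])}
        assert truth_call_cell(g, refs).kind == AMBIGUOUS

    def test_missing_snps_ignored_in_match(self, refs):
        # s5 missing: the A match is judged on the five observed SNPs only
        g = {"s0": 1.0, "s1": 1.0, "s2": 0.0, "s3": 0.0,
             "s4": 0.0, "s5": np.nan}
        t = truth_call_cell(g, refs)
        assert t.kind == SINGLET and t.sample == "A"

    def test_union_on_observed_snps_beats_partial_singlet_match(self, refs):
        # with s4 unobserved, A and A-union-C coincide on the observed SNPs,
        # so the cell is reconstructable from two samples -> multiplet
        g = {"s0": 1.0, "s1": 1.0, "s2": 0.0, "s3": 0.0,
             "s4": np.nan, "s5": 0.0}
        assert truth_call_cell(g, refs).kind == MULTIPLET

    def test_agrees_with_literal_brute_force(self, refs):
        """Oracle: literally apply the three clauses by enumeration over all
        3^6 genotypes on the 6-SNP, 3-sample reference set."""
        samples = refs.sample_ids
        P = refs.present

        def oracle(gvec):
            obs = [(j, int(v)) for j, v in enumerate(gvec) if not np.isnan(v)]
            if not obs:
                return AMBIGUOUS, None
            def matches(si):
                return all(P[si, j] == bool(v) for j, v in obs)
            def union_matches(combo):
                return all(any(P[si, j] for si in combo) == bool(v)
                           for j, v in obs)
            exact = [si for si in range(len(samples)) if matches(si)]
            unions = [c for r in (2, 3)
                      for c in itertools.combinations(range(len(samples)), r)
                      if union_matches(c)]
            if len(exact) == 1 and not unions:
                return SINGLET, samples[exact[0]]
            if unions:
                return MULTIPLET, None
            return AMBIGUOUS, None

        for gvec in itertools.product([0.0, 1.0, np.nan], repeat=6):
            g = {f"s{j}": v for j, v in enumerate(gvec)}
            got = truth_call_cell(g, refs, max_subset=3)
            want_kind, want_sample = oracle(np.array(gvec))
            assert (got.kind, got.sample) == (want_kind, want_sample), gvec

    def test_synthesis_truth_recovered_from_noiseless_references(self):
        """Generator truth reproduced by truth calling against noiseless
        single-sample references for >= 99% of non-ambiguous cells."""
        cfg = SimConfig(S=3, C=900, p=0.15, dropout_rate=0.05, seed=11)
        exp = simulate_multiplexed(cfg)
        from snacs.synthesis import generate_patient_profiles
        prof = generate_patient_profiles(3, cfg,
                                         np.random.default_rng(cfg.seed))

        def ref_matrix(sample, profile):
            vals = np.tile(profile, (50, 1)).astype(float)
            return GenotypeMatrix([f"{sample}_{i}" for i in range(50)],
                                  list(prof.snp_ids), vals)

        refs_G = {s: ref_matrix(s, prof.profiles[i])
                  for i, s in enumerate(prof.sample_ids)}
        refs = build_reference_profiles(refs_G)
        truths = truth_calls_for_matrix(exp.genotypes, refs, max_subset=2)
        expected = exp.truth_by_cell()
        agree = n = 0
        for t in truths:
            if t.kind == AMBIGUOUS:
                continue
            n += 1
            e = expected[t.cell_id]
            agree += (t.kind == e.kind and t.sample == e.sample)
        assert n > 0.5 * len(truths)
        assert agree / n >= 0.99


class TestScoreDemux:
    def _toy(self):
        """8 true singlets (6 right, 1 wrong sample, 1 called multiplet)
        + 2 true multiplets (1 called multiplet, 1 called singlet)."""
        truths = [TruthCall(f"c{i}", SINGLET, "A") for i in range(8)]
        truths += [TruthCall("c8", MULTIPLET), TruthCall("c9", MULTIPLET)]
        calls = [DemuxCall(f"c{i}", "A") for i in range(6)]
        calls += [DemuxCall("c6", "B"), DemuxCall("c7", MULTIPLET),
                  DemuxCall("c8", MULTIPLET), DemuxCall("c9", "A")]
        return calls, truths

    def test_hand_counted_confusion_table(self):
        rep = score_demux(*self._toy())
        assert rep.total_accuracy == pytest.approx(7 / 10)
        assert rep.sensitivity == pytest.approx(1 / 2)
        assert rep.specificity == pytest.approx(7 / 8)
        assert rep.alt_singlet_fraction == pytest.approx(1 / 7)

    def test_perfect_calls(self):
        truths = [TruthCall("a", SINGLET, "A"), TruthCall("b", MULTIPLET)]
        calls = [DemuxCall("a", "A"), DemuxCall("b", MULTIPLET)]
        rep = score_demux(calls, truths)
        assert rep.total_accuracy == rep.sensitivity == rep.specificity == 1.0
        assert rep.alt_singlet_fraction == 0.0

    def test_all_filtered_undefined_metrics(self):
        truths = [TruthCall("a", SINGLET, "A")]
        calls = [DemuxCall("a", FILTERED)]
        rep = score_demux(calls, truths)
        assert np.isnan(rep.total_accuracy)
        assert rep.pct_filtered == 1.0

    def test_ambiguous_and_filtered_excluded(self):
        truths = [TruthCall("a", SINGLET, "A"), TruthCall("b", AMBIGUOUS),
                  TruthCall("c", SINGLET, "A")]
        calls = [DemuxCall("a", "A"), DemuxCall("b", "B"),
                 DemuxCall("c", FILTERED)]
        rep = score_demux(calls, truths)
        assert rep.n_evaluated == 1
        assert rep.total_accuracy == 1.0
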