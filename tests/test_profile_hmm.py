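"""Profile-HMM construction, scoring and calibration."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shikscreen.alphabet import AMINO_ACIDS, BACKGROUND, encode_sequence
from shikscreen.errors import CalibrationError, NoMatchStatesError, NotCalibratedError
from shikscreen.msa import Alignment
from shikscreen.profile_hmm import (
    ScoredAlignment,
    build_profile,
    calibrate,
    coverage,
    evalue,
    forward_score,
    profile_from_dict,
    profile_to_dict,
    viterbi_score,
)

from .oracles import brute_forward, brute_viterbi, random_profile


class TestBuildProfile:
    def test_identical_rows_zero_pseudocount(self):
        hmm = build_profile(Alignment(("ACD",) * 3), pseudocount_weight=0.0)
        assert hmm.length == 3
        assert hmm.match_emissions[0][AMINO_ACIDS.index("A")] == 1.0
        assert hmm.match_emissions[2][AMINO_ACIDS.index("D")] == 1.0

    def test_pseudocount_closed_form(self, uniform_bg):
        # column {A, A, C}, weight 1: P(A) = (2 + 1/20) / (3 + 1)
        hmm = build_profile(
            Alignment(("A", "A", "C")), pseudocount_weight=1.0, background=uniform_bg
        )
        assert hmm.match_emissions[0][0] == pytest.approx(0.5125)

    def test_majority_gap_column_is_insert(self):
        rows = ("AC-D", "AC-D", "ACWD", "AC-D")
        hmm = build_profile(Alignment(rows))
        assert hmm.length == 3  # column 2 has 3/4 gaps -> insert column

    def test_half_gap_column_is_match(self):
        rows = ("A-D", "A-D", "ACD", "ACD")
        hmm = build_profile(Alignment(rows))
        assert hmm.length == 3  # exactly 50% gaps stays a match column

    def test_all_gap_alignment_raises(self):
        with pytest.raises(NoMatchStatesError):
            build_profile(Alignment(("---", "---", "A--")))

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            Alignment(())
        with pytest.raises(ValueError):
            build_profile(Alignment(("ACD",)), pseudocount_weight=-1.0)

    @given(
        rows=st.lists(
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWY-", min_size=6, max_size=6),
            min_size=2,
            max_size=8,
        ),
        w=st.floats(min_value=0.0, max_value=5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_distributions_normalized(self, rows, w):
        """Every emission and transition row sums to 1 for any input."""
        try:
            hmm = build_profile(Alignment(tuple(rows)), pseudocount_weight=w)
        except NoMatchStatesError:
            return
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(hmm.t_mm + hmm.t_mi + hmm.t_md, 1.0, atol=1e-9)
        assert np.allclose(hmm.t_im + hmm.t_ii, 1.0, atol=1e-9)
        assert np.allclose(hmm.t_dm + hmm.t_dd, 1.0, atol=1e-9)


class TestScoring:
    def test_deterministic_consensus_closed_form(self, uniform_bg):
        """A profile emitting 'MK' with probability one scores the sequence
        'MK' at 2 log2(20) plus the fixed entry/exit term."""
        hmm = build_profile(
            Alignment(("MK",) * 3), pseudocount_weight=0.0, background=uniform_bg
        )
        sa = viterbi_score(hmm, "MK")
        expected = 2 * math.log2(20.0) + hmm.entry_bits
        assert sa.bit_score == pytest.approx(expected, abs=1e-9)
        assert sa.seq_span == (0, 2)
        assert sa.model_span == (0, 2)

    def test_oracle_equivalence_smoke(self):
        """DP equals exhaustive path enumeration on random tiny models
        (the full 200-instance sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            hmm = random_profile(rng, int(rng.integers(1, 5)))
            codes = rng.integers(0, 20, size=int(rng.integers(1, 7))).astype(np.int64)
            assert hmm._viterbi_codes(codes).bit_score == pytest.approx(
                brute_viterbi(hmm, codes), abs=1e-9
            )
            assert hmm._forward_codes(codes) == pytest.approx(
                brute_forward(hmm, codes), abs=1e-9
            )

    def test_forward_at_least_viterbi(self):
        """Log-sum over paths can never fall below the best path."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            hmm = random_profile(rng, int(rng.integers(1, 6)))
            codes = rng.integers(0, 20, size=int(rng.integers(1, 12))).astype(np.int64)
            assert hmm._forward_codes(codes) >= hmm._viterbi_codes(codes).bit_score - 1e-9

    def test_single_path_forward_equals_viterbi(self, uniform_bg):
        hmm = build_profile(
            Alignment(("W",) * 2), pseudocount_weight=0.0, background=uniform_bg
        )
        assert forward_score(hmm, "W") == pytest.approx(
            viterbi_score(hmm, "W").bit_score, abs=1e-12
        )

    def test_flanking_background_is_neutral(self, small_families, small_profiles):
        """Residues outside the aligned region do not change the score:
        exactly for Viterbi, within 1e-6 bits for forward."""
        hmm = small_profiles["aroG"]
        core = small_families.consensus["aroG"]
        v0 = viterbi_score(hmm, core).bit_score
        f0 = forward_score(hmm, core)
        flanked = "X" * 8 + core + "X" * 8
        assert viterbi_score(hmm, flanked).bit_score == pytest.approx(v0, abs=1e-9)
        # forward legitimately gains a little mass from near-null paths
        # that shift the alignment into the flank; it stays tiny
        assert forward_score(hmm, flanked) == pytest.approx(f0, abs=0.01)

    def test_unknown_residues_allowed(self, small_profiles):
        hmm = small_profiles["aroG"]
        assert np.isfinite(viterbi_score(hmm, "MXXBZAAAAKLLW").bit_score)

    @pytest.mark.parametrize("bad", ["", "ACD1F", "AC D"])
    def test_illegal_sequences_raise(self, bad, small_profiles):
        hmm = small_profiles["aroG"]
        with pytest.raises(ValueError):
            viterbi_score(hmm, bad)

    def test_error_names_offending_symbol(self):
        with pytest.raises(ValueError, match="'1'"):
            encode_sequence("AC1D")

    def test_consensus_outscores_background(self, small_families, small_profiles):
        """A family member at divergence 0 beats random sequences of the
        same length in at least 99% of trials."""
        hmm = small_profiles["aroG"]
        cons = small_families.consensus["aroG"]
        ref = viterbi_score(hmm, cons).bit_score
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(100):
            codes = rng.choice(20, size=len(cons), p=BACKGROUND).astype(np.int64)
            wins += ref > hmm._viterbi_codes(codes).bit_score
        assert wins >= 99


class TestCalibration:
    def test_same_seed_same_fit(self, small_profiles):
        hmm = small_profiles["aroC"]
        a = calibrate(hmm, 60, seed=3).calibration
        b = calibrate(hmm, 60, seed=3).calibration
        assert (a.mu, a.lam) == (b.mu, b.lam)

    def test_survival_at_mu(self, small_profiles):
        """At the Gumbel location the exceedance probability is 1 - 1/e."""
        cal = small_profiles["aroC"].calibration
        assert cal.survival(cal.mu) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_evalue_at_mu_scales_with_database(self, small_profiles):
        hmm = small_profiles["aroC"]
        mu = hmm.calibration.mu
        assert evalue(hmm, mu, 100) == pytest.approx(100 * (1 - math.exp(-1)))
        assert evalue(hmm, mu, 200) == pytest.approx(2 * evalue(hmm, mu, 100))

    def test_evalue_monotone_decreasing(self, small_profiles):
        """Strictly decreasing above the Gumbel location; in the deep left
        tail the survival function saturates at 1 in double precision."""
        hmm = small_profiles["aroC"]
        mu = hmm.calibration.mu
        scores = np.linspace(mu, mu + 120, 40)
        es = [evalue(hmm, s, 500) for s in scores]
        assert all(a > b for a, b in zip(es, es[1:]))
        low = [evalue(hmm, s, 500) for s in np.linspace(mu - 30, mu, 10)]
        assert all(a >= b for a, b in zip(low, low[1:]))

    def test_uncalibrated_profile_raises(self, uniform_bg):
        hmm = build_profile(Alignment(("MKLW",) * 3), background=uniform_bg)
        with pytest.raises(NotCalibratedError):
            evalue(hmm, 10.0, 100)

    def test_degenerate_distribution_raises(self):
        # a one-state profile emitting the background scores every
        # sequence identically -> zero variance
        hmm = build_profile(Alignment(tuple("A" for _ in range(2))), pseudocount_weight=0.0)
        hmm.match_emissions[:] = BACKGROUND
        hmm._logs = None
        with pytest.raises(CalibrationError):
            calibrate(hmm, 50, seed=0)

    def test_min_samples_enforced(self, small_profiles):
        with pytest.raises(ValueError):
            calibrate(small_profiles["aroC"], 10, seed=0)


class TestCoverage:
    def test_model_coverage(self, small_profiles):
        hmm = small_profiles["aroG"]
        L = hmm.length
        full = ScoredAlignment(10.0, (0, L), (0, L))
        part = ScoredAlignment(10.0, (0, 9), (0, 9))
        assert coverage(full, hmm) == 1.0
        assert coverage(part, hmm) == pytest.approx(9 / L)

    def test_coverage_ignores_flanks(self, small_families, small_profiles):
        hmm = small_profiles["aroG"]
        cons = small_families.consensus["aroG"]
        bare = viterbi_score(hmm, cons)
        flanked = viterbi_score(hmm, "W" * 30 + cons + "W" * 30)
        assert coverage(flanked, hmm) == pytest.approx(coverage(bare, hmm))

    def test_sequence_mode(self, small_profiles):
        hmm = small_profiles["aroG"]
        sa = ScoredAlignment(10.0, (5, 45), (0, hmm.length))
        assert coverage(sa, hmm, mode="sequence", seq_length=100) == pytest.approx(0.4)
        with pytest.raises(ValueError):
            coverage(sa, hmm, mode="sequence")


def test_json_roundtrip_preserves_scores(small_families, small_profiles):
    hmm = small_profiles["aroK_model1"]
    clone = profile_from_dict(profile_to_dict(hmm))
    seq = small_families.consensus["aroK_model1"]
    assert viterbi_score(clone, seq).bit_score == pytest.approx(
        viterbi_score(hmm, seq).bit_score, abs=1e-12
    )
    assert clone.calibration.mu == hmm.calibration.mu
    assert clone.calibration.lam == hmm.calibration.lam
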