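"""Hit filtering, proteome screening and nucleotide mode."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shikscreen.screening import (
    GenomeCall,
    Hit,
    Thresholds,
    filter_hits,
    orf_segments,
    screen_nucleotide,
    screen_proteome,
    six_frame_translate,
)
from shikscreen.synthetic import GenomeTruth, make_proteome

from .test_pathway import mkhit

# one codon per amino acid, for reverse-translating test proteins
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def reverse_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def _truth(genome_id, steps, genes, n_decoys=0, **kw):
    return GenomeTruth(
        genome_id=genome_id,
        domain="Bacteria",
        lifestyle="free_living",
        culturable=True,
        present_steps=frozenset(steps),
        planted_genes=tuple(genes),
        n_decoys=n_decoys,
        **kw,
    )


ALL_GENES = ("aroG", "aroB_type1", "aroD", "aroE", "aroK_model1", "aroA", "aroC")


class TestFilterHits:
    @pytest.mark.parametrize(
        "score,e,cov,kept",
        [
            (51.0, 1e-9, 0.95, True),
            (50.0, 1e-12, 1.0, False),  # score not strictly > 50
            (80.0, 1e-20, 0.90, False),  # coverage not strictly > 0.90
            (80.0, 1e-8, 0.95, False),  # E not strictly < 1e-8
            (50.0001, 9.9e-9, 0.9001, True),
        ],
    )
    def test_strict_boundaries(self, score, e, cov, kept):
        hits = [mkhit("p", "aroC", score, e=e, cov=cov)]
        assert (len(filter_hits(hits, Thresholds())) == 1) is kept

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(1e-30, 1.0),
                st.floats(0, 1),
            ),
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_subset(self, triples):
        hits = [
            mkhit(f"p{i}", "aroC", s, e=e, cov=c)
            for i, (s, e, c) in enumerate(triples)
        ]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert set(h.protein_id for h in once) <= set(h.protein_id for h in hits)


class TestScreenProteome:
    def test_planted_full_pathway_recovered_at_zero_divergence(
        self, small_families, small_profiles
    ):
        truth = _truth("gfull", range(1, 8), ALL_GENES)
        proteome = make_proteome(truth, small_families.consensus, d_emit=0.0, seed=0)
        call = screen_proteome(proteome, small_profiles, genome_id="gfull")
        assert call.complete
        assert call.missing_steps == frozenset()

    def test_deleting_dahp_synthase_loses_step_1(
        self, small_families, small_profiles
    ):
        truth = _truth("gno1", range(2, 8), ALL_GENES[1:])
        proteome = make_proteome(truth, small_families.consensus, d_emit=0.0, seed=0)
        call = screen_proteome(proteome, small_profiles, genome_id="gno1")
        assert not call.complete
        assert call.missing_steps == frozenset({1})

    def test_empty_proteome_warns(self, small_profiles):
        call = screen_proteome([], small_profiles, genome_id="empty")
        assert not call.complete
        assert call.n_missing == 7
        assert "empty proteome" in call.warnings

    def test_order_and_linewrap_invariance(
        self, small_families, small_profiles, tmp_path
    ):
        truth = _truth("g", range(1, 8), ALL_GENES, n_decoys=5)
        proteome = make_proteome(truth, small_families.consensus, d_emit=0.1, seed=4)
        a = tmp_path / "a.faa"
        b = tmp_path / "b.faa"
        with open(a, "w") as fh:
            for pid, seq in proteome:
                fh.write(f">{pid}\n{seq}\n")
        with open(b, "w") as fh:  # reversed order, wrapped at 37 columns
            for pid, seq in reversed(proteome):
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 37):
                    fh.write(seq[i : i + 37] + "\n")
        ca = screen_proteome(a, small_profiles, genome_id="g")
        cb = screen_proteome(b, small_profiles, genome_id="g")
        assert ca.missing_steps == cb.missing_steps
        assert ca.complete == cb.complete
        assert sorted((h.protein_id, h.profile_id) for h in ca.hits) == sorted(
            (h.protein_id, h.profile_id) for h in cb.hits
        )

    def test_stricter_thresholds_never_rescue_a_genome(
        self, small_families, small_profiles
    ):
        """Raising min_score, lowering max_evalue or raising min_coverage
        can only lose steps, never gain them."""
        truth = _truth("g", range(1, 8), ALL_GENES, n_decoys=3)
        proteome = make_proteome(truth, small_families.consensus, d_emit=0.25, seed=9)
        base = screen_proteome(proteome, small_profiles, genome_id="g")
        for t in (
            Thresholds(min_score=120.0),
            Thresholds(max_evalue=1e-30),
            Thresholds(min_coverage=0.99),
            Thresholds(min_score=120.0, max_evalue=1e-30, min_coverage=0.99),
        ):
            strict = screen_proteome(proteome, small_profiles, t=t, genome_id="g")
            assert base.missing_steps <= strict.missing_steps
            assert not (strict.complete and not base.complete)

    def test_decoy_only_proteomes_never_complete(self, small_profiles):
        from shikscreen.synthetic import _draw_background_seq
        from shikscreen.alphabet import BACKGROUND

        for seed in range(3):
            rng = np.random.default_rng(seed)
            proteome = [
                (f"d{i}", _draw_background_seq(rng, int(rng.lognormal(np.log(120), 0.4)) + 30, BACKGROUND))
                for i in range(100)
            ]
            call = screen_proteome(proteome, small_profiles, genome_id=f"decoy{seed}")
            assert call.n_missing == 7
            assert not call.hits


class TestSixFrameTranslate:
    def test_codon_table(self):
        assert six_frame_translate("ATGAAA")[0] == "MK"

    def test_stop_codons_separate_segments(self):
        frames = six_frame_translate("ATGAAATAAATGGGG")
        assert frames[0] == "MK*MG"
        assert orf_segments(frames[0], min_length=2) == ["MG"] or orf_segments(
            frames[0], min_length=2
        ) == ["MK", "MG"]

    def test_illegal_nucleotide_raises(self):
        with pytest.raises(ValueError, match="'U'"):
            six_frame_translate("AUG")

    @given(st.text(alphabet="ACGT", min_size=3, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_reverse_complement_symmetry_and_lengths(self, s):
        comp = str.maketrans("ACGT", "TGCA")
        rc = s.translate(comp)[::-1]
        f = six_frame_translate(s)
        g = six_frame_translate(rc)
        # frame -1 of s is frame +1 of revcomp(s)
        assert f[3] == g[0]
        assert g[3] == f[0]
        # residue bookkeeping: each offset contributes floor((n-off)/3)
        n = len(s)
        expected = 2 * sum((n - off) // 3 for off in range(3))
        assert sum(len(fr) for fr in f) == expected


class TestScreenNucleotide:
    def test_planted_gene_detected_through_translation(
        self, small_families, small_profiles
    ):
        rng = np.random.default_rng(3)
        cons = small_families.consensus["aroC"]
        junk = "".join(rng.choice(list("ACGT"), size=210))
        dna = junk + "TAA" + reverse_translate(cons) + "TAA" + junk
        call = screen_nucleotide(dna, small_profiles, genome_id="nt")
        assert 7 not in call.missing_steps

    def test_random_dna_yields_nothing(self, small_profiles):
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            dna = "".join(rng.choice(list("ACGT"), size=9000))
            call = screen_nucleotide(dna, small_profiles, genome_id="rand")
            assert call.n_missing == 7

    def test_partial_domain_fails_coverage_not_score(
        self, small_families, small_profiles
    ):
        """Half an enzyme scores well but is rejected by the coverage
        filter — the screen's guard against partial-domain matches."""
        cons = small_families.consensus["aroK_model1"]
        half = cons[: len(cons) // 2]
        dna = "TAA" + reverse_translate(half) + "TAA"
        call = screen_nucleotide(
            dna, {"aroK_model1": small_profiles["aroK_model1"]},
            genome_id="half",
        )
        assert 5 in call.missing_steps
        # the alignment itself is strong: relax only the coverage filter
        relaxed = screen_nucleotide(
            dna,
            {"aroK_model1": small_profiles["aroK_model1"]},
            t=Thresholds(min_coverage=0.0),
            genome_id="half",
        )
        assert 5 not in relaxed.missing_steps


def test_genome_call_invariants_enforced():
    with pytest.raises(ValueError):
        GenomeCall(
            genome_id="g",
            step_calls=(),
            complete=True,
            n_missing=1,
            missing_steps=frozenset({1}),
        )
    call = GenomeCall.from_missing("g", {2, 5})
    assert call.n_missing == 2 and not call.complete
    assert call.missing_steps == frozenset({2, 5})
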