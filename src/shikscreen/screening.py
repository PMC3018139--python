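"""Per-proteome screening: score, filter, evaluate, classify.

For each proteome every profile is aligned to every protein; E-values
use the number of proteins in that proteome as the database size
(per-proteome search semantics). Hits are filtered by the screening
thresholds — bit score strictly above 50, E-value strictly below 1e-8,
and profile coverage strictly above 90% — and surviving hits drive the
pathway-step evaluation and the genome completeness call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ShikscreenError
from .pathway import PathwayDefinition, StepCall, default_pathway, evaluate_steps
from .profile_hmm import ProfileHMM, coverage, evalue, viterbi_score

logger = logging.getLogger(__name__)

#: Proteins shorter than this are skipped with a warning.
MIN_PROTEIN_LENGTH = 10

#: Minimum ORF segment length (residues) retained in nucleotide mode.
MIN_ORF_LENGTH = 30

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Hit:
    """A scored profile-vs-protein match."""

    protein_id: str
    profile_id: str
    bit_score: float
    e_value: float
    coverage: float
    seq_span: tuple[int, int]
    model_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must be in [0, 1]")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass(frozen=True)
class Thresholds:
    """Hit-filtering thresholds; all three inequalities are strict."""

    min_score: float = 50.0
    max_evalue: float = 1e-8
    min_coverage: float = 0.90

    def __post_init__(self) -> None:
        if not self.max_evalue > 0:
            raise ValueError("max_evalue must be > 0")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in [0, 1]")

    def accepts(self, hit: Hit) -> bool:
        return (
            hit.bit_score > self.min_score
            and hit.e_value < self.max_evalue
            and hit.coverage > self.min_coverage
        )


@dataclass(frozen=True)
class GenomeCall:
    """Per-genome pathway-completeness classification."""

    genome_id: str
    step_calls: tuple[StepCall, ...]
    complete: bool
    n_missing: int
    missing_steps: frozenset[int]
    rescues: tuple[tuple[int, str], ...] = ()  # (step, variant_id)
    hits: tuple[Hit, ...] = ()  # threshold-surviving hits
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.complete != (self.n_missing == 0):
            raise ValueError("complete must mean n_missing == 0")
        if self.n_missing != len(self.missing_steps):
            raise ValueError("missing_steps inconsistent with n_missing")

    @classmethod
    def from_step_calls(
        cls,
        genome_id: str,
        step_calls: Sequence[StepCall],
        hits: Sequence[Hit] = (),
        warnings: Sequence[str] = (),
    ) -> "GenomeCall":
        missing = frozenset(c.step for c in step_calls if not c.satisfied_canonical)
        rescues = tuple(
            (c.step, c.rescue_by_alternative)
            for c in step_calls
            if c.rescue_by_alternative is not None
        )
        return cls(
            genome_id=genome_id,
            step_calls=tuple(step_calls),
            complete=not missing,
            n_missing=len(missing),
            missing_steps=missing,
            rescues=rescues,
            hits=tuple(hits),
            warnings=tuple(warnings),
        )

    @classmethod
    def from_missing(
        cls, genome_id: str, missing: Iterable[int], n_steps: int = 7
    ) -> "GenomeCall":
        """Build a bare call from a set of missing steps (no hit detail);
        used when converting planted truth or parsed tables to calls."""
        missing = frozenset(missing)
        step_calls = tuple(
            StepCall(step=s, satisfied_canonical=s not in missing)
            for s in range(1, n_steps + 1)
        )
        return cls.from_step_calls(genome_id, step_calls)


def filter_hits(hits: Iterable[Hit], t: Thresholds | None = None) -> list[Hit]:
    """Retain exactly the hits passing all three strict thresholds."""
    t = t or Thresholds()
    return [h for h in hits if t.accepts(h)]


def _load_proteome(
    proteome: str | Path | Iterable[tuple[str, str]],
) -> list[tuple[str, str]]:
    if isinstance(proteome, (str, Path)):
        try:
            records = [
                (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(proteome), "fasta")
            ]
        except OSError as exc:
            raise ShikscreenError(f"cannot read proteome {proteome}: {exc}") from exc
        return records
    return [(pid, seq) for pid, seq in proteome]


def score_proteome(
    proteins: Sequence[tuple[str, str]],
    profiles: Mapping[str, ProfileHMM],
    coverage_mode: str = "model",
) -> tuple[list[Hit], list[str]]:
    """Score every (profile, protein) pair; returns raw (unfiltered) hits.

    E-values use the number of scored proteins as the database size.
    Proteins shorter than MIN_PROTEIN_LENGTH are skipped with a warning.
    """
    kept = [(pid, s) for pid, s in proteins if len(s) >= MIN_PROTEIN_LENGTH]
    notes = []
    n_short = len(proteins) - len(kept)
    if n_short:
        notes.append(f"skipped {n_short} proteins shorter than {MIN_PROTEIN_LENGTH} aa")
        logger.warning(notes[-1])
    db_size = len(kept)
    hits: list[Hit] = []
    for profile_id, hmm in profiles.items():
        for pid, seq in kept:
            sa = viterbi_score(hmm, seq)
            hits.append(
                Hit(
                    protein_id=pid,
                    profile_id=profile_id,
                    bit_score=sa.bit_score,
                    e_value=evalue(hmm, sa.bit_score, db_size),
                    coverage=coverage(sa, hmm, mode=coverage_mode, seq_length=len(seq)),
                    seq_span=sa.seq_span,
                    model_span=sa.model_span,
                )
            )
    return hits, notes


def screen_proteome(
    proteome: str | Path | Iterable[tuple[str, str]],
    profiles: Mapping[str, ProfileHMM],
    pd: PathwayDefinition | None = None,
    t: Thresholds | None = None,
    genome_id: str | None = None,
    coverage_mode: str = "model",
) -> GenomeCall:
    """Screen one proteome end to end and classify its pathway.

    ``proteome`` may be a FASTA path or an iterable of (id, sequence)
    pairs. Profiles must be calibrated. Deterministic.
    """
    pd = pd or default_pathway()
    t = t or Thresholds()
    proteins = _load_proteome(proteome)
    if genome_id is None:
        genome_id = Path(proteome).stem if isinstance(proteome, (str, Path)) else "genome"
    if not proteins:
        step_calls = [
            StepCall(step=s.index, satisfied_canonical=False) for s in pd.steps
        ]
        return GenomeCall.from_step_calls(
            genome_id, step_calls, warnings=("empty proteome",)
        )
    raw, notes = score_proteome(proteins, profiles, coverage_mode=coverage_mode)
    surviving = filter_hits(raw, t)
    step_calls = evaluate_steps(surviving, pd)
    return GenomeCall.from_step_calls(genome_id, step_calls, hits=surviving, warnings=notes)


# -- nucleotide mode ---------------------------------------------------


def _validate_dna(dna: str) -> str:
    dna = dna.upper()
    bad = set(dna) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal nucleotide {sorted(bad)[0]!r} in DNA sequence")
    return dna


def six_frame_translate(dna: str) -> list[str]:
    """Translate a nucleotide string in all six reading frames.

    Frames are +1, +2, +3 then -1, -2, -3 (reverse complement). Stop
    codons are emitted as ``*`` so each frame string carries its ORF
    segments separated by stops; trailing partial codons are dropped.
    """
    dna = _validate_dna(dna)
    rc = dna.translate(_DNA_COMPLEMENT)[::-1]
    frames = []
    for strand in (dna, rc):
        for off in range(3):
            sub = strand[off : off + 3 * ((len(strand) - off) // 3)]
            frames.append(str(Seq(sub).translate()))
    return frames


def orf_segments(frame: str, min_length: int = MIN_ORF_LENGTH) -> list[str]:
    """Split a translated frame on stop codons; keep segments >= min_length."""
    return [seg for seg in frame.split("*") if len(seg) >= min_length]


def screen_nucleotide(
    dna: str | Path | Iterable[tuple[str, str]],
    profiles: Mapping[str, ProfileHMM],
    pd: PathwayDefinition | None = None,
    t: Thresholds | None = None,
    genome_id: str | None = None,
    min_orf_length: int = MIN_ORF_LENGTH,
    coverage_mode: str = "model",
) -> GenomeCall:
    """Six-frame-translate nucleotide input and screen the ORF segments.

    ``dna`` may be a FASTA path or an iterable of (id, sequence) pairs.
    """
    def _looks_like_path(obj) -> bool:
        if isinstance(obj, Path):
            return True
        if isinstance(obj, str) and len(obj) < 4096:
            try:
                return Path(obj).exists()
            except OSError:
                return False
        return False

    if _looks_like_path(dna):
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(dna), "fasta")]
        if genome_id is None:
            genome_id = Path(dna).stem
    elif isinstance(dna, str):
        records = [("dna", dna)]
    else:
        records = [(rid, s) for rid, s in dna]
    segments: list[tuple[str, str]] = []
    for rid, seq in records:
        for f, frame in enumerate(six_frame_translate(seq)):
            strand = "+" if f < 3 else "-"
            fnum = (f % 3) + 1
            for i, seg in enumerate(orf_segments(frame, min_orf_length)):
                segments.append((f"{rid}|{strand}{fnum}|orf{i}", seg))
    return screen_proteome(
        segments,
        profiles,
        pd,
        t,
        genome_id=genome_id or "nucleotide",
        coverage_mode=coverage_mode,
    )


# -- pipeline glue -----------------------------------------------------


def build_profiles(
    alignments: "Mapping[str, object]",
    pseudocount_weight: float = 1.0,
    calibrate_n: int = 200,
    seed: int = 0,
    length_distribution=None,
):
    """Build and calibrate one profile per alignment (dict id -> Alignment).

    Calibration seeds are derived per profile from ``seed`` so the result
    is reproducible and independent of dict ordering.
    """
    import numpy as np

    from .profile_hmm import build_profile, calibrate

    ss = np.random.SeedSequence(seed)
    ids = sorted(alignments)
    child = {
        pid: int(s.generate_state(1)[0] % (2**31)) for pid, s in zip(ids, ss.spawn(len(ids)))
    }
    profiles = {}
    for pid in ids:
        hmm = build_profile(alignments[pid], pseudocount_weight, name=pid)
        profiles[pid] = calibrate(
            hmm, calibrate_n, length_distribution=length_distribution, seed=child[pid]
        )
    return profiles


def screen_cohort(
    proteomes: Mapping[str, Iterable[tuple[str, str]]],
    profiles: Mapping[str, ProfileHMM],
    pd: PathwayDefinition | None = None,
    t: Thresholds | None = None,
    coverage_mode: str = "model",
) -> list[GenomeCall]:
    """Screen every proteome in a cohort; returns calls in genome-id order."""
    return [
        screen_proteome(
            proteomes[gid], profiles, pd, t, genome_id=gid, coverage_mode=coverage_mode
        )
        for gid in sorted(proteomes)
    ]


# -- tabular serialization --------------------------------------------


def write_calls(calls: Sequence[GenomeCall], path) -> None:
    """Write per-genome calls as TSV (one row per genome)."""
    with open(path, "w") as fh:
        fh.write("genome_id\tcomplete\tn_missing\tmissing_steps\trescues\n")
        for c in calls:
            rescues = ";".join(f"{s}:{v}" for s, v in c.rescues)
            fh.write(
                f"{c.genome_id}\t{str(c.complete).lower()}\t{c.n_missing}\t"
                f"{','.join(map(str, sorted(c.missing_steps)))}\t{rescues}\n"
            )


def read_calls(path) -> list[GenomeCall]:
    """Read a calls TSV back into bare GenomeCall objects."""
    import pandas as _pd

    df = _pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        missing = [int(x) for x in r["missing_steps"].split(",") if x]
        call = GenomeCall.from_missing(r["genome_id"], missing)
        if r.get("rescues"):
            rescues = tuple(
                (int(item.split(":")[0]), item.split(":")[1])
                for item in r["rescues"].split(";")
                if item
            )
            call = GenomeCall(
                genome_id=call.genome_id,
                step_calls=call.step_calls,
                complete=call.complete,
                n_missing=call.n_missing,
                missing_steps=call.missing_steps,
                rescues=rescues,
            )
        out.append(call)
    return out


def write_hits(calls: Sequence[GenomeCall], path) -> None:
    """Write all threshold-surviving hits as TSV (one row per hit)."""
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tprotein_id\tprofile_id\tbit_score\te_value\tcoverage\t"
            "seq_start\tseq_end\tmodel_start\tmodel_end\n"
        )
        for c in calls:
            for h in c.hits:
                fh.write(
                    f"{c.genome_id}\t{h.protein_id}\t{h.profile_id}\t"
                    f"{h.bit_score:.2f}\t{h.e_value:.3e}\t{h.coverage:.4f}\t"
                    f"{h.seq_span[0]}\t{h.seq_span[1]}\t"
                    f"{h.model_span[0]}\t{h.model_span[1]}\n"
                )
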