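"""Multiple sequence alignments: the input to profile construction."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import AlignIO

from .alphabet import AA_INDEX, AMBIGUOUS, GAP_CHARS


@dataclass(frozen=True)
class Alignment:
    """A gapped protein multiple sequence alignment.

    All rows must have the same length; the alphabet is the 20 standard
    amino acids plus gap characters ('-' or '.'); ambiguity codes are
    accepted and later scored at background.
    """

    sequences: tuple[str, ...]
    ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        seqs = tuple(s.upper() for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if not seqs:
            raise ValueError("alignment has no rows")
        width = len(seqs[0])
        if width == 0:
            raise ValueError("alignment has no columns")
        if any(len(s) != width for s in seqs):
            raise ValueError("alignment rows have unequal lengths")
        ids = self.ids or tuple(f"seq{i}" for i in range(len(seqs)))
        if len(ids) != len(seqs):
            raise ValueError("ids and sequences differ in count")
        object.__setattr__(self, "ids", tuple(ids))
        legal = set(AA_INDEX) | AMBIGUOUS | GAP_CHARS
        for rid, row in zip(ids, seqs):
            bad = set(row) - legal
            if bad:
                raise ValueError(
                    f"illegal characters {sorted(bad)} in alignment row {rid!r}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def n_cols(self) -> int:
        return len(self.sequences[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.sequences)


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    The format is inferred from the suffix when not given: ``.sto`` /
    ``.stk`` / ``.stockholm`` are Stockholm, everything else aligned
    FASTA.
    """
    path = Path(path)
    if fmt is None:
        fmt = (
            "stockholm"
            if path.suffix.lower() in {".sto", ".stk", ".stockholm"}
            else "fasta"
        )
    msa = AlignIO.read(str(path), fmt)
    return Alignment(
        sequences=tuple(str(rec.seq) for rec in msa),
        ids=tuple(rec.id for rec in msa),
    )


def write_alignment(aln: Alignment, path: str | Path, fmt: str = "fasta") -> None:
    path = Path(path)
    if fmt == "fasta":
        with open(path, "w") as fh:
            for rid, row in zip(aln.ids, aln.sequences):
                fh.write(f">{rid}\n{row}\n")
    elif fmt == "stockholm":
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            pad = max(len(i) for i in aln.ids) + 2
            for rid, row in zip(aln.ids, aln.sequences):
                fh.write(f"{rid:<{pad}}{row}\n")
            fh.write("//\n")
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")


def iter_alignment_files(directory: str | Path) -> Iterable[Path]:
    """Yield alignment files (FASTA / Stockholm) in a directory, sorted."""
    directory = Path(directory)
    exts = {".fa", ".fasta", ".afa", ".aln", ".sto", ".stk", ".stockholm"}
    for p in sorted(directory.iterdir()):
        if p.is_file() and p.suffix.lower() in exts:
            yield p
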