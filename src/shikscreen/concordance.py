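"""Concordance of pipeline completeness calls with a curated reference.

Agreement is on the binary complete/incomplete call per genome, computed
over the genomes present in both inputs; genomes found on only one side
are reported separately, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import percent_incomplete
from .errors import ConcordanceError
from .screening import GenomeCall


@dataclass(frozen=True)
class ReferenceCall:
    """A per-genome completeness call from an external curated annotation."""

    genome_id: str
    complete: bool
    source: str = "reference"


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 cross-tabulation of pipeline vs reference completeness calls."""

    n_evaluated: int
    n_agree: int
    agreement_pct: int
    both_complete: int
    both_incomplete: int
    reference_only_complete: int  # reference complete, pipeline incomplete
    pipeline_only_complete: int  # pipeline complete, reference incomplete
    pipeline_unmatched: tuple[str, ...] = ()  # genomes absent from reference
    reference_unmatched: tuple[str, ...] = ()  # genomes absent from pipeline

    def __post_init__(self) -> None:
        if self.n_agree != self.both_complete + self.both_incomplete:
            raise ValueError("n_agree must equal both_complete + both_incomplete")
        cells = (
            self.both_complete
            + self.both_incomplete
            + self.reference_only_complete
            + self.pipeline_only_complete
        )
        if cells != self.n_evaluated:
            raise ValueError("2x2 cells must sum to n_evaluated")


def _as_bool_map(calls, label: str) -> dict[str, bool]:
    if isinstance(calls, Mapping):
        return {str(k): bool(v) for k, v in calls.items()}
    out: dict[str, bool] = {}
    for c in calls:
        gid = c.genome_id
        if gid in out:
            raise ConcordanceError(f"duplicate genome_id in {label}: {gid!r}")
        out[gid] = bool(c.complete)
    return out


def compare_calls(
    pipeline: Sequence[GenomeCall] | Mapping[str, bool],
    reference: Sequence[ReferenceCall] | Mapping[str, bool],
) -> ConcordanceTable:
    """Cross-tabulate pipeline vs reference completeness calls.

    Restricted to genome ids present in both inputs; raises if the
    overlap is empty.
    """
    p = _as_bool_map(pipeline, "pipeline")
    r = _as_bool_map(reference, "reference")
    shared = sorted(set(p) & set(r))
    if not shared:
        raise ConcordanceError("no genomes shared between pipeline and reference")
    bc = bi = rc = pc = 0
    for gid in shared:
        if p[gid] and r[gid]:
            bc += 1
        elif not p[gid] and not r[gid]:
            bi += 1
        elif r[gid]:
            rc += 1
        else:
            pc += 1
    n = len(shared)
    n_agree = bc + bi
    return ConcordanceTable(
        n_evaluated=n,
        n_agree=n_agree,
        agreement_pct=percent_incomplete(n_agree, n),  # same rounding rule
        both_complete=bc,
        both_incomplete=bi,
        reference_only_complete=rc,
        pipeline_only_complete=pc,
        pipeline_unmatched=tuple(sorted(set(p) - set(r))),
        reference_unmatched=tuple(sorted(set(r) - set(p))),
    )


def read_reference_calls(path: str | Path) -> list[ReferenceCall]:
    """Read a reference annotation TSV (genome_id, complete[, source])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            ReferenceCall(
                genome_id=row["genome_id"],
                complete=str(row["complete"]).lower() in ("1", "true", "yes"),
                source=row.get("source", "reference") if "source" in df.columns else "reference",
            )
        )
    return out


def write_reference_calls(calls: Iterable[ReferenceCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"genome_id": c.genome_id, "complete": str(c.complete).lower(), "source": c.source}
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def concordance_to_frame(t: ConcordanceTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "n_evaluated": t.n_evaluated,
                "n_agree": t.n_agree,
                "agreement_pct": t.agreement_pct,
                "both_complete": t.both_complete,
                "both_incomplete": t.both_incomplete,
                "reference_only_complete": t.reference_only_complete,
                "pipeline_only_complete": t.pipeline_only_complete,
                "n_pipeline_unmatched": len(t.pipeline_unmatched),
                "n_reference_unmatched": len(t.reference_unmatched),
            }
        ]
    )
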