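"""Cohort-level aggregation of genome completeness calls.

Summaries mirror the layout of pan-genome screening reports: stratified
complete/incomplete tables with integer percentages, per-enzyme loss
distributions, missing-count histograms, single-loss profiles, and a
sliding-window gene-clustering check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import CohortError
from .screening import GenomeCall

N_STEPS = 7


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    domain: str  # "Bacteria" | "Archaea"
    lifestyle: str  # "free_living" | "host_associated"
    culturable: bool | None = None  # None = unknown

    def __post_init__(self) -> None:
        if self.domain not in ("Bacteria", "Archaea"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.lifestyle not in ("free_living", "host_associated"):
            raise ValueError(f"unknown lifestyle {self.lifestyle!r}")


def percent_incomplete(n_incomplete: int, n_total: int) -> int:
    """Integer percentage, rounded to nearest with ties away from zero."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_incomplete <= n_total:
        raise ValueError("need 0 <= n_incomplete <= n_total")
    return int(math.floor(100.0 * n_incomplete / n_total + 0.5))


Selector = Callable[[GenomeMetadata], bool]

#: Domain/lifestyle grouping: Total, Bacteria (split into free-living and
#: host-associated), Archaea.
GROUPING_DOMAIN: list[tuple[str, Selector]] = [
    ("Bacteria", lambda m: m.domain == "Bacteria"),
    ("Free living", lambda m: m.domain == "Bacteria" and m.lifestyle == "free_living"),
    ("Host-associated", lambda m: m.domain == "Bacteria" and m.lifestyle == "host_associated"),
    ("Archaea", lambda m: m.domain == "Archaea"),
]

#: Culturability split of host-associated Bacteria.
GROUPING_CULTURABILITY: list[tuple[str, Selector]] = [
    ("Culturable", lambda m: m.culturable is True),
    ("Non-culturable", lambda m: m.culturable is False),
]

GROUPINGS: dict[str, dict] = {
    "domain": {"rows": GROUPING_DOMAIN, "universe": lambda m: True},
    "culturability": {
        "rows": GROUPING_CULTURABILITY,
        "universe": lambda m: m.domain == "Bacteria"
        and m.lifestyle == "host_associated",
    },
}


def _meta_map(meta: Iterable[GenomeMetadata]) -> dict[str, GenomeMetadata]:
    out: dict[str, GenomeMetadata] = {}
    for m in meta:
        if m.genome_id in out:
            raise CohortError(f"duplicate genome_id in metadata: {m.genome_id!r}")
        out[m.genome_id] = m
    return out


def summarize_by_group(
    calls: Sequence[GenomeCall],
    meta: Iterable[GenomeMetadata],
    grouping: str | list[tuple[str, Selector]] = "domain",
    include_unknown: bool = False,
) -> pd.DataFrame:
    """Stratified completeness table with a leading Total row.

    ``grouping`` is a preset name ("domain", "culturability") or an
    explicit list of (label, selector) rows. For the culturability
    preset, genomes of unknown culturability get their own row only when
    ``include_unknown`` is set; the Total row always covers the whole
    universe.
    """
    if isinstance(grouping, str):
        spec = GROUPINGS[grouping]
        rows = list(spec["rows"])
        universe = spec["universe"]
        if grouping == "culturability" and include_unknown:
            rows.append(("Unknown", lambda m: m.culturable is None))
    else:
        rows = list(grouping)
        universe = lambda m: True  # noqa: E731

    mmap = _meta_map(meta)
    missing = [c.genome_id for c in calls if c.genome_id not in mmap]
    if missing:
        raise CohortError(f"calls without metadata: {missing}")

    scoped = [(c, mmap[c.genome_id]) for c in calls if universe(mmap[c.genome_id])]

    def _row(label: str, items: list[GenomeCall]) -> dict:
        n = len(items)
        n_complete = sum(c.complete for c in items)
        n_incomplete = n - n_complete
        return {
            "group": label,
            "n_total": n,
            "n_complete": n_complete,
            "n_incomplete": n_incomplete,
            "pct_incomplete": percent_incomplete(n_incomplete, n) if n else 0,
        }

    out = [_row("Total", [c for c, _ in scoped])]
    for label, sel in rows:
        out.append(_row(label, [c for c, m in scoped if sel(m)]))
    return pd.DataFrame(out)


def enzyme_loss_distribution(
    calls: Sequence[GenomeCall], n_steps: int = N_STEPS
) -> pd.Series:
    """Per-step count of genomes in which that step is unsatisfied."""
    counts = {s: 0 for s in range(1, n_steps + 1)}
    for c in calls:
        for s in c.missing_steps:
            counts[s] += 1
    return pd.Series(counts, name="n_missing").rename_axis("step")


def missing_count_histogram(
    calls: Sequence[GenomeCall], n_steps: int = N_STEPS
) -> pd.Series:
    """Histogram of the number of missing enzymes per genome (0..n_steps)."""
    counts = {k: 0 for k in range(n_steps + 1)}
    for c in calls:
        counts[c.n_missing] += 1
    return pd.Series(counts, name="n_genomes").rename_axis("n_missing")


def single_loss_profile(
    calls: Sequence[GenomeCall], n_steps: int = N_STEPS
) -> pd.Series:
    """Among genomes missing exactly one enzyme, which step is lost."""
    singles = [c for c in calls if c.n_missing == 1]
    return enzyme_loss_distribution(singles, n_steps).rename("n_genomes")


@dataclass(frozen=True)
class ClusteringResult:
    clustered: bool
    per_replicon: dict  # replicon -> max pathway-gene starts in any window
    window: int
    min_genes: int
    missing_gene_ids: tuple[str, ...] = ()


def assess_gene_clustering(
    coords: pd.DataFrame,
    pathway_gene_ids: set[str],
    window: int = 20_000,
    min_genes: int = 4,
) -> ClusteringResult:
    """Sliding-window test of whether pathway genes are physically clustered.

    ``coords`` needs columns ``replicon``, ``gene_id``, ``start``, ``end``
    with 1-based inclusive coordinates (converted internally to half-open).
    The statistic is, per replicon, the maximum number of pathway gene
    starts falling in any window of ``window`` bp; the genome is called
    clustered iff that maximum reaches ``min_genes`` anywhere.
    """
    required = {"replicon", "gene_id", "start", "end"}
    if not required <= set(coords.columns):
        raise ValueError(f"coordinate table needs columns {sorted(required)}")
    present = coords[coords["gene_id"].isin(pathway_gene_ids)]
    missing = tuple(sorted(pathway_gene_ids - set(coords["gene_id"])))
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "pathway genes absent from coordinate table: %s", ", ".join(missing)
        )
    per_replicon: dict = {}
    for rep, grp in present.groupby("replicon"):
        starts = sorted(int(s) - 1 for s in grp["start"])  # to 0-based half-open
        best = 0
        j = 0
        for i, w in enumerate(starts):
            while starts[j] < w:  # pragma: no cover - starts sorted, j<=i
                j += 1
            # count starts in [w, w + window)
            k = i
            while k < len(starts) and starts[k] < w + window:
                k += 1
            best = max(best, k - i)
        per_replicon[rep] = best
    clustered = any(v >= min_genes for v in per_replicon.values())
    return ClusteringResult(
        clustered=clustered,
        per_replicon=per_replicon,
        window=window,
        min_genes=min_genes,
        missing_gene_ids=missing,
    )


# -- metadata I/O ------------------------------------------------------


def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    """Read a genome metadata TSV (genome_id, domain, lifestyle, culturable)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        cult = r.get("culturable")
        if cult is None or pd.isna(cult) or str(cult).lower() in ("unknown", "na", ""):
            cval = None
        else:
            cval = str(cult).lower() in ("1", "true", "yes")
        out.append(
            GenomeMetadata(
                genome_id=r["genome_id"],
                domain=r["domain"],
                lifestyle=r["lifestyle"],
                culturable=cval,
            )
        )
    return out


def write_metadata(meta: Iterable[GenomeMetadata], path: str | Path) -> None:
    rows = [
        {
            "genome_id": m.genome_id,
            "domain": m.domain,
            "lifestyle": m.lifestyle,
            "culturable": "unknown" if m.culturable is None else str(m.culturable).lower(),
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
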