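"""Synthetic enzyme families, proteomes and cohorts with known truth.

Every pipeline stage is testable without downloads: this module draws
protein families at controlled divergence, plants pathway enzymes
(including fusion proteins and non-orthologous alternatives) into
proteomes padded with background decoys, assembles cohorts whose
domain/lifestyle/culturability structure mirrors a prokaryotic
pan-genome screen, and emits reference annotations with a configurable
disagreement rate.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, BACKGROUND
from .cohort import GenomeMetadata, write_metadata
from .concordance import ReferenceCall
from .msa import Alignment, write_alignment
from .screening import GenomeCall

ALL_STEPS = frozenset(range(1, 8))

#: Default per-family lengths (residues) and the pathway profile each
#: stands for. Lengths are typical bacterial sizes for these enzymes.
DEFAULT_FAMILY_LENGTHS: dict[str, int] = {
    "aroG": 340,  # DAHP synthase
    "aroB_type1": 350,  # DHQ synthase, subtype 1
    "aroB_type2": 350,  # DHQ synthase, subtype 2
    "aroD": 240,  # dehydroquinate dehydratase
    "aroE": 260,  # shikimate dehydrogenase
    "ydiB": 270,  # shikimate dehydrogenase paralog
    "aroK_model1": 160,  # shikimate kinase, model 1
    "aroK_model2": 160,  # shikimate kinase, model 2
    "aroA": 420,  # EPSP synthase
    "aroC": 350,  # chorismate synthase
    "kdpgal": 200,  # KDPGal aldolase (alternative, step 1)
    "ghmp": 290,  # GHMP-superfamily kinase (alternative, step 5)
}

#: Fusion families: consensus is the concatenation of the components.
FUSION_COMPONENTS: dict[str, tuple[str, ...]] = {
    "aroM": ("aroB_type1", "aroD", "aroE", "aroK_model1", "aroA"),
    "aroDE": ("aroD", "aroE"),
}

#: Families a step can be satisfied by when planting canonical genes.
STEP_FAMILIES: dict[int, tuple[str, ...]] = {
    1: ("aroG",),
    2: ("aroB_type1", "aroB_type2"),
    3: ("aroD",),
    4: ("aroE", "ydiB"),
    5: ("aroK_model1", "aroK_model2"),
    6: ("aroA",),
    7: ("aroC",),
}

#: Cohort composition fractions over (domain, lifestyle, culturable),
#: mirroring a 488-genome prokaryotic screen: 147 free-living Bacteria,
#: 295 host-associated Bacteria (250 culturable, 45 not), 46 Archaea.
DEFAULT_GROUP_MIX: dict[tuple[str, str, bool | None], float] = {
    ("Bacteria", "free_living", True): 147 / 488,
    ("Bacteria", "host_associated", True): 250 / 488,
    ("Bacteria", "host_associated", False): 45 / 488,
    ("Archaea", "free_living", True): 46 / 488,
}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic enzyme family."""

    family_id: str
    length: int
    divergence: float = 0.3  # per-site substitution probability
    n_members: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ValueError("family length must be >= 10")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")


@dataclass(frozen=True)
class GenomeTruth:
    """Planted ground truth for one synthetic genome."""

    genome_id: str
    domain: str
    lifestyle: str
    culturable: bool | None
    present_steps: frozenset[int]
    planted_genes: tuple[str, ...]  # family ids emitted in the proteome
    fusions: tuple[str, ...] = ()
    alternatives: tuple[str, ...] = ()
    n_decoys: int = 100

    @property
    def complete(self) -> bool:
        return self.present_steps == ALL_STEPS

    @property
    def missing_steps(self) -> frozenset[int]:
        return ALL_STEPS - self.present_steps

    def metadata(self) -> GenomeMetadata:
        return GenomeMetadata(
            genome_id=self.genome_id,
            domain=self.domain,
            lifestyle=self.lifestyle,
            culturable=self.culturable,
        )


@dataclass
class FamilySet:
    """Seed alignments and consensus sequences for all families."""

    alignments: dict[str, Alignment]
    consensus: dict[str, str]
    divergence: float
    seed: int


@dataclass
class Cohort:
    """A synthetic cohort: proteomes, metadata and planted truth."""

    truths: list[GenomeTruth]
    proteomes: dict[str, list[tuple[str, str]]]
    families: FamilySet
    d_emit: float
    seed: int

    @property
    def metadata(self) -> list[GenomeMetadata]:
        return [t.metadata() for t in self.truths]

    def truth_calls(self) -> list[GenomeCall]:
        """The calls a perfect pipeline would make."""
        return [
            GenomeCall.from_missing(t.genome_id, t.missing_steps) for t in self.truths
        ]

    def write(self, out_dir: str | Path) -> None:
        """Write proteome FASTAs, metadata TSV, truth TSV and family
        alignments; byte-identical for identical cohorts."""
        out = Path(out_dir)
        (out / "proteomes").mkdir(parents=True, exist_ok=True)
        (out / "families").mkdir(parents=True, exist_ok=True)
        for gid in sorted(self.proteomes):
            with open(out / "proteomes" / f"{gid}.faa", "w") as fh:
                for pid, seq in self.proteomes[gid]:
                    fh.write(f">{pid}\n{seq}\n")
        write_metadata(self.metadata, out / "metadata.tsv")
        with open(out / "truth.tsv", "w") as fh:
            fh.write(
                "genome_id\tdomain\tlifestyle\tculturable\tcomplete\t"
                "missing_steps\tplanted_genes\tfusions\talternatives\tn_decoys\n"
            )
            for t in self.truths:
                fh.write(
                    "\t".join(
                        [
                            t.genome_id,
                            t.domain,
                            t.lifestyle,
                            "unknown" if t.culturable is None else str(t.culturable).lower(),
                            str(t.complete).lower(),
                            ",".join(map(str, sorted(t.missing_steps))),
                            ",".join(t.planted_genes),
                            ",".join(t.fusions),
                            ",".join(t.alternatives),
                            str(t.n_decoys),
                        ]
                    )
                    + "\n"
                )
        for fid in sorted(self.families.alignments):
            write_alignment(
                self.families.alignments[fid], out / "families" / f"{fid}.afa"
            )


# -- sequence-level generators ----------------------------------------


def _draw_background_seq(rng: np.random.Generator, length: int, background) -> str:
    codes = rng.choice(20, size=length, p=background)
    return "".join(AMINO_ACIDS[c] for c in codes)


def mutate_sequence(
    seq: str,
    divergence: float,
    rng: np.random.Generator,
    background=BACKGROUND,
) -> str:
    """Per-site substitution at rate ``divergence`` (replacement drawn
    from the background) plus indels at rate ``divergence / 10`` (split
    evenly between single-residue insertions and deletions)."""
    d = divergence
    out: list[str] = []
    for ch in seq:
        r = rng.random()
        if r < d / 20:  # deletion
            continue
        if rng.random() < d:
            out.append(AMINO_ACIDS[rng.choice(20, p=background)])
        else:
            out.append(ch)
        if r >= d / 20 and r < d / 10:  # insertion after this site
            out.append(AMINO_ACIDS[rng.choice(20, p=background)])
    if not out:  # pathological tiny input: keep one residue
        out.append(seq[0])
    return "".join(out)


def make_enzyme_family(
    spec: FamilySpec,
    background=BACKGROUND,
    consensus: str | None = None,
) -> tuple[Alignment, str]:
    """Draw a consensus from the background and diverge members from it.

    Members substitute per site at rate ``spec.divergence`` and carry
    indels at a tenth of that rate; the returned alignment is gapped so
    all members align to the consensus coordinate system (insertions
    open all-gap columns in the other rows).
    """
    rng = np.random.default_rng(spec.seed)
    if consensus is None:
        consensus = _draw_background_seq(rng, spec.length, background)
    Lc = len(consensus)
    d = spec.divergence
    rows_core: list[list[str]] = []
    rows_ins: list[list[str]] = []  # insertion after position j (or before 0)
    for _ in range(spec.n_members):
        core = []
        ins = [""] * (Lc + 1)
        for j, ch in enumerate(consensus):
            if rng.random() < d / 20:
                core.append("-")
            elif rng.random() < d:
                core.append(AMINO_ACIDS[rng.choice(20, p=background)])
            else:
                core.append(ch)
            if rng.random() < d / 20:
                ins[j + 1] += AMINO_ACIDS[rng.choice(20, p=background)]
        rows_core.append(core)
        rows_ins.append(ins)
    # assemble gapped rows: consensus columns interleaved with insert columns
    gapped = []
    widths = [
        max(len(ins[j]) for ins in rows_ins) for j in range(Lc + 1)
    ]
    for core, ins in zip(rows_core, rows_ins):
        parts = [ins[0].ljust(widths[0], "-")]
        for j in range(Lc):
            parts.append(core[j])
            parts.append(ins[j + 1].ljust(widths[j + 1], "-"))
        gapped.append("".join(parts))
    ids = tuple(f"{spec.family_id}_m{i}" for i in range(spec.n_members))
    return Alignment(tuple(gapped), ids), consensus


def make_default_families(
    seed: int = 0,
    divergence: float = 0.3,
    n_members: int = 25,
    lengths: Mapping[str, int] | None = None,
) -> FamilySet:
    """Generate the full default family set, fusions included."""
    lengths = dict(lengths or DEFAULT_FAMILY_LENGTHS)
    ss = np.random.SeedSequence(seed)
    child_seeds = {
        fid: int(s.generate_state(1)[0] % (2**31))
        for fid, s in zip(
            sorted(lengths) + sorted(FUSION_COMPONENTS),
            ss.spawn(len(lengths) + len(FUSION_COMPONENTS)),
        )
    }
    alignments: dict[str, Alignment] = {}
    consensus: dict[str, str] = {}
    for fid in sorted(lengths):
        spec = FamilySpec(
            fid, lengths[fid], divergence, n_members, seed=child_seeds[fid]
        )
        aln, cons = make_enzyme_family(spec)
        alignments[fid] = aln
        consensus[fid] = cons
    for fid in sorted(FUSION_COMPONENTS):
        cons = "".join(consensus[c] for c in FUSION_COMPONENTS[fid])
        spec = FamilySpec(
            fid, len(cons), divergence, n_members, seed=child_seeds[fid]
        )
        aln, cons = make_enzyme_family(spec, consensus=cons)
        alignments[fid] = aln
        consensus[fid] = cons
    return FamilySet(
        alignments=alignments, consensus=consensus, divergence=divergence, seed=seed
    )


# -- proteome and cohort generators ------------------------------------


def make_proteome(
    truth: GenomeTruth,
    families: Mapping[str, str],
    d_emit: float = 0.2,
    n_decoys: int | None = None,
    seed: int = 0,
    background=BACKGROUND,
) -> list[tuple[str, str]]:
    """Emit one diverged copy of each planted gene plus background decoys.

    Decoy lengths follow a log-normal with median 300 and sigma 0.4,
    typical of bacterial proteins.
    """
    rng = np.random.default_rng(seed)
    if n_decoys is None:
        n_decoys = truth.n_decoys
    records: list[tuple[str, str]] = []
    for fid in truth.planted_genes:
        if fid not in families:
            raise KeyError(f"truth references unknown family {fid!r}")
        seq = mutate_sequence(families[fid], d_emit, rng, background)
        records.append((f"{truth.genome_id}|{fid}", seq))
    for i in range(n_decoys):
        length = max(50, int(round(rng.lognormal(math.log(300.0), 0.4))))
        records.append(
            (f"{truth.genome_id}|decoy{i:04d}", _draw_background_seq(rng, length, background))
        )
    return records


def _sample_pattern(rng: np.random.Generator, domain: str, lifestyle: str) -> frozenset[int]:
    """Default missing-step patterns per cohort group.

    Free-living Bacteria are nearly all complete (131/147) and, when
    incomplete, miss one or two enzymes with no step preference.
    Host-associated Bacteria are complete in 204/295; of the incomplete
    ones most (67/91) have lost five or more genes, 20/91 exactly one
    (16 of those 20 the first enzyme), the rest two. Archaea are almost
    never complete (1/46) and predominantly lack the first enzyme (DAHP
    synthase) or the fifth (shikimate kinase).
    """
    steps = list(range(1, 8))
    if domain == "Archaea":
        if rng.random() < 1 / 46:
            return ALL_STEPS
        k = 1 if rng.random() < 0.5 else 2
        if rng.random() < 0.8:
            first = 1 if rng.random() < 0.5 else 5
        else:
            first = int(rng.choice(steps))
        missing = {first}
        while len(missing) < k:
            missing.add(int(rng.choice(steps)))
        return ALL_STEPS - missing
    if lifestyle == "free_living":
        if rng.random() < 131 / 147:
            return ALL_STEPS
        k = 1 if rng.random() < 0.5 else 2
        missing = set(rng.choice(steps, size=k, replace=False).tolist())
        return ALL_STEPS - missing
    # host-associated Bacteria
    if rng.random() < 204 / 295:
        return ALL_STEPS
    r = rng.random()
    if r < 67 / 91:
        k = int(rng.integers(5, 8))
        missing = set(rng.choice(steps, size=k, replace=False).tolist())
    elif r < 87 / 91:
        missing = {1} if rng.random() < 16 / 20 else {int(rng.choice(steps[1:]))}
    else:
        missing = set(rng.choice(steps, size=2, replace=False).tolist())
    return ALL_STEPS - missing


def _allocate_groups(
    n: int, group_mix: Mapping[tuple[str, str, bool | None], float]
) -> list[tuple[str, str, bool | None]]:
    """Largest-remainder allocation of n genomes to groups (deterministic,
    exact marginals whenever n * fraction is integral)."""
    items = sorted(group_mix.items(), key=lambda kv: kv[0])
    total = sum(f for _, f in items)
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError("group_mix fractions must sum to 1")
    raw = [(key, n * frac) for key, frac in items]
    counts = {key: int(math.floor(x)) for key, x in raw}
    short = n - sum(counts.values())
    by_remainder = sorted(raw, key=lambda kv: (-(kv[1] - math.floor(kv[1])), kv[0]))
    for key, _ in by_remainder[:short]:
        counts[key] += 1
    out: list[tuple[str, str, bool | None]] = []
    for key, _ in items:
        out.extend([key] * counts[key])
    return out


def sample_cohort_truth(
    n_genomes: int,
    group_mix: Mapping[tuple[str, str, bool | None], float] | None = None,
    completeness_mix=None,
    n_decoys: int = 100,
    seed: int = 0,
) -> list[GenomeTruth]:
    """Sample per-genome metadata, missing-step patterns and planted genes.

    ``completeness_mix`` may be None (built-in group-specific patterns),
    a float (probability of a complete pathway; incomplete genomes miss
    one or two uniformly chosen enzymes), a mapping from step-set
    patterns to probabilities, or a callable ``f(rng, domain, lifestyle)
    -> frozenset`` of present steps.
    """
    group_mix = group_mix or DEFAULT_GROUP_MIX
    rng = np.random.default_rng(seed)
    groups = _allocate_groups(n_genomes, group_mix)

    if completeness_mix is None:
        sampler = _sample_pattern
    elif isinstance(completeness_mix, float):
        p_complete = completeness_mix

        def sampler(rng, domain, lifestyle, _p=p_complete):
            if rng.random() < _p:
                return ALL_STEPS
            k = 1 if rng.random() < 0.5 else 2
            missing = set(rng.choice(range(1, 8), size=k, replace=False).tolist())
            return ALL_STEPS - missing

    elif callable(completeness_mix):
        sampler = completeness_mix
    else:
        patterns = [frozenset(p) for p in completeness_mix]
        probs = np.array(list(completeness_mix.values()), dtype=float)
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("completeness_mix probabilities must sum to 1")

        def sampler(rng, domain, lifestyle, _ps=patterns, _pr=probs):
            return _ps[int(rng.choice(len(_ps), p=_pr))]

    truths: list[GenomeTruth] = []
    width = max(3, len(str(n_genomes - 1)))
    for g, (domain, lifestyle, culturable) in enumerate(groups):
        present = frozenset(sampler(rng, domain, lifestyle))
        fusions: list[str] = []
        covered: set[int] = set()
        if {2, 3, 4, 5, 6} <= present and rng.random() < 0.10:
            fusions.append("aroM")
            covered |= {2, 3, 4, 5, 6}
        elif {3, 4} <= present and rng.random() < 0.10:
            fusions.append("aroDE")
            covered |= {3, 4}
        genes: list[str] = list(fusions)
        for step in sorted(present - covered):
            choices = STEP_FAMILIES[step]
            genes.append(choices[int(rng.integers(len(choices)))])
        alternatives: list[str] = []
        p_kdpgal = 0.5 if 1 in present else 14 / 108
        if rng.random() < p_kdpgal:
            alternatives.append("kdpgal")
        if rng.random() < 0.9:  # serine kinases are near-universal
            alternatives.append("ghmp")
        genes.extend(alternatives)
        truths.append(
            GenomeTruth(
                genome_id=f"g{g:0{width}d}",
                domain=domain,
                lifestyle=lifestyle,
                culturable=culturable,
                present_steps=present,
                planted_genes=tuple(genes),
                fusions=tuple(fusions),
                alternatives=tuple(alternatives),
                n_decoys=n_decoys,
            )
        )
    return truths


def make_cohort(
    n_genomes: int = 60,
    group_mix: Mapping[tuple[str, str, bool | None], float] | None = None,
    completeness_mix=None,
    d_emit: float = 0.2,
    n_decoys: int = 100,
    seed: int = 0,
    families: FamilySet | None = None,
) -> Cohort:
    """Generate a full synthetic cohort: families, truth, proteomes."""
    ss = np.random.SeedSequence(seed)
    fam_seed, truth_seed, prot_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    if families is None:
        families = make_default_families(seed=fam_seed)
    truths = sample_cohort_truth(
        n_genomes, group_mix, completeness_mix, n_decoys=n_decoys, seed=truth_seed
    )
    pss = np.random.SeedSequence(prot_seed)
    proteomes: dict[str, list[tuple[str, str]]] = {}
    for t, child in zip(truths, pss.spawn(len(truths))):
        proteomes[t.genome_id] = make_proteome(
            t,
            families.consensus,
            d_emit=d_emit,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
    return Cohort(
        truths=truths,
        proteomes=proteomes,
        families=families,
        d_emit=d_emit,
        seed=seed,
    )


def make_reference_annotation(
    truths: Sequence[GenomeTruth],
    flip_rate: float = 0.0,
    seed: int = 0,
    source: str = "synthetic-reference",
) -> list[ReferenceCall]:
    """Copy truth completeness, flipping each call independently with
    probability ``flip_rate`` — a stand-in for an independently curated
    annotation with a known disagreement rate."""
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for t in truths:
        complete = t.complete
        if rng.random() < flip_rate:
            complete = not complete
        out.append(ReferenceCall(genome_id=t.genome_id, complete=complete, source=source))
    return out
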