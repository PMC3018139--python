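"""Declarative model of the seven-step shikimate pathway.

The pathway runs from phosphoenolpyruvate + erythrose-4-phosphate to
chorismate in seven enzyme-mediated steps. Each step can be satisfied by
one or more enzyme variants: isoforms (the three feedback-regulated DAHP
synthases aroF/aroG/aroH), paralogs (YdiB for shikimate dehydrogenase),
multi-profile families (DHQ synthase and shikimate kinase are divergent
enough to need two models each), fusion proteins covering several steps
at once (the pentafunctional AROM protein, steps 2-6; the bifunctional
dehydroquinate dehydratase / shikimate dehydrogenase, steps 3-4), and
non-orthologous alternatives (KDPGal aldolase for step 1, archaeal GHMP
kinase for step 5). Alternatives are recorded as rescues but never count
toward the canonical completeness call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import yaml

from .errors import PathwayConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .screening import Hit

N_STEPS = 7


@dataclass(frozen=True)
class Step:
    index: int
    product: str
    ec: str


@dataclass(frozen=True)
class EnzymeVariant:
    """One way of satisfying one or more pathway steps.

    ``profile_ids`` lists the profiles whose best-scoring hit represents
    this variant; ``role`` is "canonical" or "alternative".
    """

    variant_id: str
    profile_ids: tuple[str, ...]
    role: str
    steps_satisfied: frozenset[int]

    def __post_init__(self) -> None:
        if self.role not in ("canonical", "alternative"):
            raise PathwayConfigError(
                f"variant {self.variant_id!r}: role must be canonical or "
                f"alternative, got {self.role!r}"
            )
        if not self.profile_ids:
            raise PathwayConfigError(
                f"variant {self.variant_id!r} lists no profiles"
            )
        if not self.steps_satisfied:
            raise PathwayConfigError(
                f"variant {self.variant_id!r} satisfies no steps"
            )

    @property
    def is_fusion(self) -> bool:
        return len(self.steps_satisfied) > 1


@dataclass(frozen=True)
class PathwayDefinition:
    steps: tuple[Step, ...]
    variants: tuple[EnzymeVariant, ...]

    def __post_init__(self) -> None:
        indices = [s.index for s in self.steps]
        if indices != list(range(1, len(indices) + 1)):
            raise PathwayConfigError("step indices must be 1..n in order")
        valid = set(indices)
        seen: set[str] = set()
        for v in self.variants:
            if v.variant_id in seen:
                raise PathwayConfigError(f"duplicate variant_id {v.variant_id!r}")
            seen.add(v.variant_id)
            unknown = v.steps_satisfied - valid
            if unknown:
                raise PathwayConfigError(
                    f"variant {v.variant_id!r} references unknown steps "
                    f"{sorted(unknown)}"
                )
        for idx in indices:
            if not any(
                idx in v.steps_satisfied and v.role == "canonical"
                for v in self.variants
            ):
                raise PathwayConfigError(
                    f"step {idx} has no canonical variant"
                )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def variants_for_step(self, step: int, role: str | None = None):
        return [
            v
            for v in self.variants
            if step in v.steps_satisfied and (role is None or v.role == role)
        ]

    @property
    def profile_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for v in self.variants:
            for p in v.profile_ids:
                seen.setdefault(p)
        return tuple(seen)


@dataclass(frozen=True)
class StepCall:
    """Presence/absence call for one pathway step in one proteome."""

    step: int
    satisfied_canonical: bool
    satisfied_by: str | None = None
    rescue_by_alternative: str | None = None
    best_hit: "Hit | None" = None


#: Default pathway definition. Step products and EC numbers follow the
#: classical shikimate-pathway description; profile identifiers are the
#: E. coli gene names used throughout this package.
DEFAULT_PATHWAY_CONFIG: dict = {
    "steps": [
        {"index": 1, "product": "3-deoxy-D-arabino-heptulosonate-7-phosphate", "ec": "4.1.2.15"},
        {"index": 2, "product": "3-dehydroquinate", "ec": "4.2.3.4"},
        {"index": 3, "product": "3-dehydroshikimate", "ec": "4.2.1.10"},
        {"index": 4, "product": "shikimate", "ec": "1.1.1.25"},
        {"index": 5, "product": "shikimate-3-phosphate", "ec": "2.7.1.71"},
        {"index": 6, "product": "5-enolpyruvylshikimate-3-phosphate", "ec": "2.5.1.19"},
        {"index": 7, "product": "chorismate", "ec": "4.2.3.5"},
    ],
    "variants": [
        # three DAHP synthase isoforms, one profile each
        {"variant_id": "dahp_synthase", "profiles": ["aroF", "aroG", "aroH"],
         "role": "canonical", "steps": [1]},
        {"variant_id": "kdpgal_aldolase", "profiles": ["kdpgal"],
         "role": "alternative", "steps": [1]},
        # DHQ synthase is divergent: two profile models, best score wins
        {"variant_id": "dhq_synthase", "profiles": ["aroB_type1", "aroB_type2"],
         "role": "canonical", "steps": [2]},
        {"variant_id": "dhq_dehydratase", "profiles": ["aroD"],
         "role": "canonical", "steps": [3]},
        {"variant_id": "shikimate_dehydrogenase", "profiles": ["aroE"],
         "role": "canonical", "steps": [4]},
        {"variant_id": "ydiB_paralog", "profiles": ["ydiB"],
         "role": "canonical", "steps": [4]},
        # shikimate kinase likewise carries two models
        {"variant_id": "shikimate_kinase", "profiles": ["aroK_model1", "aroK_model2"],
         "role": "canonical", "steps": [5]},
        {"variant_id": "ghmp_kinase", "profiles": ["ghmp"],
         "role": "alternative", "steps": [5]},
        {"variant_id": "epsp_synthase", "profiles": ["aroA"],
         "role": "canonical", "steps": [6]},
        {"variant_id": "chorismate_synthase", "profiles": ["aroC"],
         "role": "canonical", "steps": [7]},
        # pentafunctional AROM fusion (aroB-aroD-aroE-aroL-aroA), steps 2-6
        {"variant_id": "aroM_pentafunctional", "profiles": ["aroM"],
         "role": "canonical", "steps": [2, 3, 4, 5, 6]},
        # bifunctional dehydroquinate dehydratase / shikimate dehydrogenase
        {"variant_id": "aroDE_bifunctional", "profiles": ["aroDE"],
         "role": "canonical", "steps": [3, 4]},
    ],
}


def load_pathway_definition(source: str | Path | Mapping | None = None) -> PathwayDefinition:
    """Load and validate a pathway definition.

    ``source`` may be a mapping, a path to a YAML/JSON document, or None
    for the shipped default (the seven-step shikimate pathway with its
    isoforms, fusions and non-orthologous alternatives).
    """
    if source is None:
        doc = DEFAULT_PATHWAY_CONFIG
    elif isinstance(source, Mapping):
        doc = source
    else:
        path = Path(source)
        with open(path) as fh:
            if path.suffix.lower() == ".json":
                doc = json.load(fh)
            else:
                doc = yaml.safe_load(fh)
    try:
        steps = tuple(
            Step(index=int(s["index"]), product=str(s["product"]), ec=str(s["ec"]))
            for s in doc["steps"]
        )
        variants = tuple(
            EnzymeVariant(
                variant_id=str(v["variant_id"]),
                profile_ids=tuple(v["profiles"]),
                role=str(v.get("role", "canonical")),
                steps_satisfied=frozenset(int(i) for i in v["steps"]),
            )
            for v in doc["variants"]
        )
    except (KeyError, TypeError) as exc:
        raise PathwayConfigError(f"malformed pathway definition: {exc}") from exc
    return PathwayDefinition(steps=steps, variants=variants)


def default_pathway() -> PathwayDefinition:
    return load_pathway_definition(None)


def _hit_key(h: "Hit"):
    # maximal bit score; ties by smaller E-value, then protein id
    return (-h.bit_score, h.e_value, h.protein_id)


def best_variant_hit(hits: Iterable["Hit"], variant: EnzymeVariant) -> "Hit | None":
    """Best hit to any of the variant's profiles (deterministic tie-break:
    higher score, then smaller E-value, then lexicographic protein id)."""
    pool = [h for h in hits if h.profile_id in variant.profile_ids]
    if not pool:
        return None
    return min(pool, key=_hit_key)


def evaluate_steps(
    filtered_hits: Sequence["Hit"], pd: PathwayDefinition
) -> list[StepCall]:
    """Map threshold-surviving hits to per-step satisfaction calls.

    A step is canonically satisfied iff some canonical variant covering
    it (including fusions) has a surviving hit. An alternative variant's
    hit is recorded as a rescue and never flips the canonical call.
    """
    calls: list[StepCall] = []
    for step in (s.index for s in pd.steps):
        best_canonical: tuple | None = None
        for v in pd.variants_for_step(step, role="canonical"):
            h = best_variant_hit(filtered_hits, v)
            if h is not None:
                cand = (_hit_key(h), v.variant_id, h)
                if best_canonical is None or cand[:2] < best_canonical[:2]:
                    best_canonical = cand
        best_rescue: tuple | None = None
        for v in pd.variants_for_step(step, role="alternative"):
            h = best_variant_hit(filtered_hits, v)
            if h is not None:
                cand = (_hit_key(h), v.variant_id, h)
                if best_rescue is None or cand[:2] < best_rescue[:2]:
                    best_rescue = cand
        calls.append(
            StepCall(
                step=step,
                satisfied_canonical=best_canonical is not None,
                satisfied_by=best_canonical[1] if best_canonical else None,
                rescue_by_alternative=best_rescue[1] if best_rescue else None,
                best_hit=best_canonical[2] if best_canonical else None,
            )
        )
    return calls
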