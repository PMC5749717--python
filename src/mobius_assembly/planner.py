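"""Hierarchical assembly planning: N ordered TUs -> Level 1/2 reaction schedule.

Capacity grows along the geometric sequence 1, 4, 16, 64, ... (first term 1,
ratio 4): tier 1 holds single TUs in Level 1 vectors, even tiers are Level 2
rounds fusing up to four cassettes with an Auxiliary linker, odd tiers >= 3
are Level 1 fusion rounds (no Auxiliary Plasmid needed when cloning from
Level 2 back to Level 1).

Packing is greedy left-packed (4, 4, ..., remainder), preserving TU order.
Single-TU Level 1 construction is implicit for n >= 2: the plan records the
Level 1 vector assigned to each TU (``tu_vectors``) and the simulator runs
those reactions as a preliminary stage; plan ``steps`` cover the multi-TU
routing only. Planning is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

from .standard import DEFAULT_STANDARD, MobiusStandard, POSITION_LETTERS

__all__ = [
    "Chunk",
    "AssemblyStep",
    "AssemblyPlan",
    "ExtensionError",
    "capacity",
    "rounds_required",
    "plan_assembly",
    "extend_plan",
    "bench_sheet",
    "plan_to_yaml",
    "plan_from_yaml",
]

_FAILURE_COLOUR = {0: "purple (amilCP retained)", 1: "magenta (spisPink retained)", 2: "yellow (sfGFP retained)"}


class ExtensionError(ValueError):
    """Existing construct cannot be re-entered into the assembly cycle."""


def capacity(tier: int) -> int:
    """TU capacity after ``tier`` assembly tiers: 4**(tier-1)."""
    if tier < 1:
        raise ValueError(f"tier must be >= 1, got {tier}")
    return 4 ** (tier - 1)


def rounds_required(n: int) -> int:
    """Smallest tier count whose capacity reaches ``n`` TUs."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    tier = 1
    while capacity(tier) < n:
        tier += 1
    return tier


@dataclass(frozen=True)
class Chunk:
    """Contiguous ordered group of units within one Level 2 round.

    ``position`` (1-4) maps to vector A/B/Gamma/Delta; a chunk of size < 4 is
    always terminal (Middle-to-End linkers only provide CGCT, which closes
    the chain), and the last chunk of each Level 1 group is terminal too.
    """

    unit_refs: tuple[str, ...]
    position: int
    size: int
    terminal: bool


@dataclass(frozen=True)
class AssemblyStep:
    id: str
    level: int
    vector: str
    inputs: tuple[str, ...]
    linker: str | None
    tier: int


@dataclass
class AssemblyPlan:
    n_tus: int
    steps: list[AssemblyStep]
    rounds: int
    tu_vectors: dict[int, str] = field(default_factory=dict)

    @property
    def final_step(self) -> AssemblyStep:
        return self.steps[-1]

    def linkers_used(self) -> list[str]:
        return [s.linker for s in self.steps if s.linker is not None]


def _tu_ref(i: int) -> str:
    return f"tu:{i}"


def _step_ref(step_id: str) -> str:
    return f"step:{step_id}"


def _pack4(units: list[str]) -> list[list[str]]:
    return [units[i : i + 4] for i in range(0, len(units), 4)]


def _expand(
    units: list[str],
    first_tier: int,
    steps: list[AssemblyStep],
    next_num: int,
) -> int:
    """Alternate Level 2 / Level 1 tiers until a single unit remains."""
    tier = first_tier
    while True:
        new_units: list[str] = []
        if tier % 2 == 0:  # Level 2 round: chunks of up to 4 + linker
            chunks = _pack4(units)
            c = len(chunks)
            for i, chunk in enumerate(chunks, start=1):
                pos = (i - 1) % 4 + 1
                letter = POSITION_LETTERS[pos - 1]
                terminal = (i == c) or (i % 4 == 0)
                size = len(chunk)
                if size < 4:
                    linker = f"M{size}"
                elif terminal:
                    linker = "4D"
                else:
                    linker = f"4{letter}"
                step = AssemblyStep(
                    id=f"s{next_num}",
                    level=2,
                    vector=f"L2-{letter}",
                    inputs=tuple(chunk),
                    linker=linker,
                    tier=tier,
                )
                next_num += 1
                steps.append(step)
                new_units.append(_step_ref(step.id))
        else:  # Level 1 fusion round: groups of up to 4, no Auxiliary Plasmid
            groups = _pack4(units)
            for g, group in enumerate(groups, start=1):
                letter = POSITION_LETTERS[(g - 1) % 4]
                step = AssemblyStep(
                    id=f"s{next_num}",
                    level=1,
                    vector=f"L1-{letter}",
                    inputs=tuple(group),
                    linker=None,
                    tier=tier,
                )
                next_num += 1
                steps.append(step)
                new_units.append(_step_ref(step.id))
        units = new_units
        tier += 1
        if len(units) == 1:
            return next_num


def plan_assembly(n: int) -> AssemblyPlan:
    """Minimal-round schedule assembling TUs 1..n in order."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n == 1:
        step = AssemblyStep("s1", 1, "L1-A", (_tu_ref(1),), None, 1)
        return AssemblyPlan(1, [step], rounds=1, tu_vectors={1: "A"})
    tu_vectors = {j: POSITION_LETTERS[(j - 1) % 4] for j in range(1, n + 1)}
    steps: list[AssemblyStep] = []
    _expand([_tu_ref(j) for j in range(1, n + 1)], 2, steps, 1)
    rounds = max(s.tier for s in steps)
    return AssemblyPlan(n, steps, rounds=rounds, tu_vectors=tu_vectors)


def extend_plan(existing: AssemblyPlan, extra: int) -> AssemblyPlan:
    """Append ``extra`` TUs to an already planned construct.

    The existing final cassette re-enters as chunk-position-1 unit of a new
    round: a terminal Level 2 final (payload CGCT) is first re-housed alone
    in Level 1 A, switching cloning levels; a Level 1 final is a releasable
    super-cassette already and is reused directly.
    """
    if extra < 0:
        raise ValueError("extra must be >= 0")
    if extra == 0:
        return existing
    final = existing.final_step
    steps = list(existing.steps)
    next_num = len(existing.steps) + 1
    if final.level == 2:
        if final.linker is None or DEFAULT_STANDARD.linker_spec(final.linker).payload_overhang != "CGCT":
            raise ExtensionError(
                f"final construct of step {final.id} is not terminal (does not end CGCT)"
            )
        rehouse = AssemblyStep(
            id=f"s{next_num}",
            level=1,
            vector="L1-A",
            inputs=(_step_ref(final.id),),
            linker=None,
            tier=final.tier + 1,
        )
        next_num += 1
        steps.append(rehouse)
        seed_unit = _step_ref(rehouse.id)
        next_tier = rehouse.tier + 1
    else:
        seed_unit = _step_ref(final.id)
        next_tier = final.tier + 1
    a = existing.n_tus
    new_tus = list(range(a + 1, a + extra + 1))
    tu_vectors = dict(existing.tu_vectors)
    # the prebuilt cassette occupies position 1 of the first new chunk
    for j in new_tus:
        tu_vectors[j] = POSITION_LETTERS[(j - a) % 4]
    units = [seed_unit] + [_tu_ref(j) for j in new_tus]
    _expand(units, next_tier, steps, next_num)
    rounds = max(s.tier for s in steps)
    return AssemblyPlan(a + extra, steps, rounds=rounds, tu_vectors=tu_vectors)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _plan_dict(plan: AssemblyPlan) -> dict:
    return {
        "n_tus": plan.n_tus,
        "rounds": plan.rounds,
        "tu_vectors": {str(k): v for k, v in sorted(plan.tu_vectors.items())},
        "steps": [
            {
                "id": s.id,
                "level": s.level,
                "vector": s.vector,
                "inputs": list(s.inputs),
                "linker": s.linker,
                "tier": s.tier,
            }
            for s in plan.steps
        ],
    }


def plan_to_yaml(plan: AssemblyPlan) -> str:
    return yaml.safe_dump(_plan_dict(plan), sort_keys=False)


def plan_from_yaml(text: str) -> AssemblyPlan:
    doc = yaml.safe_load(text)
    steps = [
        AssemblyStep(
            id=s["id"],
            level=s["level"],
            vector=s["vector"],
            inputs=tuple(s["inputs"]),
            linker=s["linker"],
            tier=s["tier"],
        )
        for s in doc["steps"]
    ]
    return AssemblyPlan(
        n_tus=doc["n_tus"],
        steps=steps,
        rounds=doc["rounds"],
        tu_vectors={int(k): v for k, v in doc.get("tu_vectors", {}).items()},
    )


def plan_to_json(plan: AssemblyPlan) -> str:
    return json.dumps(_plan_dict(plan), indent=2)


def bench_sheet(plan: AssemblyPlan, standard: MobiusStandard = DEFAULT_STANDARD) -> str:
    """Human-readable per-step bench sheet with failure colony colours."""
    lines = [
        f"Mobius Assembly bench sheet — {plan.n_tus} TU(s), {plan.rounds} tier(s)",
        "",
    ]
    if plan.n_tus >= 2:
        lines.append("Preliminary Level 1 reactions (one per TU; BsaI + ligase):")
        for j in sorted(plan.tu_vectors):
            v = standard.vector_spec(f"L1-{plan.tu_vectors[j]}")
            lines.append(
                f"  TU {j}: parts -> {v.display_name} "
                f"[failures {_FAILURE_COLOUR[1]}]"
            )
        lines.append("")
    for s in plan.steps:
        v = standard.vector_spec(s.vector)
        enzyme = v.acceptance_enzyme
        linker = f", Auxiliary {standard.linker_spec(s.linker).display_name}" if s.linker else ""
        inputs = ", ".join(s.inputs)
        lines.append(
            f"{s.id} (tier {s.tier}, Level {s.level}): {inputs} -> {v.display_name} "
            f"({enzyme}{linker}) [failures {_FAILURE_COLOUR[v.level]}]"
        )
    lines.append("")
    lines.append("Correct assemblies yield white colonies.")
    return "\n".join(lines)
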