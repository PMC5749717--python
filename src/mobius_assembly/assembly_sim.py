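"""One-pot Golden Gate reaction simulation.

Digest every input plasmid, build the overhang-labelled multigraph (nodes =
4-mer tokens, directed edges = fragments plus the reversed edge for the
reverse-complemented fragment), enumerate simple cycles using each physical
fragment at most once and containing exactly one backbone fragment, and keep
the products whose closed sequence retains zero intact recognition sites of
the reaction enzyme on either strand. Site-free closure automatically
rejects re-ligation of the dropout marker, whose fragment keeps its sites.

This is an idealized end-point model: ligase kinetics, buffer effects and
thermocycling are not modelled, and products are capped at ``max_cycle_len``
fragments with one copy per physical fragment (no concatemers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .planner import AssemblyPlan
from .seq_core import (
    DnaMolecule,
    Feature,
    StickyFragment,
    TypeIISEnzyme,
    count_sites,
    digest,
    get_enzyme,
    reverse_complement_seq,
    write_genbank,
)

__all__ = [
    "FailureMode",
    "ReactionMix",
    "AssemblyProduct",
    "AssemblyDiagnostics",
    "ReleaseError",
    "PlanExecutionError",
    "simulate_one_pot",
    "cassette_of",
    "simulate_plan",
    "write_product",
]


class FailureMode(str, Enum):
    NONE = "none"
    NO_CLOSED_CYCLE = "no_closed_cycle"
    MULTIPLE_VALID_PRODUCTS = "multiple_valid_products"
    OVERHANG_CLASH = "overhang_clash"
    UNCUT_INPUT = "uncut_input"


class ReleaseError(ValueError):
    """Release enzyme does not cut the product exactly twice."""


class PlanExecutionError(RuntimeError):
    def __init__(self, step_id: str, diagnostics: "AssemblyDiagnostics"):
        self.step_id = step_id
        self.diagnostics = diagnostics
        super().__init__(
            f"assembly step {step_id} failed: {diagnostics.failure_mode.value} "
            f"({diagnostics.detail})"
        )


@dataclass
class ReactionMix:
    """Acceptor + inserts + one registered Type IIS enzyme.

    Inserts are normally circular plasmids; linear molecules (e.g. tailed PCR
    amplicons entering the mUAV) are accepted — their blunt terminal
    fragments simply never ligate.
    """

    acceptor: DnaMolecule
    inserts: list[DnaMolecule]
    enzyme: TypeIISEnzyme
    max_cycle_len: int = 12

    def __post_init__(self) -> None:
        if not self.acceptor.is_circular:
            raise ValueError("acceptor must be circular")
        get_enzyme(self.enzyme.name)  # must be a registered enzyme


@dataclass
class AssemblyProduct:
    molecule: DnaMolecule
    fragment_order: list[tuple[str, str]]
    valid: bool


@dataclass
class AssemblyDiagnostics:
    products_found: int
    failure_mode: FailureMode
    detail: str = ""
    warnings: list[str] = field(default_factory=list)


def _has_resistance(frag: StickyFragment) -> bool:
    return any(f.kind == "resistance" for f in frag.features)


def _join_cycle(oriented: list[StickyFragment], product_id: str) -> DnaMolecule:
    """Circularize a closed chain of fragments, counting junctions once."""
    ov = len(oriented[0].left_overhang)
    parts: list[str] = []
    feats: list[Feature] = []
    offset = 0
    total = sum(len(f.core) - ov for f in oriented)
    for frag in oriented:
        parts.append(frag.core[: len(frag.core) - ov])
        for f in frag.features:
            start = (offset + f.start) % total
            end = start + (f.end - f.start)
            if end <= total:
                feats.append(Feature(f.label, start, end, f.strand, f.kind))
            else:  # feature spans the origin after rotation; keep within range
                feats.append(Feature(f.label, start, total, f.strand, f.kind))
        offset += len(frag.core) - ov
    seq = "".join(parts)
    feats.sort(key=lambda f: f.start)
    return DnaMolecule(product_id, seq, "circular", feats)


def _enumerate_cycles(
    backbone: int,
    frags: list[StickyFragment],
    max_len: int,
) -> list[list[tuple[int, str]]]:
    """Simple cycles through the backbone fragment (taken forward).

    Returns lists of (fragment index, orientation) with the backbone first.
    Both orientations of every other fragment are explored.
    """
    ends: dict[int, dict[str, tuple[str, str]]] = {}
    for i, f in enumerate(frags):
        rc_left = reverse_complement_seq(f.right_overhang)
        rc_right = reverse_complement_seq(f.left_overhang)
        ends[i] = {"+": (f.left_overhang, f.right_overhang), "-": (rc_left, rc_right)}

    start_token = ends[backbone]["+"][0]
    cycles: list[list[tuple[int, str]]] = []
    path: list[tuple[int, str]] = [(backbone, "+")]
    used = {backbone}

    def dfs(current_end: str) -> None:
        if len(path) >= 2 and current_end == start_token:
            cycles.append(list(path))
            # junction labels are unique in well-formed reactions; a longer
            # cycle revisiting this token would reuse it, so stop here.
            return
        if len(path) >= max_len:
            return
        for j, f in enumerate(frags):
            if j in used:
                continue
            for orient in ("+", "-"):
                left, right = ends[j][orient]
                if left != current_end or not left:
                    continue
                path.append((j, orient))
                used.add(j)
                dfs(right)
                used.discard(j)
                path.pop()

    first_right = ends[backbone]["+"][1]
    if first_right:
        dfs(first_right)
    return cycles


def simulate_one_pot(mix: ReactionMix) -> tuple[AssemblyProduct | None, AssemblyDiagnostics]:
    """Simulate a one-pot digestion-ligation and identify the unique valid
    assembly, or a diagnostic explaining the failure."""
    enzyme = mix.enzyme
    acceptor_frags = digest(mix.acceptor, enzyme)
    if len(acceptor_frags) == 1 and acceptor_frags[0].uncut:
        return None, AssemblyDiagnostics(
            0, FailureMode.UNCUT_INPUT, f"acceptor {mix.acceptor.id} has no {enzyme.name} sites"
        )
    backbone_candidates = [i for i, f in enumerate(acceptor_frags) if _has_resistance(f)]
    if len(backbone_candidates) != 1:
        raise ValueError(
            f"acceptor {mix.acceptor.id} must yield exactly one fragment with a "
            f"resistance feature, found {len(backbone_candidates)}"
        )

    frags: list[StickyFragment] = list(acceptor_frags)
    backbone = backbone_candidates[0]
    for ins in mix.inserts:
        frags.extend(digest(ins, enzyme))

    warnings = []
    seen_tokens = set()
    for f in frags:
        for token in (f.left_overhang, f.right_overhang):
            if token and token == reverse_complement_seq(token) and token not in seen_tokens:
                warnings.append(f"palindromic overhang {token} (fidelity risk)")
                seen_tokens.add(token)

    cycles = _enumerate_cycles(backbone, frags, mix.max_cycle_len)

    products: list[AssemblyProduct] = []
    seen_sequences: set[str] = set()
    for cyc in cycles:
        oriented = [frags[i] if o == "+" else frags[i].reverse_complement() for i, o in cyc]
        mol = _join_cycle(oriented, f"assembly:{mix.acceptor.id}")
        if count_sites(mol.sequence, enzyme, circular=True) != 0:
            continue
        # every cycle starts at the same backbone cut, so identical products
        # compare equal without rotation
        if mol.sequence in seen_sequences:
            continue
        seen_sequences.add(mol.sequence)
        order = [(frags[i].source, o) for i, o in cyc]
        products.append(AssemblyProduct(mol, order, valid=True))

    if len(products) == 1:
        return products[0], AssemblyDiagnostics(
            len(cycles), FailureMode.NONE, "unique valid product", warnings
        )
    if not products:
        return None, AssemblyDiagnostics(
            len(cycles),
            FailureMode.NO_CLOSED_CYCLE,
            f"{len(cycles)} closed cycle(s), none free of {enzyme.name} sites",
            warnings,
        )
    # several valid products: duplicated overhang labels among fragments that
    # are themselves site-free point to an overhang clash
    clean = [f for f in frags if count_sites(f.core, enzyme) == 0]
    lefts = [f.left_overhang for f in clean if f.left_overhang]
    rights = [f.right_overhang for f in clean if f.right_overhang]
    clash = len(set(lefts)) < len(lefts) or len(set(rights)) < len(rights)
    mode = FailureMode.OVERHANG_CLASH if clash else FailureMode.MULTIPLE_VALID_PRODUCTS
    return None, AssemblyDiagnostics(
        len(cycles), mode, f"{len(products)} distinct valid products", warnings
    )


def cassette_of(product: AssemblyProduct, release_enzyme: TypeIISEnzyme) -> StickyFragment:
    """Release the insert-side fragment (the one without the resistance
    feature) from a valid product; the release enzyme must cut exactly twice."""
    if not product.valid:
        raise ValueError("cannot release a cassette from an invalid product")
    frags = digest(product.molecule, release_enzyme)
    if len(frags) != 2 or any(f.uncut for f in frags):
        raise ReleaseError(
            f"{release_enzyme.name} must cut the product exactly twice, "
            f"got {len(frags)} fragment(s)"
        )
    insert_side = [f for f in frags if not _has_resistance(f)]
    if len(insert_side) != 1:
        raise ReleaseError("could not identify the insert-side fragment by resistance feature")
    return insert_side[0]


@dataclass
class TuParts:
    """Level 0 plasmids making up one transcriptional unit."""

    promoter: DnaMolecule
    cds: DnaMolecule
    terminator: DnaMolecule

    def plasmids(self) -> list[DnaMolecule]:
        return [self.promoter, self.cds, self.terminator]


def simulate_plan(
    plan: AssemblyPlan,
    toolkit,
    cargo: list[TuParts],
    max_cycle_len: int = 12,
) -> AssemblyProduct:
    """Execute every reaction of a plan in dependency order.

    ``toolkit`` is a :class:`~mobius_assembly.fixtures.SyntheticToolkit` (or
    anything exposing ``vector(name)``/``auxiliary(name)``); ``cargo`` holds
    one :class:`TuParts` per TU. Single-TU Level 1 constructions implied by
    ``plan.tu_vectors`` run first; any failing intermediate aborts with the
    step identified.
    """
    if len(cargo) != plan.n_tus:
        raise ValueError(f"plan covers {plan.n_tus} TUs but {len(cargo)} were supplied")
    bsa = get_enzyme("BsaI")
    aar = get_enzyme("AarI")

    resolved: dict[str, DnaMolecule] = {}

    def build_tu(j: int) -> DnaMolecule:
        ref = f"tu:{j}"
        if ref not in resolved:
            vec = toolkit.vector(f"L1-{plan.tu_vectors[j]}")
            mix = ReactionMix(vec, cargo[j - 1].plasmids(), bsa, max_cycle_len)
            product, diag = simulate_one_pot(mix)
            if product is None:
                raise PlanExecutionError(f"tu:{j}", diag)
            product.molecule.id = f"TU{j}-in-L1-{plan.tu_vectors[j]}"
            resolved[ref] = product.molecule
        return resolved[ref]

    final_product: AssemblyProduct | None = None
    for step in plan.steps:
        inserts: list[DnaMolecule] = []
        tu_inputs = [r for r in step.inputs if r.startswith("tu:")]
        if step.level == 1 and step.tier == 1:
            # explicit single-TU construction (n == 1 plans)
            vec = toolkit.vector(step.vector)
            j = int(tu_inputs[0].split(":")[1])
            inserts = cargo[j - 1].plasmids()
            enzyme = bsa
        else:
            for ref in step.inputs:
                if ref.startswith("tu:"):
                    inserts.append(build_tu(int(ref.split(":")[1])))
                else:
                    inserts.append(resolved[ref])
            vec = toolkit.vector(step.vector)
            if step.level == 2:
                enzyme = aar
                inserts.append(toolkit.auxiliary(step.linker))
            else:
                enzyme = bsa
        product, diag = simulate_one_pot(ReactionMix(vec, inserts, enzyme, max_cycle_len))
        if product is None:
            raise PlanExecutionError(step.id, diag)
        product.molecule.id = f"{step.id}-{step.vector}"
        resolved[f"step:{step.id}"] = product.molecule
        final_product = product
    assert final_product is not None
    return final_product


def payload_order(molecule: DnaMolecule) -> list[str]:
    """Payload feature labels in top-strand coordinate order."""
    payloads = sorted(molecule.features_of_kind("payload"), key=lambda f: f.start)
    return [f.label for f in payloads]


def write_product(product: AssemblyProduct, path: str | Path) -> None:
    write_genbank([product.molecule], path)
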