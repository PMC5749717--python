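"""Primer tail design: convert a template region into a Level 0 standard part.

Each primer reads, 5' to 3': a short clamp, the AarI recognition CACCTGC, a
4-nt spacer matching AarI's (4/8) cut geometry so the cut lands exactly on
the fusion 4-mer, the mUAV fusion site (CTCT forward / reverse complement of
TGAG reverse), the standard part overhang for the declared role, and an
18-25 nt annealing region. AarI digestion of the amplicon therefore exposes
CTCT/TGAG, and the ligated Level 0 plasmid reconstitutes inward-facing BsaI
sites that later release the part with its standard overhangs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seq_core import (
    AAR_I,
    BSA_I,
    DnaMolecule,
    count_sites,
    find_sites,
    reverse_complement_seq,
)
from .standard import DEFAULT_STANDARD, MobiusStandard, PartTypeSpec

__all__ = [
    "PartDefinition",
    "PrimerDesign",
    "PrimerDesignError",
    "DomesticationRequiredError",
    "PartReport",
    "design_primers",
    "amplify",
    "verify_part",
    "wallace_tm",
]

_SPACER_CHOICES = ("AAAA", "AACA", "ACAA", "TTAA", "ATTA")


class PrimerDesignError(ValueError):
    pass


class DomesticationRequiredError(PrimerDesignError):
    """The cargo contains internal AarI/BsaI sites; domesticate it first."""


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting estimate: 2(A+T) + 4(G+C). A design aid only."""
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


@dataclass(frozen=True)
class PartDefinition:
    """Cargo span on a template molecule plus its standard part role."""

    template: DnaMolecule
    start: int
    end: int
    role: PartTypeSpec
    name: str = ""

    @property
    def cargo(self) -> str:
        return self.template.sequence[self.start : self.end]

    @property
    def part_name(self) -> str:
        return self.name or f"{self.template.id}[{self.start}:{self.end}]"


@dataclass(frozen=True)
class PrimerDesign:
    forward: str
    reverse: str
    forward_anneal: str
    reverse_anneal: str
    forward_tm: float
    reverse_tm: float
    part_name: str

    @property
    def forward_tail(self) -> str:
        return self.forward[: -len(self.forward_anneal)]

    @property
    def reverse_tail(self) -> str:
        return self.reverse[: -len(self.reverse_anneal)]


def _pick_anneal(
    region: str, tm_bounds: tuple[float, float], lengths: tuple[int, int]
) -> str:
    lo, hi = lengths
    best: tuple[float, str] | None = None
    for k in range(lo, min(hi, len(region)) + 1):
        cand = region[:k]
        tm = wallace_tm(cand)
        if tm_bounds[0] <= tm <= tm_bounds[1]:
            score = abs(tm - 60.0)
            if best is None or score < best[0]:
                best = (score, cand)
    if best is None:
        raise PrimerDesignError(
            f"no annealing region of {lo}-{hi} nt has Tm within {tm_bounds}"
        )
    return best[1]


def _pick_tail(clamp: str, fusion: str, overhang: str, cargo_head: str) -> str:
    """Choose a spacer whose tail introduces no site beyond the intended AarI."""
    for spacer in _SPACER_CHOICES:
        tail = clamp + AAR_I.recognition + spacer + fusion + overhang
        probe = tail + cargo_head
        if count_sites(probe, AAR_I) == 1 and count_sites(probe, BSA_I) == 0:
            return tail
    raise PrimerDesignError("every spacer choice creates a stray recognition site")


def design_primers(
    part: PartDefinition,
    clamp: str = "GG",
    tm_bounds: tuple[float, float] = (40.0, 75.0),
    anneal_lengths: tuple[int, int] = (18, 25),
) -> PrimerDesign:
    """Primer pair onboarding a cargo span into the mUAV.

    Raises :class:`DomesticationRequiredError` when the cargo itself carries
    AarI/BsaI sites, and :class:`PrimerDesignError` when no annealing region
    satisfies the Tm bounds.
    """
    cargo = part.cargo
    if len(cargo) < anneal_lengths[0]:
        raise PrimerDesignError(f"cargo shorter than {anneal_lengths[0]} nt")
    internal = count_sites(cargo, AAR_I) + count_sites(cargo, BSA_I)
    if internal:
        raise DomesticationRequiredError(
            f"cargo of {part.part_name} carries {internal} internal AarI/BsaI "
            "site(s); run domestication first"
        )
    fwd_anneal = _pick_anneal(cargo, tm_bounds, anneal_lengths)
    rev_region = reverse_complement_seq(cargo)
    rev_anneal = _pick_anneal(rev_region, tm_bounds, anneal_lengths)

    fwd_tail = _pick_tail(clamp, "CTCT", part.role.left_overhang, cargo[:10])
    rev_tail = _pick_tail(
        clamp,
        reverse_complement_seq("TGAG"),
        reverse_complement_seq(part.role.right_overhang),
        rev_region[:10],
    )
    return PrimerDesign(
        forward=fwd_tail + fwd_anneal,
        reverse=rev_tail + rev_anneal,
        forward_anneal=fwd_anneal,
        reverse_anneal=rev_anneal,
        forward_tm=wallace_tm(fwd_anneal),
        reverse_tm=wallace_tm(rev_anneal),
        part_name=part.part_name,
    )


def amplify(part: PartDefinition, design: PrimerDesign) -> DnaMolecule:
    """In silico PCR: tailed linear amplicon of the cargo span.

    Template features fully inside the cargo span are carried over.
    """
    offset = len(design.forward_tail)
    seq = design.forward_tail + part.cargo + reverse_complement_seq(design.reverse_tail)
    feats = []
    for f in part.template.features:
        if f.start >= part.start and f.end <= part.end:
            feats.append(
                type(f)(f.label, f.start - part.start + offset, f.end - part.start + offset, f.strand, f.kind)
            )
    return DnaMolecule(f"amplicon:{design.part_name}", seq, "linear", feats)


@dataclass
class PartReport:
    molecule_id: str
    passed: bool
    messages: list[str]


def verify_part(
    level0: DnaMolecule,
    role: PartTypeSpec | None = None,
    standard: MobiusStandard = DEFAULT_STANDARD,
) -> PartReport:
    """Check a Level 0 plasmid conforms to the standard.

    Confirms a circular plasmid with exactly two BsaI sites facing the cargo,
    zero internal AarI/BsaI sites within the released cargo, and (when a role
    is declared) release overhangs matching that role's standard entry.
    """
    from .assembly_sim import _has_resistance  # local to avoid cycle at import

    messages: list[str] = []
    if not level0.is_circular:
        return PartReport(level0.id, False, ["plasmid must be circular"])
    hits = find_sites(level0, BSA_I)
    if len(hits) != 2:
        positions = [h.position for h in hits]
        messages.append(f"expected exactly 2 BsaI sites, found {len(hits)} at {positions}")
        return PartReport(level0.id, False, messages)
    aar_hits = find_sites(level0, AAR_I)
    if aar_hits:
        messages.append(f"{len(aar_hits)} residual AarI site(s) at "
                        f"{[h.position for h in aar_hits]}")
    from .seq_core import digest

    frags = digest(level0, BSA_I)
    cargo_frags = [f for f in frags if not _has_resistance(f)]
    if len(cargo_frags) != 1:
        messages.append("could not identify the cargo fragment by resistance feature")
        return PartReport(level0.id, False, messages)
    cargo = cargo_frags[0]
    internal = count_sites(cargo.core, AAR_I) + count_sites(cargo.core, BSA_I)
    if internal:
        messages.append(f"{internal} forbidden site(s) inside the released cargo")
    if role is not None:
        expected = (role.left_overhang, role.right_overhang)
        got = (cargo.left_overhang, cargo.right_overhang)
        if got != expected:
            messages.append(f"release overhangs {got} do not match role {expected}")
    passed = not messages
    return PartReport(level0.id, passed, messages or ["ok"])


def primers_tsv(designs: Sequence[PrimerDesign]) -> str:
    lines = ["name\tsequence\ttm"]
    for d in designs:
        lines.append(f"{d.part_name}-F\t{d.forward}\t{d.forward_tm:.1f}")
        lines.append(f"{d.part_name}-R\t{d.reverse}\t{d.reverse_tm:.1f}")
    return "\n".join(lines) + "\n"


def primers_fasta(designs: Sequence[PrimerDesign]) -> str:
    out = []
    for d in designs:
        out.append(f">{d.part_name}-F\n{d.forward}")
        out.append(f">{d.part_name}-R\n{d.reverse}")
    return "\n".join(out) + "\n"
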