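"""The Mobius Assembly routing standard as data.

Vector specifications, Auxiliary linker overhang triples, standard part
overhangs and the junction constants. Greek vector names are ASCII-aliased
(G for Gamma, D for Delta) in all machine interfaces; display names keep the
Greek letters.

The whole standard is exportable/importable as a single YAML document so
alternative overhang standards can be used without code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "VectorSpec",
    "LinkerSpec",
    "PartTypeSpec",
    "RoutingTable",
    "MobiusStandard",
    "ChainReport",
    "DEFAULT_STANDARD",
    "vector_spec",
    "linker_spec",
    "part_type",
    "validate_tu_chain",
    "normalize_name",
    "POSITION_LETTERS",
]

POSITION_LETTERS = ("A", "B", "G", "D")
_GREEK = {"A": "A", "B": "B", "G": "Γ", "D": "Δ"}
_ASCII = {"Γ": "G", "Δ": "D", "Г": "G"}


def normalize_name(name: str) -> str:
    """Map Greek letters in vector/linker names to their ASCII aliases."""
    return "".join(_ASCII.get(c, c) for c in name)


@dataclass(frozen=True)
class VectorSpec:
    """Per-vector routing entry: enzymes, overhangs, marker, resistance.

    ``inner_overhangs`` are the 5'/3' 4-mers exposed on the backbone when the
    dropout is excised by the acceptance enzyme; ``outer_overhangs`` are
    exposed when the finished cassette is released by the release enzyme
    (None where the standard leaves them context-defined: the mUAV outer
    overhangs come from the part role, the Level 2 outer 3' from the chosen
    linker's payload overhang).
    """

    name: str
    level: int
    acceptance_enzyme: str
    release_enzyme: str
    inner_overhangs: tuple[str, str]
    outer_overhangs: tuple[str | None, str | None]
    dropout_marker: str
    resistance: str
    backbone_origin: str

    @property
    def display_name(self) -> str:
        return "".join(_GREEK.get(c, c) for c in self.name)


@dataclass(frozen=True)
class LinkerSpec:
    """Auxiliary Plasmid linker: (upstream, payload, downstream) overhangs.

    The upstream overhang anneals to the last cassette of the Level 2 chain,
    the payload overhang is exposed on later release of the Level 2 cassette,
    and the downstream overhang (ACCC for all seven) anneals to the Level 2
    vector. End-to-End linkers close a full four-cassette chain;
    Middle-to-End linkers close a 1-3 cassette chain and always carry the
    CGCT payload needed to continue assembly back to Level 1.
    """

    name: str
    kind: str  # "end_to_end" | "middle_to_end"
    upstream_overhang: str
    payload_overhang: str
    downstream_overhang: str = "ACCC"
    length: int = 50

    @property
    def display_name(self) -> str:
        return "".join(_GREEK.get(c, c) for c in self.name)


@dataclass(frozen=True)
class PartTypeSpec:
    role: str
    left_overhang: str
    right_overhang: str
    frame_sensitive: bool = False


@dataclass(frozen=True)
class RoutingTable:
    """Junction constants of the two-level standard."""

    l1_outer: dict[str, tuple[str, str]]
    l1_inner: tuple[str, str]
    l2_inner: tuple[str, str]
    l2_outer_5: dict[str, str]
    muav_fusion: tuple[str, str]


_L1_OUTER = {"A": ("GGAG", "CAGA"), "B": ("CAGA", "GTCA"), "G": ("GTCA", "CTTG"), "D": ("CTTG", "CGCT")}
_L2_OUTER_5 = {"A": "GGAG", "B": "CAGA", "G": "GTCA", "D": "CTTG"}


def _default_vectors() -> dict[str, VectorSpec]:
    vs: dict[str, VectorSpec] = {
        "mUAV": VectorSpec(
            name="mUAV",
            level=0,
            acceptance_enzyme="AarI",
            release_enzyme="BsaI",
            inner_overhangs=("CTCT", "TGAG"),
            outer_overhangs=(None, None),
            dropout_marker="amilCP",
            resistance="chloramphenicol",
            backbone_origin="pSB1C3",
        )
    }
    for letter in POSITION_LETTERS:
        vs[f"L1-{letter}"] = VectorSpec(
            name=f"L1-{letter}",
            level=1,
            acceptance_enzyme="BsaI",
            release_enzyme="AarI",
            inner_overhangs=("GGAG", "CGCT"),
            outer_overhangs=_L1_OUTER[letter],
            dropout_marker="spisPink",
            resistance="kanamycin",
            backbone_origin="pSB1K3",
        )
        vs[f"L2-{letter}"] = VectorSpec(
            name=f"L2-{letter}",
            level=2,
            acceptance_enzyme="AarI",
            release_enzyme="BsaI",
            inner_overhangs=("GGAG", "ACCC"),
            outer_overhangs=(_L2_OUTER_5[letter], None),
            dropout_marker="sfGFP",
            resistance="chloramphenicol",
            backbone_origin="pSB1C3",
        )
    return vs


def _default_linkers() -> dict[str, LinkerSpec]:
    end_payload = {"4A": "CAGA", "4B": "GTCA", "4G": "CTTG", "4D": "CGCT"}
    mid_upstream = {"M1": "CAGA", "M2": "GTCA", "M3": "CTTG"}
    ls: dict[str, LinkerSpec] = {}
    for name, payload in end_payload.items():
        ls[name] = LinkerSpec(name, "end_to_end", "CGCT", payload)
    for name, upstream in mid_upstream.items():
        ls[name] = LinkerSpec(name, "middle_to_end", upstream, "CGCT")
    return ls


def _default_part_types() -> dict[str, PartTypeSpec]:
    # MoClo/Phytobrick internal junction convention; configurable via YAML.
    return {
        "promoter": PartTypeSpec("promoter", "GGAG", "AATG"),
        "CDS": PartTypeSpec("CDS", "AATG", "GCTT", frame_sensitive=True),
        "terminator": PartTypeSpec("terminator", "GCTT", "CGCT"),
    }


@dataclass
class MobiusStandard:
    """The 16-entry standard: 9 acceptor vectors + 7 auxiliary linkers."""

    vectors: dict[str, VectorSpec] = field(default_factory=_default_vectors)
    linkers: dict[str, LinkerSpec] = field(default_factory=_default_linkers)
    part_types: dict[str, PartTypeSpec] = field(default_factory=_default_part_types)

    def __len__(self) -> int:
        return len(self.vectors) + len(self.linkers)

    @property
    def routing(self) -> RoutingTable:
        return RoutingTable(
            l1_outer={k: self.vectors[f"L1-{k}"].outer_overhangs for k in POSITION_LETTERS},
            l1_inner=self.vectors["L1-A"].inner_overhangs,
            l2_inner=self.vectors["L2-A"].inner_overhangs,
            l2_outer_5={k: self.vectors[f"L2-{k}"].outer_overhangs[0] for k in POSITION_LETTERS},
            muav_fusion=self.vectors["mUAV"].inner_overhangs,
        )

    def vector_spec(self, name: str) -> VectorSpec:
        key = normalize_name(name)
        try:
            return self.vectors[key]
        except KeyError:
            raise KeyError(f"unknown vector {name!r}; known: {sorted(self.vectors)}") from None

    def linker_spec(self, name: str) -> LinkerSpec:
        key = normalize_name(str(name))
        if key in ("1", "2", "3"):  # Middle-to-End linkers by numeric label
            key = f"M{key}"
        try:
            return self.linkers[key]
        except KeyError:
            raise KeyError(f"unknown linker {name!r}; known: {sorted(self.linkers)}") from None

    def part_type(self, role: str) -> PartTypeSpec:
        try:
            return self.part_types[role]
        except KeyError:
            raise KeyError(f"unknown part role {role!r}; known: {sorted(self.part_types)}") from None

    # -- chain arithmetic ---------------------------------------------------

    def level2_chain(self, size: int, linker_name: str) -> list[tuple[str, str]]:
        """Junction-labelled chain of ``size`` Level 1 cassettes plus a linker.

        Returns the ordered (5', 3') overhang pairs; the chain is well formed
        iff consecutive labels match, it starts at the Level 2 inner 5' and
        the linker terminates at the Level 2 inner 3'.
        """
        if not 1 <= size <= 4:
            raise ValueError("a Level 2 reaction fuses 1-4 cassettes")
        chain = [self.vectors[f"L1-{POSITION_LETTERS[i]}"].outer_overhangs for i in range(size)]
        lk = self.linker_spec(linker_name)
        chain.append((lk.upstream_overhang, lk.downstream_overhang))
        return chain

    def chain_is_closed(self, size: int, linker_name: str) -> bool:
        chain = self.level2_chain(size, linker_name)
        inner5, inner3 = self.vectors["L2-A"].inner_overhangs
        if chain[0][0] != inner5 or chain[-1][1] != inner3:
            return False
        return all(a[1] == b[0] for a, b in zip(chain, chain[1:]))

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "vectors": {
                k: {
                    "level": v.level,
                    "acceptance_enzyme": v.acceptance_enzyme,
                    "release_enzyme": v.release_enzyme,
                    "inner_overhangs": list(v.inner_overhangs),
                    "outer_overhangs": list(v.outer_overhangs),
                    "dropout_marker": v.dropout_marker,
                    "resistance": v.resistance,
                    "backbone_origin": v.backbone_origin,
                }
                for k, v in self.vectors.items()
            },
            "linkers": {
                k: {
                    "kind": l.kind,
                    "upstream_overhang": l.upstream_overhang,
                    "payload_overhang": l.payload_overhang,
                    "downstream_overhang": l.downstream_overhang,
                    "length": l.length,
                }
                for k, l in self.linkers.items()
            },
            "part_types": {
                k: {
                    "left_overhang": p.left_overhang,
                    "right_overhang": p.right_overhang,
                    "frame_sensitive": p.frame_sensitive,
                }
                for k, p in self.part_types.items()
            },
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "MobiusStandard":
        doc = yaml.safe_load(text)
        vectors = {
            k: VectorSpec(
                name=k,
                level=v["level"],
                acceptance_enzyme=v["acceptance_enzyme"],
                release_enzyme=v["release_enzyme"],
                inner_overhangs=tuple(v["inner_overhangs"]),
                outer_overhangs=tuple(v["outer_overhangs"]),
                dropout_marker=v["dropout_marker"],
                resistance=v["resistance"],
                backbone_origin=v["backbone_origin"],
            )
            for k, v in doc["vectors"].items()
        }
        linkers = {
            k: LinkerSpec(
                name=k,
                kind=l["kind"],
                upstream_overhang=l["upstream_overhang"],
                payload_overhang=l["payload_overhang"],
                downstream_overhang=l["downstream_overhang"],
                length=l["length"],
            )
            for k, l in doc["linkers"].items()
        }
        part_types = {
            k: PartTypeSpec(k, p["left_overhang"], p["right_overhang"], p["frame_sensitive"])
            for k, p in doc["part_types"].items()
        }
        return cls(vectors=vectors, linkers=linkers, part_types=part_types)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "MobiusStandard":
        return cls.from_yaml(Path(path).read_text())


DEFAULT_STANDARD = MobiusStandard()


def vector_spec(name: str, standard: MobiusStandard = DEFAULT_STANDARD) -> VectorSpec:
    """Immutable standard entry for a vector name (Greek or ASCII alias)."""
    return standard.vector_spec(name)


def linker_spec(name: str, standard: MobiusStandard = DEFAULT_STANDARD) -> LinkerSpec:
    return standard.linker_spec(name)


def part_type(role: str, standard: MobiusStandard = DEFAULT_STANDARD) -> PartTypeSpec:
    return standard.part_type(role)


@dataclass(frozen=True)
class ChainReport:
    valid: bool
    mismatch_index: int | None = None
    message: str = "ok"


def validate_tu_chain(
    parts: list[PartTypeSpec],
    start: str = "GGAG",
    end: str = "CGCT",
) -> ChainReport:
    """Check a chain of part types forms a transcriptional unit.

    Valid iff consecutive overhangs match, the chain starts at ``start``
    (GGAG) and ends at ``end`` (CGCT). Reports the first mismatch position.
    """
    if not parts:
        raise ValueError("empty part chain")
    if parts[0].left_overhang != start:
        return ChainReport(False, 0, f"chain starts {parts[0].left_overhang}, expected {start}")
    for i, (a, b) in enumerate(zip(parts, parts[1:])):
        if a.right_overhang != b.left_overhang:
            return ChainReport(
                False, i + 1, f"junction {a.right_overhang}|{b.left_overhang} does not match"
            )
    if parts[-1].right_overhang != end:
        return ChainReport(
            False, len(parts) - 1, f"chain ends {parts[-1].right_overhang}, expected {end}"
        )
    return ChainReport(True)
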