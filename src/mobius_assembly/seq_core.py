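"""Double-stranded DNA primitives and Type IIS digestion mechanics.

Coordinates are 0-based, half-open, on the top strand. For circular
molecules all position arithmetic is modulo the sequence length, with the
origin between position ``len - 1`` and ``0``.

Every sticky end is recorded as the top-strand 4-mer spanning the cut, so
two ends are ligation-compatible iff their 4-mers are equal. This collapses
the top/bottom 5' extension asymmetry into a single comparable token and
makes the ligation graph a plain label-matching graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlphabetError",
    "GeometryError",
    "Feature",
    "DnaMolecule",
    "TypeIISEnzyme",
    "SiteHit",
    "StickyFragment",
    "AAR_I",
    "BSA_I",
    "ENZYMES",
    "get_enzyme",
    "reverse_complement",
    "reverse_complement_seq",
    "find_sites",
    "count_sites",
    "digest",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_genbank",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")


class AlphabetError(ValueError):
    """Sequence contains characters outside the strict {A,C,G,T} alphabet."""


class GeometryError(ValueError):
    """A cut coordinate falls outside a linear molecule."""


def reverse_complement_seq(seq: str) -> str:
    """Watson-Crick reverse complement of a top-strand string."""
    bad = set(seq) - _VALID_BASES
    if bad:
        raise AlphabetError(f"invalid bases {sorted(bad)} (IUPAC degeneracy is rejected)")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """Annotation on a molecule: half-open [start, end) on the top strand.

    ``kind`` carries assembly semantics ("marker", "resistance", "payload",
    "linker") or a plain GenBank-style key.
    """

    label: str
    start: int
    end: int
    strand: int = 1
    kind: str = "misc_feature"


@dataclass
class DnaMolecule:
    """Annotated double-stranded sequence, represented by its top strand."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise AlphabetError("empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise AlphabetError(
                f"invalid bases {sorted(bad)} in molecule {self.id!r} "
                "(IUPAC degeneracy is rejected)"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def rotated(self, offset: int) -> "DnaMolecule":
        """Circular molecule re-written with its origin shifted by ``offset``."""
        if not self.is_circular:
            raise ValueError("only circular molecules can be rotated")
        n = len(self.sequence)
        k = offset % n
        feats = [
            replace(f, start=(f.start - k) % n, end=((f.end - k - 1) % n) + 1)
            for f in self.features
        ]
        return DnaMolecule(self.id, self.sequence[k:] + self.sequence[:k], "circular", feats)

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


def reverse_complement(m: DnaMolecule) -> DnaMolecule:
    """Reverse complement with feature coordinates and strands flipped."""
    n = len(m.sequence)
    feats = [
        Feature(f.label, n - f.end, n - f.start, -f.strand, f.kind) for f in m.features
    ]
    return DnaMolecule(m.id, reverse_complement_seq(m.sequence), m.topology, feats)


@dataclass(frozen=True)
class TypeIISEnzyme:
    """Type IIS enzyme cutting downstream of a non-palindromic recognition.

    ``spacer`` is the number of nucleotides between the recognition end and
    the top-strand cut; the bottom-strand cut offset is
    ``spacer + overhang_len``, leaving a 4-nt 5' extension for both built-ins.
    """

    name: str
    recognition: str
    spacer: int
    overhang_len: int

    def __post_init__(self) -> None:
        if self.spacer < 0:
            raise ValueError("spacer must be >= 0")
        if self.overhang_len <= 0:
            raise ValueError("overhang_len must be positive")
        bad = set(self.recognition) - _VALID_BASES
        if bad:
            raise AlphabetError(f"invalid recognition bases {sorted(bad)}")

    @property
    def rc_recognition(self) -> str:
        return reverse_complement_seq(self.recognition)


# AarI recognizes the 7-bp CACCTGC(4/8); BsaI is the classic GGTCTC(1/5).
AAR_I = TypeIISEnzyme("AarI", "CACCTGC", 4, 4)
BSA_I = TypeIISEnzyme("BsaI", "GGTCTC", 1, 4)
ENZYMES: dict[str, TypeIISEnzyme] = {e.name: e for e in (AAR_I, BSA_I)}


def get_enzyme(name: str) -> TypeIISEnzyme:
    try:
        return ENZYMES[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; registered: {sorted(ENZYMES)}") from None


@dataclass(frozen=True)
class SiteHit:
    """One recognition-site occurrence with its cut coordinates.

    For a + strand hit ``cut_top = position + len(recognition) + spacer`` and
    ``cut_bottom = cut_top + overhang_len``; mirrored arithmetic on -.
    Coordinates are taken modulo length for circular molecules; for linear
    molecules they may fall outside [0, len] (digest then raises).
    """

    enzyme: str
    position: int
    strand: str
    cut_top: int
    cut_bottom: int


def _occurrences(text: str, motif: str, limit: int) -> list[int]:
    """Start positions < limit of motif in text (overlaps allowed)."""
    out = []
    i = text.find(motif)
    while i != -1 and i < limit:
        out.append(i)
        i = text.find(motif, i + 1)
    return out


def find_sites(m: DnaMolecule, enzyme: TypeIISEnzyme) -> list[SiteHit]:
    """All recognition occurrences on both strands, sorted by position.

    For circular molecules occurrences spanning the origin are found by
    scanning the doubled-and-truncated linearization.
    """
    n = len(m.sequence)
    rec = enzyme.recognition
    rc = enzyme.rc_recognition
    if m.is_circular:
        text = m.sequence + m.sequence[: len(rec) - 1]
    else:
        text = m.sequence
    hits: list[SiteHit] = []
    for pos in _occurrences(text, rec, n):
        cut_top = pos + len(rec) + enzyme.spacer
        cut_bottom = cut_top + enzyme.overhang_len
        if m.is_circular:
            cut_top, cut_bottom = cut_top % n, cut_bottom % n
        hits.append(SiteHit(enzyme.name, pos, "+", cut_top, cut_bottom))
    for pos in _occurrences(text, rc, n):
        cut_top = pos - enzyme.spacer - enzyme.overhang_len
        cut_bottom = pos - enzyme.spacer
        if m.is_circular:
            cut_top, cut_bottom = cut_top % n, cut_bottom % n
        hits.append(SiteHit(enzyme.name, pos, "-", cut_top, cut_bottom))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def count_sites(seq: str, enzyme: TypeIISEnzyme, circular: bool = False) -> int:
    """Intact recognition-site count on both strands of a sequence string."""
    n = len(seq)
    text = seq + seq[: len(enzyme.recognition) - 1] if circular else seq
    return len(_occurrences(text, enzyme.recognition, n)) + len(
        _occurrences(text, enzyme.rc_recognition, n)
    )


@dataclass
class StickyFragment:
    """Linear duplex with 4-nt 5' extensions recorded as top-strand 4-mers.

    ``core`` includes both terminal overhang sequences, so the two overhang
    strings are substrings of ``core`` at its ends. ``carries_sites`` counts
    intact recognition sites remaining anywhere on either strand of the core
    (a site spanning a cut junction counts only once completed by ligation,
    but the core string includes the single-stranded overhang region, so a
    junction-straddling remnant is counted; product validity is always
    re-derived from the full ligated sequence).
    """

    core: str
    left_overhang: str
    right_overhang: str
    source: str
    carries_sites: dict[str, int] = field(default_factory=dict)
    features: list[Feature] = field(default_factory=list)
    uncut: bool = False

    def __len__(self) -> int:
        return len(self.core)

    @property
    def is_blunt(self) -> bool:
        return not self.left_overhang and not self.right_overhang

    def reverse_complement(self) -> "StickyFragment":
        n = len(self.core)
        feats = [
            Feature(f.label, n - f.end, n - f.start, -f.strand, f.kind)
            for f in self.features
        ]
        return StickyFragment(
            core=reverse_complement_seq(self.core),
            left_overhang=reverse_complement_seq(self.right_overhang)
            if self.right_overhang
            else "",
            right_overhang=reverse_complement_seq(self.left_overhang)
            if self.left_overhang
            else "",
            source=self.source,
            carries_sites=dict(self.carries_sites),
            features=feats,
            uncut=self.uncut,
        )


def _slice_circular(seq: str, start: int, length: int) -> str:
    n = len(seq)
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    doubled = seq + seq
    # length may exceed n by the overhang width when there is a single cut
    if start + length <= 2 * n:
        return doubled[start : start + length]
    return (doubled + seq)[start : start + length]


def _contained_features(
    m: DnaMolecule, frag_start: int, frag_len: int
) -> list[Feature]:
    """Parent features fully contained in the fragment span, re-based."""
    n = len(m.sequence)
    out = []
    for f in m.features:
        flen = f.end - f.start
        if flen < 0 or flen > frag_len:
            continue
        if m.is_circular:
            rel = (f.start - frag_start) % n
        else:
            rel = f.start - frag_start
        if 0 <= rel and rel + flen <= frag_len:
            out.append(Feature(f.label, rel, rel + flen, f.strand, f.kind))
    out.sort(key=lambda f: f.start)
    return out


def digest(m: DnaMolecule, enzyme: TypeIISEnzyme) -> list[StickyFragment]:
    """Cut a molecule at every site of ``enzyme`` into sticky fragments.

    A circular molecule with k cuts yields k fragments; a linear molecule
    with k cuts yields k+1 (terminal fragments blunt on their outer ends).
    A circular molecule with no sites is returned intact, flagged ``uncut``.
    A cut running off a linear end raises :class:`GeometryError`.
    """
    hits = find_sites(m, enzyme)
    n = len(m.sequence)
    ov = enzyme.overhang_len

    if not hits:
        frag = StickyFragment(
            core=m.sequence,
            left_overhang="",
            right_overhang="",
            source=m.id,
            carries_sites={enzyme.name: 0},
            features=list(m.features),
            uncut=m.is_circular,
        )
        return [frag]

    if not m.is_circular:
        for h in hits:
            if h.cut_top < 0 or h.cut_bottom > n:
                raise GeometryError(
                    f"cut at {h.cut_top}/{h.cut_bottom} runs off linear molecule "
                    f"{m.id!r} (length {n})"
                )

    cuts = sorted({h.cut_top % n if m.is_circular else h.cut_top for h in hits})
    frags: list[StickyFragment] = []

    def make(start: int, core: str, left: str, right: str) -> StickyFragment:
        return StickyFragment(
            core=core,
            left_overhang=left,
            right_overhang=right,
            source=m.id,
            carries_sites={enzyme.name: count_sites(core, enzyme)},
            features=_contained_features(m, start, len(core)),
        )

    if m.is_circular:
        k = len(cuts)
        for i, a in enumerate(cuts):
            b = cuts[(i + 1) % k]
            span = (b - a) % n if k > 1 else n
            core = _slice_circular(m.sequence, a, span + ov)
            frags.append(make(a, core, core[:ov], core[-ov:]))
    else:
        first = cuts[0]
        core = m.sequence[: first + ov]
        frags.append(make(0, core, "", core[-ov:]))
        for a, b in zip(cuts, cuts[1:]):
            core = m.sequence[a : b + ov]
            frags.append(make(a, core, core[:ov], core[-ov:]))
        last = cuts[-1]
        core = m.sequence[last:]
        frags.append(make(last, core, core[:ov], ""))
    return frags


# ---------------------------------------------------------------------------
# FASTA / GenBank plumbing
# ---------------------------------------------------------------------------

_STANDARD_KEYS = {"CDS", "promoter", "terminator", "misc_feature", "primer_bind"}
_KIND_TO_KEY = {
    "payload": "CDS",
    "marker": "CDS",
    "resistance": "CDS",
    "linker": "misc_feature",
}


def _to_record(m: DnaMolecule) -> SeqRecord:
    rec = SeqRecord(Seq(m.sequence), id=m.id, name=m.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = m.topology
    for f in m.features:
        key = f.kind if f.kind in _STANDARD_KEYS else _KIND_TO_KEY.get(f.kind, "misc_feature")
        sf = SeqFeature(
            FeatureLocation(f.start, f.end, strand=f.strand),
            type=key,
            qualifiers={"label": [f.label], "note": [f"mobius:kind={f.kind}"]},
        )
        rec.features.append(sf)
    return rec


def _from_record(rec: SeqRecord, topology: str | None = None) -> DnaMolecule:
    topo = topology or rec.annotations.get("topology", "linear")
    feats = []
    for sf in rec.features:
        if sf.location is None:
            continue
        kind = sf.type
        for note in sf.qualifiers.get("note", []):
            if note.startswith("mobius:kind="):
                kind = note.split("=", 1)[1]
        label = sf.qualifiers.get("label", [sf.type])[0]
        feats.append(
            Feature(
                label,
                int(sf.location.start),
                int(sf.location.end),
                sf.location.strand or 1,
                kind,
            )
        )
    return DnaMolecule(rec.id, str(rec.seq), topo, feats)


def write_genbank(molecules: Iterable[DnaMolecule], path: str | Path) -> None:
    SeqIO.write([_to_record(m) for m in molecules], str(path), "genbank")


def read_genbank(path: str | Path) -> list[DnaMolecule]:
    return [_from_record(rec) for rec in SeqIO.parse(str(path), "genbank")]


def write_fasta(molecules: Iterable[DnaMolecule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in molecules:
            tag = " [circular]" if m.is_circular else ""
            fh.write(f">{m.id}{tag}\n")
            for i in range(0, len(m.sequence), 70):
                fh.write(m.sequence[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> list[DnaMolecule]:
    """FASTA reader; topology defaults to linear unless the description
    carries a ``[circular]`` tag."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topo = "circular" if "[circular]" in rec.description else "linear"
        out.append(DnaMolecule(rec.id, str(rec.seq), topo))
    if not out:
        raise IOError(f"no FASTA records in {path}")
    return out
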