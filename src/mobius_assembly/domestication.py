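"""Forbidden-site scanning, synonymous-codon domestication and the analytic
domestication-burden model.

The burden model assumes i.i.d. uniform bases (GC = 50%): a non-palindromic
recognition of length L is expected at 2 * 4**(-L) sites per bp counting
both strands. Swapping one 6-bp cutter of a three-enzyme system for the 7-bp
AarI drops the expected burden by 1 - (4**-6 + 4**-7) / (3 * 4**-6) = 7/12
(58.3%), and by 3/8 (37.5%) against a two-enzyme 6-bp system; the ratio is
invariant to the strand factor. GC-weighted densities are offered as an
option but are not used for the headline numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .seq_core import (
    DnaMolecule,
    Feature,
    SiteHit,
    TypeIISEnzyme,
    find_sites,
    reverse_complement_seq,
)

__all__ = [
    "SiteReport",
    "BurdenModel",
    "DomesticationEdit",
    "UnresolvableSiteError",
    "scan",
    "site_density",
    "burden_reduction",
    "domesticate_cds",
    "apply_edits",
    "site_report_tsv",
    "annotate_hits",
]


@dataclass
class SiteReport:
    molecule_id: str
    hits: list[SiteHit] = field(default_factory=list)

    @property
    def needs_domestication(self) -> bool:
        return bool(self.hits)


def scan(m: DnaMolecule, forbidden: Sequence[TypeIISEnzyme]) -> SiteReport:
    """All hits of every forbidden enzyme on both strands, merged and sorted."""
    hits: list[SiteHit] = []
    for enzyme in forbidden:
        hits.extend(find_sites(m, enzyme))
    hits.sort(key=lambda h: (h.position, h.enzyme, h.strand))
    return SiteReport(m.id, hits)


def site_density(recognition_lengths: Sequence[int]) -> float:
    """Expected recognition sites per bp, both strands, i.i.d. uniform bases:
    sum over the set of 2 * 4**-L."""
    if not recognition_lengths:
        raise ValueError("empty enzyme set")
    return sum(2.0 * 4.0 ** (-L) for L in recognition_lengths)


def site_density_gc(recognitions: Sequence[str], gc: float) -> float:
    """GC-weighted variant for concrete recognition sequences (optional
    model; the headline burden numbers use the uniform one)."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    total = 0.0
    for rec in recognitions:
        p = 1.0
        for base in rec:
            p *= gc / 2 if base in "GC" else (1 - gc) / 2
        q = 1.0
        for base in reverse_complement_seq(rec):
            q *= gc / 2 if base in "GC" else (1 - gc) / 2
        total += p + q
    return total


@dataclass(frozen=True)
class BurdenModel:
    """Expected site density of an enzyme set under i.i.d. uniform bases."""

    recognition_lengths: tuple[int, ...]

    @property
    def per_bp_density(self) -> float:
        return site_density(self.recognition_lengths)

    def expected_hits(self, length_bp: int) -> float:
        return self.per_bp_density * length_bp


def burden_reduction(new_set: Sequence[int], reference_set: Sequence[int]) -> float:
    """Percent drop in expected domestication burden: 100*(1 - new/ref)."""
    ref = site_density(reference_set)
    if ref == 0:
        raise ValueError("reference enzyme set has zero site density")
    return 100.0 * (1.0 - site_density(new_set) / ref)


# ---------------------------------------------------------------------------
# Synonymous-codon domestication
# ---------------------------------------------------------------------------

# Approximate E. coli K-12 relative codon usage; tie-break determinism only.
CODON_USAGE: dict[str, float] = {
    "TTT": 0.57, "TTC": 0.43, "TTA": 0.13, "TTG": 0.13, "CTT": 0.10, "CTC": 0.10,
    "CTA": 0.04, "CTG": 0.50, "ATT": 0.51, "ATC": 0.42, "ATA": 0.07, "ATG": 1.00,
    "GTT": 0.26, "GTC": 0.22, "GTA": 0.15, "GTG": 0.37, "TCT": 0.15, "TCC": 0.15,
    "TCA": 0.12, "TCG": 0.15, "AGT": 0.15, "AGC": 0.28, "CCT": 0.16, "CCC": 0.12,
    "CCA": 0.19, "CCG": 0.53, "ACT": 0.17, "ACC": 0.44, "ACA": 0.13, "ACG": 0.27,
    "GCT": 0.16, "GCC": 0.27, "GCA": 0.21, "GCG": 0.36, "TAT": 0.57, "TAC": 0.43,
    "TAA": 0.64, "TAG": 0.07, "TGA": 0.29, "CAT": 0.57, "CAC": 0.43, "CAA": 0.35,
    "CAG": 0.65, "AAT": 0.45, "AAC": 0.55, "GAT": 0.63, "GAC": 0.37, "GAA": 0.69,
    "GAG": 0.31, "TGT": 0.45, "TGC": 0.55, "TGG": 1.00, "CGT": 0.38, "CGC": 0.40,
    "CGA": 0.06, "CGG": 0.10, "AGA": 0.04, "AGG": 0.02, "GGT": 0.34, "GGC": 0.40,
    "GGA": 0.11, "GGG": 0.15,
}

_TABLE = standard_dna_table
_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)
_SYNONYMS["*"] = sorted(_TABLE.stop_codons)


def _codon_aa(codon: str) -> str:
    return "*" if codon in _TABLE.stop_codons else _TABLE.forward_table[codon]


@dataclass(frozen=True)
class DomesticationEdit:
    """Single synonymous codon replacement breaking one forbidden site."""

    position: int  # codon index within the coding span
    original: str
    replacement: str
    broken_site: SiteHit
    new_sites_created: int = 0


class UnresolvableSiteError(ValueError):
    def __init__(self, span: tuple[int, int], message: str):
        self.span = span
        super().__init__(f"forbidden site at {span} cannot be removed: {message}")


def _hit_keys(seq: str, forbidden: Sequence[TypeIISEnzyme]) -> set[tuple[str, int, str]]:
    m = DnaMolecule("_scan", seq, "linear")
    return {(h.enzyme, h.position, h.strand) for e in forbidden for h in find_sites(m, e)}


def apply_edits(sequence: str, frame_offset: int, edits: Sequence[DomesticationEdit]) -> str:
    seq = list(sequence)
    for e in edits:
        start = frame_offset + 3 * e.position
        if seq[start : start + 3] != list(e.original):
            raise ValueError(f"edit at codon {e.position} does not match the sequence")
        seq[start : start + 3] = list(e.replacement)
    return "".join(seq)


def domesticate_cds(
    m: DnaMolecule,
    frame_offset: int = 0,
    forbidden: Sequence[TypeIISEnzyme] | None = None,
) -> list[DomesticationEdit]:
    """Minimal synonymous single-codon edits removing every forbidden site.

    Works hit by hit (fixpoint loop, re-scanning after each applied edit):
    for the left-most remaining hit, every codon overlapping the recognition
    span is tried with every synonymous replacement; a candidate must remove
    that hit and must not create any hit absent before. Tie-break, in order:
    prefer changes confined to the codon third position, then the
    highest-usage synonymous codon, then the lowest codon position. Raises
    :class:`UnresolvableSiteError` when no synonymous change can break a
    site (e.g. runs of Met/Trp codons).
    """
    from .seq_core import AAR_I, BSA_I

    if forbidden is None:
        forbidden = [AAR_I, BSA_I]
    seq = m.sequence
    n_coding = len(seq) - frame_offset
    if n_coding <= 0 or n_coding % 3 != 0:
        raise ValueError("coding span length must be a positive multiple of 3")
    n_codons = n_coding // 3

    edits: list[DomesticationEdit] = []
    for _ in range(len(seq)):  # bounded fixpoint loop
        current = _hit_keys(seq, forbidden)
        if not current:
            break
        enzymes = {e.name: e for e in forbidden}
        name, pos, strand = min(current, key=lambda k: (k[1], k[0], k[2]))
        span = (pos, pos + len(enzymes[name].recognition))
        lo = max(span[0], frame_offset)
        hi = min(span[1], frame_offset + 3 * n_codons)
        if lo >= hi:
            raise UnresolvableSiteError(span, "site lies outside the coding span")
        first_codon = (lo - frame_offset) // 3
        last_codon = (hi - 1 - frame_offset) // 3
        hit_key = (name, pos, strand)

        candidates: list[tuple[tuple, DomesticationEdit, str]] = []
        for ci in range(first_codon, last_codon + 1):
            start = frame_offset + 3 * ci
            orig = seq[start : start + 3]
            for alt in _SYNONYMS[_codon_aa(orig)]:
                if alt == orig:
                    continue
                trial = seq[:start] + alt + seq[start + 3 :]
                new_keys = _hit_keys(trial, forbidden)
                if hit_key in new_keys or not new_keys <= current:
                    continue
                changed = {i for i in range(3) if orig[i] != alt[i]}
                sort_key = (0 if changed == {2} else 1, -CODON_USAGE.get(alt, 0.0), ci)
                edit = DomesticationEdit(
                    position=ci,
                    original=orig,
                    replacement=alt,
                    broken_site=SiteHit(name, pos, strand, -1, -1),
                )
                candidates.append((sort_key, edit, trial))
        if not candidates:
            raise UnresolvableSiteError(span, "no synonymous codon change breaks it")
        candidates.sort(key=lambda c: c[0])
        _, edit, seq = candidates[0]
        edits.append(edit)

    final = apply_edits(m.sequence, frame_offset, edits)
    assert final == seq
    before = Seq(m.sequence[frame_offset:]).translate()
    after = Seq(seq[frame_offset:]).translate()
    assert before == after, "domestication must preserve the protein sequence"
    return edits


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def site_report_tsv(reports: Sequence[SiteReport]) -> str:
    lines = ["molecule\tenzyme\tposition\tstrand"]
    for r in reports:
        for h in r.hits:
            lines.append(f"{r.molecule_id}\t{h.enzyme}\t{h.position}\t{h.strand}")
    return "\n".join(lines) + "\n"


def annotate_hits(m: DnaMolecule, report: SiteReport) -> DnaMolecule:
    """Copy of the molecule with a misc_feature on every forbidden hit."""
    from .seq_core import ENZYMES

    n = len(m.sequence)
    feats = list(m.features)
    for h in report.hits:
        end = min(h.position + len(ENZYMES[h.enzyme].recognition), n)
        feats.append(
            Feature(
                f"{h.enzyme} site",
                h.position,
                end,
                1 if h.strand == "+" else -1,
                "misc_feature",
            )
        )
    feats.sort(key=lambda f: f.start)
    return DnaMolecule(m.id, m.sequence, m.topology, feats)
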