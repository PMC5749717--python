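"""Deterministic synthetic 16-vector toolkit and dummy parts.

The generated plasmids reproduce the standard's site architecture — correct
enzymes, overhang routing, dropout markers and resistances — without any
claim of sequence identity to the deposited vectors. Markers are
length-realistic labelled stubs, not real coding sequences.

Junction layouts (top strand, left to right):

* mUAV uses the overlapping-site layout: the backbone ends ``GGT`` and AarI
  exposes the adjacent ``CTCT``, so ligating a CTCT-tailed insert
  reconstitutes an inward-facing BsaI site (GGTCTC) whose spacer ``T`` is
  the last base of CTCT; mirrored on the right, ``TGAG`` + ``ACC`` holds the
  bottom-strand BsaI recognition. AarI cuts through the BsaI sequence.
* Level 1/2 acceptors use plain non-overlapping inward AarI/BsaI placements:
  release recognitions sit in the backbone outside the inner cuts; the
  acceptance recognitions sit inside the dropout, pointing outward, so
  dropout fragments retain their sites and can never re-ligate validly.
* Auxiliary Plasmids hold a 50-bp linker (released intact by AarI) whose
  internal bottom-strand BsaI recognition exposes the payload overhang on
  later release of the Level 2 cassette.

EcoRI/PstI sites flank every cassette, enabling backbone-swap demos.
Generation is a pure function of the config: same seed, same bytes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .assembly_sim import ReactionMix, TuParts, simulate_one_pot
from .onboarding import PartDefinition, PrimerDesignError, amplify, design_primers
from .seq_core import (
    AAR_I,
    BSA_I,
    DnaMolecule,
    Feature,
    count_sites,
    reverse_complement_seq,
    write_genbank,
)
from .standard import DEFAULT_STANDARD, MobiusStandard, POSITION_LETTERS, normalize_name

__all__ = [
    "FixtureConfig",
    "SyntheticToolkit",
    "FixtureGenerationError",
    "build_toolkit",
    "build_dummy_tu_parts",
    "export_toolkit",
]

_SP4 = 4  # AarI (4/8): four spacer nt between recognition and cut 4-mer
_AARI_F = "CACCTGC"
_AARI_R = "GCAGGTG"
_BSAI_F = "GGTCTC"
_BSAI_R = "GAGACC"
_ECORI = "GAATTC"
_PSTI = "CTGCAG"
_FORBIDDEN = (_AARI_F, _AARI_R, _BSAI_F, _BSAI_R, _ECORI, _PSTI)

_RESISTANCE_LABEL = {"chloramphenicol": "CamR", "kanamycin": "KanR"}


class FixtureGenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 1
    backbone_stub_length: int = 2000
    marker_stub_lengths: dict = field(
        default_factory=lambda: {"amilCP": 330, "spisPink": 340, "sfGFP": 350}
    )
    cargo_length_range: tuple[int, int] = (150, 250)
    max_retries: int = 25


@dataclass
class SyntheticToolkit:
    """9 acceptor plasmids + 7 auxiliary plasmids, keyed by ASCII name."""

    vectors: dict[str, DnaMolecule]
    standard: MobiusStandard
    config: FixtureConfig

    def __len__(self) -> int:
        return len(self.vectors)

    def vector(self, name: str) -> DnaMolecule:
        key = normalize_name(name)
        try:
            return self.vectors[key]
        except KeyError:
            raise KeyError(f"no toolkit vector {name!r}; known: {sorted(self.vectors)}") from None

    def auxiliary(self, linker_name: str) -> DnaMolecule:
        return self.vector(f"AP-{normalize_name(linker_name)}")

    def acceptors(self) -> list[DnaMolecule]:
        return [m for k, m in self.vectors.items() if not k.startswith("AP-")]

    def auxiliaries(self) -> list[DnaMolecule]:
        return [m for k, m in self.vectors.items() if k.startswith("AP-")]


def _clean_random(rng: random.Random, n: int, extra_forbidden: tuple[str, ...] = ()) -> str:
    """Random sequence free of recognition/flank motifs on either strand."""
    motifs = _FORBIDDEN + extra_forbidden
    seq = [rng.choice("ACGT") for _ in range(n)]
    for _ in range(200):
        s = "".join(seq)
        hit = None
        for m in motifs:
            i = s.find(m)
            if i != -1 and (hit is None or i < hit[0]):
                hit = (i, m)
        if hit is None:
            return s
        i, m = hit
        j = i + rng.randrange(len(m))
        old = seq[j]
        seq[j] = rng.choice([b for b in "ACGT" if b != old])
    raise FixtureGenerationError("could not scrub forbidden motifs from a random stub")


def _backbone(rng: random.Random, cfg: FixtureConfig, resistance: str, origin: str):
    """Backbone stub with a labelled resistance feature."""
    seq = _clean_random(rng, cfg.backbone_stub_length)
    label = _RESISTANCE_LABEL[resistance]
    res_len = min(660, len(seq) - 120)
    feat = Feature(label, 60, 60 + res_len, 1, "resistance")
    origin_feat = Feature(origin, 60 + res_len + 20, min(60 + res_len + 220, len(seq)), 1, "misc_feature")
    return seq, [feat, origin_feat]


def _assemble(
    name: str,
    pieces: list[tuple[str, str | None, str | None]],
    expected: dict[str, int],
) -> DnaMolecule:
    """Concatenate (seq, label, kind) pieces into a circular plasmid and
    verify the exact expected site counts."""
    parts = []
    feats = []
    pos = 0
    for seq, label, kind in pieces:
        if label is not None:
            feats.append(Feature(label, pos, pos + len(seq), 1, kind or "misc_feature"))
        parts.append(seq)
        pos += len(seq)
    full = "".join(parts)
    mol = DnaMolecule(name, full, "circular", feats)
    for enzyme, want in (
        (AAR_I, expected.get("AarI", 0)),
        (BSA_I, expected.get("BsaI", 0)),
    ):
        got = count_sites(full, enzyme, circular=True)
        if got != want:
            raise FixtureGenerationError(
                f"{name}: {enzyme.name} count {got} != expected {want} "
                "(accidental junction site)"
            )
    return mol


def _build_muav(rng: random.Random, cfg: FixtureConfig, std: MobiusStandard) -> DnaMolecule:
    spec = std.vector_spec("mUAV")
    marker_len = cfg.marker_stub_lengths[spec.dropout_marker]
    sp_l = _clean_random(rng, _SP4)
    sp_r = _clean_random(rng, _SP4)
    marker = _clean_random(rng, marker_len)
    pad1 = _clean_random(rng, 12)
    pad2 = _clean_random(rng, 12)
    bb, bb_feats = _backbone(rng, cfg, spec.resistance, spec.backbone_origin)
    pieces = [
        (_ECORI, "EcoRI", "misc_feature"),
        (pad1, None, None),
        ("GGT", None, None),  # completed to GGTCTC by the incoming CTCT tail
        ("CTCT", "fusion-5", "misc_feature"),
        (sp_l, None, None),
        (_AARI_R, None, None),  # bottom-strand AarI, cutting leftward at CTCT
        (marker, spec.dropout_marker, "marker"),
        (_AARI_F, None, None),  # top-strand AarI, cutting rightward at TGAG
        (sp_r, None, None),
        ("TGAG", "fusion-3", "misc_feature"),
        ("ACC", None, None),  # TGAG + ACC holds the bottom-strand BsaI site
        (pad2, None, None),
        (_PSTI, "PstI", "misc_feature"),
        (bb, None, None),
    ]
    mol = _assemble("mUAV", pieces, {"AarI": 2, "BsaI": 2})
    offset = len(mol.sequence) - len(bb)
    for f in bb_feats:
        mol.features.append(Feature(f.label, f.start + offset, f.end + offset, f.strand, f.kind))
    mol.features.sort(key=lambda f: f.start)
    return mol


def _build_l1(rng: random.Random, cfg: FixtureConfig, std: MobiusStandard, letter: str) -> DnaMolecule:
    spec = std.vector_spec(f"L1-{letter}")
    o5, o3 = spec.outer_overhangs
    inner5, inner3 = spec.inner_overhangs
    marker = _clean_random(rng, cfg.marker_stub_lengths[spec.dropout_marker])
    bb, bb_feats = _backbone(rng, cfg, spec.resistance, spec.backbone_origin)
    pieces = [
        (_ECORI, "EcoRI", "misc_feature"),
        (_clean_random(rng, 12), None, None),
        (_AARI_F, None, None),  # release: exposes the outer 5' overhang
        (_clean_random(rng, _SP4), None, None),
        (o5, "outer-5", "misc_feature"),
        (_clean_random(rng, 8), None, None),
        (inner5, "inner-5", "misc_feature"),
        ("T", None, None),
        (_BSAI_R, None, None),  # acceptance: bottom-strand BsaI in the dropout
        (marker, spec.dropout_marker, "marker"),
        (_BSAI_F, None, None),  # acceptance: top-strand BsaI in the dropout
        ("T", None, None),
        (inner3, "inner-3", "misc_feature"),
        (_clean_random(rng, 10), None, None),
        (o3, "outer-3", "misc_feature"),
        (_clean_random(rng, _SP4), None, None),
        (_AARI_R, None, None),  # release: exposes the outer 3' overhang
        (_clean_random(rng, 12), None, None),
        (_PSTI, "PstI", "misc_feature"),
        (bb, None, None),
    ]
    mol = _assemble(f"L1-{letter}", pieces, {"AarI": 2, "BsaI": 2})
    offset = len(mol.sequence) - len(bb)
    for f in bb_feats:
        mol.features.append(Feature(f.label, f.start + offset, f.end + offset, f.strand, f.kind))
    mol.features.sort(key=lambda f: f.start)
    return mol


def _build_l2(rng: random.Random, cfg: FixtureConfig, std: MobiusStandard, letter: str) -> DnaMolecule:
    spec = std.vector_spec(f"L2-{letter}")
    w5 = spec.outer_overhangs[0]
    inner5, inner3 = spec.inner_overhangs
    marker = _clean_random(rng, cfg.marker_stub_lengths[spec.dropout_marker])
    bb, bb_feats = _backbone(rng, cfg, spec.resistance, spec.backbone_origin)
    pieces = [
        (_ECORI, "EcoRI", "misc_feature"),
        (_clean_random(rng, 12), None, None),
        (_BSAI_F, None, None),  # release: exposes the outer 5' overhang
        ("T", None, None),
        (w5, "outer-5", "misc_feature"),
        (_clean_random(rng, 8), None, None),
        (inner5, "inner-5", "misc_feature"),
        (_clean_random(rng, _SP4), None, None),
        (_AARI_R, None, None),  # acceptance: bottom-strand AarI in the dropout
        (marker, spec.dropout_marker, "marker"),
        (_AARI_F, None, None),  # acceptance: top-strand AarI in the dropout
        (_clean_random(rng, _SP4), None, None),
        (inner3, "inner-3", "misc_feature"),
        (_clean_random(rng, 12), None, None),
        (_PSTI, "PstI", "misc_feature"),
        (bb, None, None),
    ]
    mol = _assemble(f"L2-{letter}", pieces, {"AarI": 2, "BsaI": 1})
    offset = len(mol.sequence) - len(bb)
    for f in bb_feats:
        mol.features.append(Feature(f.label, f.start + offset, f.end + offset, f.strand, f.kind))
    mol.features.sort(key=lambda f: f.start)
    return mol


def _build_auxiliary(rng: random.Random, cfg: FixtureConfig, std: MobiusStandard, name: str) -> DnaMolecule:
    lk = std.linker_spec(name)
    # 50 bp: upstream(4) f1(15) payload(4) T(1) GAGACC(6) f2(16) ACCC(4)
    f1 = _clean_random(rng, 15)
    f2 = _clean_random(rng, 16)
    linker = (
        lk.upstream_overhang
        + f1
        + lk.payload_overhang
        + "T"
        + _BSAI_R
        + f2
        + lk.downstream_overhang
    )
    if len(linker) != lk.length:
        raise FixtureGenerationError(f"linker {name} is {len(linker)} bp, want {lk.length}")
    bb, bb_feats = _backbone(rng, cfg, "kanamycin", "pSB1K3")
    pieces = [
        (_ECORI, "EcoRI", "misc_feature"),
        (_clean_random(rng, 12), None, None),
        (_AARI_F, None, None),
        (_clean_random(rng, _SP4), None, None),
        (linker, lk.name, "linker"),
        (_clean_random(rng, _SP4), None, None),
        (_AARI_R, None, None),
        (_clean_random(rng, 12), None, None),
        (_PSTI, "PstI", "misc_feature"),
        (bb, None, None),
    ]
    mol = _assemble(f"AP-{lk.name}", pieces, {"AarI": 2, "BsaI": 1})
    offset = len(mol.sequence) - len(bb)
    for f in bb_feats:
        mol.features.append(Feature(f.label, f.start + offset, f.end + offset, f.strand, f.kind))
    mol.features.sort(key=lambda f: f.start)
    return mol


def build_toolkit(cfg: FixtureConfig | None = None, standard: MobiusStandard = DEFAULT_STANDARD) -> SyntheticToolkit:
    """Generate the full 16-vector synthetic toolkit for a config.

    Accidental recognition sites formed across junctions trigger a bounded,
    deterministic regeneration with fresh stub draws.
    """
    cfg = cfg or FixtureConfig()
    rng = random.Random(cfg.seed)
    builders = [("mUAV", _build_muav)]
    builders += [(f"L1-{l}", lambda r, c, s, l=l: _build_l1(r, c, s, l)) for l in POSITION_LETTERS]
    builders += [(f"L2-{l}", lambda r, c, s, l=l: _build_l2(r, c, s, l)) for l in POSITION_LETTERS]
    builders += [
        (f"AP-{n}", lambda r, c, s, n=n: _build_auxiliary(r, c, s, n))
        for n in ("4A", "4B", "4G", "4D", "M1", "M2", "M3")
    ]
    vectors: dict[str, DnaMolecule] = {}
    for name, build in builders:
        last_err: Exception | None = None
        for _ in range(cfg.max_retries):
            try:
                vectors[name] = build(rng, cfg, standard)
                break
            except FixtureGenerationError as err:  # perturbed stubs on retry
                last_err = err
        else:
            raise FixtureGenerationError(f"could not generate {name}: {last_err}")
    return SyntheticToolkit(vectors=vectors, standard=standard, config=cfg)


def _random_cds(rng: random.Random, cfg: FixtureConfig) -> str:
    lo, hi = cfg.cargo_length_range
    n_codons = max(4, rng.randint(lo, hi) // 3)
    body = _clean_random(rng, 3 * (n_codons - 2))
    for _ in range(50):
        cand = "ATG" + body + "TAA"
        if all(cand.find(m) == -1 and reverse_complement_seq(cand).find(m) == -1 for m in _FORBIDDEN):
            return cand
        body = _clean_random(rng, 3 * (n_codons - 2))
    raise FixtureGenerationError("could not draw a clean dummy CDS")


def build_dummy_tu_parts(
    cfg: FixtureConfig,
    n: int,
    toolkit: SyntheticToolkit | None = None,
) -> list[TuParts]:
    """n triples of Level 0 plasmids (promoter, CDS, terminator).

    Cargo sequences are rejection-sampled site-free; each CDS carries a
    unique payload feature for order tracking. Parts are onboarded through
    the actual primer-design -> amplification -> mUAV reaction pipeline, so
    every fixture part is a simulated Level 0 product.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    toolkit = toolkit or build_toolkit(cfg)
    muav = toolkit.vector("mUAV")
    rng = random.Random(cfg.seed * 1_000_003 + 17)
    std = toolkit.standard
    out: list[TuParts] = []
    for i in range(1, n + 1):
        plasmids = {}
        for role_name, cargo_fn, feat_kind in (
            ("promoter", lambda: _clean_random(rng, rng.randint(50, 80)), "promoter"),
            ("CDS", lambda: _random_cds(rng, cfg), "payload"),
            ("terminator", lambda: _clean_random(rng, rng.randint(40, 60)), "terminator"),
        ):
            role = std.part_type(role_name)
            label = f"TU{i:02d}" if feat_kind == "payload" else f"{role_name[:4]}-{i:02d}"
            product = None
            for _ in range(10):
                cargo = cargo_fn()
                template = DnaMolecule(
                    f"template-{label}", cargo, "linear",
                    [Feature(label, 0, len(cargo), 1, feat_kind)],
                )
                part = PartDefinition(template, 0, len(cargo), role, name=label)
                try:
                    design = design_primers(part)
                except PrimerDesignError:
                    continue  # tail/cargo junction formed a stray site; redraw
                amplicon = amplify(part, design)
                candidate, diag = simulate_one_pot(ReactionMix(muav, [amplicon], AAR_I))
                if candidate is not None:
                    product = candidate
                    break
            if product is None:
                raise FixtureGenerationError(f"could not onboard dummy part {label}")
            product.molecule.id = f"L0-{label}"
            plasmids[role_name] = product.molecule
        out.append(TuParts(plasmids["promoter"], plasmids["CDS"], plasmids["terminator"]))
    return out


def export_toolkit(toolkit: SyntheticToolkit, directory: str | Path) -> Path:
    """Write one GenBank file per vector plus a manifest YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, mol in toolkit.vectors.items():
        write_genbank([mol], directory / f"{name}.gb")
        if name.startswith("AP-"):
            lk = toolkit.standard.linker_spec(name[3:])
            manifest[name] = {
                "kind": "auxiliary",
                "linker": lk.display_name,
                "overhangs": [lk.upstream_overhang, lk.payload_overhang, lk.downstream_overhang],
                "resistance": "kanamycin",
                "length": len(mol.sequence),
            }
        else:
            spec = toolkit.standard.vector_spec(name)
            manifest[name] = {
                "kind": "acceptor",
                "level": spec.level,
                "marker": spec.dropout_marker,
                "resistance": spec.resistance,
                "inner_overhangs": list(spec.inner_overhangs),
                "outer_overhangs": list(spec.outer_overhangs),
                "length": len(mol.sequence),
            }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return directory
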