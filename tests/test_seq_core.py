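import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobius_assembly.seq_core import (
    AAR_I,
    BSA_I,
    AlphabetError,
    DnaMolecule,
    Feature,
    GeometryError,
    count_sites,
    digest,
    find_sites,
    get_enzyme,
    read_fasta,
    read_genbank,
    reverse_complement,
    reverse_complement_seq,
    write_fasta,
    write_genbank,
)

# ---------------------------------------------------------------------------
# independent oracle: naive per-position scan
# ---------------------------------------------------------------------------


def naive_hits(seq, circular, enzyme):
    """Brute-force recognition scan on the doubled-and-truncated linearization."""
    n = len(seq)
    rc_seq = reverse_complement_seq(seq)
    text = seq + seq[: len(enzyme.recognition) - 1] if circular else seq
    rc_text = rc_seq + rc_seq[: len(enzyme.recognition) - 1] if circular else rc_seq
    plus = [
        i for i in range(n) if text[i : i + len(enzyme.recognition)] == enzyme.recognition
    ]
    # a bottom-strand recognition at rc-coordinate j starts at top coordinate
    # n - j - len(recognition)
    minus = [
        (n - j - len(enzyme.recognition)) % n if circular else n - j - len(enzyme.recognition)
        for j in range(n)
        if rc_text[j : j + len(enzyme.recognition)] == enzyme.recognition
    ]
    return sorted(plus), sorted(m for m in minus if circular or m >= 0)


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestReverseComplement:
    def test_palindrome(self):
        m = DnaMolecule("x", "ACGT")
        assert reverse_complement(m).sequence == "ACGT"

    def test_aari_recognition(self):
        assert reverse_complement_seq("CACCTGC") == "GCAGGTG"

    def test_involution_100_random_200mers(self):
        for seed in range(100):
            rng = random.Random(seed)
            m = DnaMolecule(f"r{seed}", random_seq(rng, 200))
            assert reverse_complement(reverse_complement(m)).sequence == m.sequence

    def test_feature_flip(self):
        m = DnaMolecule("x", "AAAACGTTTT", features=[Feature("f", 2, 5, 1)])
        rc = reverse_complement(m)
        (f,) = rc.features
        assert (f.start, f.end, f.strand) == (5, 8, -1)

    def test_invalid_alphabet(self):
        with pytest.raises(AlphabetError):
            DnaMolecule("x", "ACGN")
        with pytest.raises(AlphabetError):
            reverse_complement_seq("ACGU")


class TestFindSites:
    def test_plus_hit(self):
        m = DnaMolecule("x", "AAACACCTGCAAA")
        hits = find_sites(m, AAR_I)
        assert len(hits) == 1
        h = hits[0]
        assert (h.position, h.strand) == (3, "+")
        assert (h.cut_top, h.cut_bottom) == (3 + 7 + 4, 3 + 7 + 8)

    def test_minus_hit(self):
        m = DnaMolecule("x", "AAAGCAGGTGAAA")
        hits = find_sites(m, AAR_I)
        assert len(hits) == 1
        assert hits[0].strand == "-"

    def test_origin_spanning_site(self):
        # CACCTGC split across the circular origin
        m = DnaMolecule("x", "TGCAAAAAAAAAAAAAAAAACACC", topology="circular")
        assert len(find_sites(m, AAR_I)) == 1
        assert len(find_sites(DnaMolecule("y", m.sequence), AAR_I)) == 0

    @pytest.mark.parametrize("enzyme", [AAR_I, BSA_I])
    def test_brute_force_oracle_500_circular_300mers(self, enzyme):
        for seed in range(500):
            rng = random.Random(seed + 10_000)
            m = DnaMolecule(f"c{seed}", random_seq(rng, 300), topology="circular")
            hits = find_sites(m, enzyme)
            plus, minus = naive_hits(m.sequence, True, enzyme)
            got_plus = sorted(h.position for h in hits if h.strand == "+")
            # a minus SiteHit records the top-strand start of the rc motif
            got_minus = sorted(
                h.position % len(m.sequence) for h in hits if h.strand == "-"
            )
            assert got_plus == plus
            assert got_minus == minus

    def test_strand_symmetry(self):
        for seed in range(50):
            rng = random.Random(seed)
            m = DnaMolecule(f"s{seed}", random_seq(rng, 400))
            a = find_sites(m, BSA_I)
            b = find_sites(reverse_complement(m), BSA_I)
            assert len(a) == len(b)
            assert sorted(h.strand for h in a) == sorted(
                "+" if h.strand == "-" else "-" for h in b
            )


def two_site_circle(cargo, filler):
    seq = "GGTCTC" + "T" + "GGAG" + cargo + "CGCT" + "A" + "GAGACC" + filler
    return DnaMolecule("circle", seq, topology="circular")


class TestDigest:
    def test_cargo_release_overhangs(self):
        # spisPink-style dropout: BsaI exposes GGAG and CGCT
        m = two_site_circle("ATTCCGGAATCC", "TTCTTAAGGCAT")
        frags = digest(m, BSA_I)
        assert len(frags) == 2
        cargo = next(f for f in frags if "ATTCCGGAATCC" in f.core)
        assert (cargo.left_overhang, cargo.right_overhang) == ("GGAG", "CGCT")

    def test_linear_no_sites_blunt(self):
        m = DnaMolecule("x", "AAATTTAAATTT")
        frags = digest(m, BSA_I)
        assert len(frags) == 1
        assert frags[0].is_blunt and not frags[0].uncut

    def test_circular_no_sites_uncut(self):
        m = DnaMolecule("x", "AAATTTAAATTT", topology="circular")
        (frag,) = digest(m, BSA_I)
        assert frag.uncut

    def test_linear_cut_off_end(self):
        with pytest.raises(GeometryError):
            digest(DnaMolecule("x", "AAAGGTCTCT"), BSA_I)

    def test_fragment_counts(self):
        m = two_site_circle("ATTCCGGAATCC", "TTCTTAAGGCAT")
        assert len(digest(m, BSA_I)) == 2
        lin = DnaMolecule("lin", "AAAA" + m.sequence + "AAAA")
        assert len(digest(lin, BSA_I)) == 3

    def test_length_conservation_200_random_circles(self):
        for seed in range(200):
            rng = random.Random(seed + 999)
            m = two_site_circle(random_seq(rng, rng.randint(10, 80)), random_seq(rng, rng.randint(10, 80)))
            frags = digest(m, BSA_I)
            assert sum(len(f.core) - 4 for f in frags) == len(m.sequence)

    def test_rotation_invariance(self):
        m = two_site_circle("ATTCCGGAATCCAT", "TTCTTAAGGCATAA")
        base = sorted(f.core for f in digest(m, BSA_I))
        for offset in (1, 7, 19, len(m.sequence) - 3):
            rot = sorted(f.core for f in digest(m.rotated(offset), BSA_I))
            assert rot == base

    def test_single_cut_circle(self):
        m = DnaMolecule("x", "GGTCTCTAAAATTTTCCCCGGGGAAA", topology="circular")
        (frag,) = digest(m, BSA_I)
        assert len(frag.core) == len(m.sequence) + 4
        assert frag.left_overhang == frag.right_overhang

    def test_carries_sites_recomputed(self):
        m = two_site_circle("ATTCCGGAATCC", "TTCTTAAGGCAT")
        frags = digest(m, BSA_I)
        backbone = next(f for f in frags if "ATTCCGGAATCC" not in f.core)
        assert backbone.carries_sites["BsaI"] == 2  # outward-facing sites retained
        cargo = next(f for f in frags if "ATTCCGGAATCC" in f.core)
        assert cargo.carries_sites["BsaI"] == 0

    def test_sticky_fragment_reverse_complement(self):
        m = two_site_circle("ATTCCGGAATCC", "TTCTTAAGGCAT")
        cargo = next(f for f in digest(m, BSA_I) if "ATTCCGGAATCC" in f.core)
        rc = cargo.reverse_complement()
        assert rc.left_overhang == reverse_complement_seq(cargo.right_overhang)
        assert rc.right_overhang == reverse_complement_seq(cargo.left_overhang)
        assert rc.reverse_complement().core == cargo.core


def _canonical(frag):
    # an uncut circle is the same molecule from any written origin
    if frag.uncut:
        s = frag.core
        return min(s[i:] + s[:i] for i in range(len(s)))
    return frag.core


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=20, max_size=300), st.integers(0, 299))
def test_rotation_invariant_fragments_property(seq, offset):
    m = DnaMolecule("h", seq, topology="circular")
    frags = digest(m, BSA_I)
    rot = digest(m.rotated(offset % len(seq)), BSA_I)
    assert sorted(map(_canonical, frags)) == sorted(map(_canonical, rot))


class TestEnzymes:
    def test_builtins(self):
        assert get_enzyme("AarI").recognition == "CACCTGC"
        assert get_enzyme("AarI").spacer == 4
        assert get_enzyme("BsaI").recognition == "GGTCTC"
        assert get_enzyme("BsaI").spacer == 1
        assert get_enzyme("AarI").overhang_len == get_enzyme("BsaI").overhang_len == 4

    def test_unknown(self):
        with pytest.raises(KeyError):
            get_enzyme("EcoRI")

    def test_count_sites_circular(self):
        assert count_sites("CACCTGCAAA", AAR_I) == 1
        assert count_sites("CTGCAAACAC", AAR_I, circular=True) == 1


class TestIO:
    def test_genbank_round_trip(self, tmp_path):
        m = DnaMolecule(
            "plasmid1",
            "ACGT" * 30,
            topology="circular",
            features=[Feature("marker1", 5, 25, 1, "marker"), Feature("p", 30, 50, -1, "promoter")],
        )
        path = tmp_path / "m.gb"
        write_genbank([m], path)
        (back,) = read_genbank(path)
        assert back.sequence == m.sequence
        assert back.topology == "circular"
        assert [(f.label, f.start, f.end, f.strand, f.kind) for f in back.features] == [
            (f.label, f.start, f.end, f.strand, f.kind) for f in m.features
        ]

    def test_fasta_round_trip_topology(self, tmp_path):
        mols = [
            DnaMolecule("circ1", "ACGTACGTAC", topology="circular"),
            DnaMolecule("lin1", "TTTTAAAACC"),
        ]
        path = tmp_path / "m.fasta"
        write_fasta(mols, path)
        back = read_fasta(path)
        assert [(m.id, m.topology, m.sequence) for m in back] == [
            (m.id, m.topology, m.sequence) for m in mols
        ]
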