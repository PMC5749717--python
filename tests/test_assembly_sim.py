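import pytest

from mobius_assembly.assembly_sim import (
    FailureMode,
    PlanExecutionError,
    ReactionMix,
    ReleaseError,
    cassette_of,
    payload_order,
    simulate_one_pot,
    simulate_plan,
)
from mobius_assembly.fixtures import build_dummy_tu_parts
from mobius_assembly.onboarding import PartDefinition, amplify, design_primers
from mobius_assembly.planner import plan_assembly
from mobius_assembly.seq_core import (
    AAR_I,
    BSA_I,
    DnaMolecule,
    Feature,
    count_sites,
    digest,
)
from mobius_assembly.standard import DEFAULT_STANDARD


def make_amplicon(cargo, role_name="CDS", name="part1"):
    role = DEFAULT_STANDARD.part_type(role_name)
    template = DnaMolecule(
        f"tmpl-{name}", cargo, "linear", [Feature(name, 0, len(cargo), 1, "payload")]
    )
    part = PartDefinition(template, 0, len(cargo), role, name=name)
    return amplify(part, design_primers(part))


CARGO = "ATGGATCCATTTACGAGCGCATCATTTGCCGCAGCAGATATTGACCATTACGCAATGA"


class TestSimulateOnePot:
    def test_muav_reaction_replaces_amilcp(self, toolkit):
        muav = toolkit.vector("mUAV")
        amplicon = make_amplicon(CARGO)
        product, diag = simulate_one_pot(ReactionMix(muav, [amplicon], AAR_I))
        assert diag.failure_mode is FailureMode.NONE
        assert product.valid
        labels = {f.label for f in product.molecule.features}
        assert "part1" in labels and "amilCP" not in labels
        assert count_sites(product.molecule.sequence, AAR_I, circular=True) == 0

    def test_acceptor_alone_no_closed_cycle(self, toolkit):
        product, diag = simulate_one_pot(ReactionMix(toolkit.vector("mUAV"), [], AAR_I))
        assert product is None
        assert diag.failure_mode is FailureMode.NO_CLOSED_CYCLE
        # marker re-ligation was enumerated but rejected: it retains sites
        assert diag.products_found >= 1

    def test_uncut_acceptor(self):
        acceptor = DnaMolecule(
            "no-sites",
            "ACGATCGATTACCAGGATCCATGCATCCTAGGACTATT",
            "circular",
            [Feature("CamR", 2, 30, 1, "resistance")],
        )
        product, diag = simulate_one_pot(ReactionMix(acceptor, [], AAR_I))
        assert product is None
        assert diag.failure_mode is FailureMode.UNCUT_INPUT

    def test_level2_assembly_with_linker(self, toolkit, parts16):
        bsa, aar = BSA_I, AAR_I
        l1_products = []
        for j, letter in enumerate("ABGD", start=1):
            vec = toolkit.vector(f"L1-{letter}")
            product, diag = simulate_one_pot(
                ReactionMix(vec, parts16[j - 1].plasmids(), bsa)
            )
            assert diag.failure_mode is FailureMode.NONE
            l1_products.append(product.molecule)
        mix = ReactionMix(
            toolkit.vector("L2-A"), l1_products + [toolkit.auxiliary("4A")], aar
        )
        product, diag = simulate_one_pot(mix)
        assert diag.failure_mode is FailureMode.NONE
        assert payload_order(product.molecule) == ["TU01", "TU02", "TU03", "TU04"]
        assert "4A" in {f.label for f in product.molecule.features}
        assert count_sites(product.molecule.sequence, aar, circular=True) == 0

    def test_overhang_clash_on_duplicate(self, toolkit, parts16):
        # two different promoters share GGAG/AATG overhangs -> two valid
        # products with duplicated labels in the clean fragment set
        mix = ReactionMix(
            toolkit.vector("L1-A"),
            [parts16[0].promoter, parts16[1].promoter, parts16[0].cds, parts16[0].terminator],
            BSA_I,
        )
        product, diag = simulate_one_pot(mix)
        assert product is None
        assert diag.failure_mode is FailureMode.OVERHANG_CLASH

    def test_linear_acceptor_rejected(self, toolkit):
        lin = DnaMolecule("lin", "ACGTACGT")
        with pytest.raises(ValueError):
            ReactionMix(lin, [], AAR_I)


class TestCassetteOf:
    @pytest.fixture()
    def l0_product(self, toolkit):
        amplicon = make_amplicon(CARGO)
        product, _ = simulate_one_pot(ReactionMix(toolkit.vector("mUAV"), [amplicon], AAR_I))
        return product

    def test_level0_release_overhangs(self, l0_product):
        frag = cassette_of(l0_product, BSA_I)
        role = DEFAULT_STANDARD.part_type("CDS")
        assert (frag.left_overhang, frag.right_overhang) == (
            role.left_overhang,
            role.right_overhang,
        )

    def test_level0_site_bookkeeping(self, l0_product):
        assert count_sites(l0_product.molecule.sequence, BSA_I, circular=True) == 2
        frag = cassette_of(l0_product, BSA_I)
        assert frag.carries_sites["BsaI"] == 0

    def test_level1_release_overhangs(self, toolkit, parts16):
        product, _ = simulate_one_pot(
            ReactionMix(toolkit.vector("L1-A"), parts16[0].plasmids(), BSA_I)
        )
        frag = cassette_of(product, AAR_I)
        assert (frag.left_overhang, frag.right_overhang) == ("GGAG", "CAGA")

    def test_wrong_cut_count(self, l0_product):
        with pytest.raises(ReleaseError):
            cassette_of(l0_product, AAR_I)  # zero AarI sites remain


class TestSimulatePlan:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 7, 8, 12, 16])
    def test_order_preserved(self, toolkit, parts16, n):
        product = simulate_plan(plan_assembly(n), toolkit, parts16[:n])
        assert product.valid
        assert payload_order(product.molecule) == [f"TU{i:02d}" for i in range(1, n + 1)]

    def test_single_tu_degenerate(self, toolkit, parts16):
        plan = plan_assembly(1)
        product = simulate_plan(plan, toolkit, parts16[:1])
        assert plan.final_step.level == 1
        assert payload_order(product.molecule) == ["TU01"]

    def test_plan4_contains_4d_linker(self, toolkit, parts16):
        product = simulate_plan(plan_assembly(4), toolkit, parts16[:4])
        assert "4D" in {f.label for f in product.molecule.features}

    def test_no_residual_reaction_sites(self, toolkit, parts16):
        for n in (1, 4, 7):
            plan = plan_assembly(n)
            product = simulate_plan(plan, toolkit, parts16[:n])
            enzyme = BSA_I if plan.final_step.level == 1 else AAR_I
            assert count_sites(product.molecule.sequence, enzyme, circular=True) == 0

    def test_length_conservation(self, toolkit, parts16):
        # final length from independent digestion arithmetic
        plan = plan_assembly(4)
        step = plan.steps[0]
        l1_products = []
        for j in range(1, 5):
            vec = toolkit.vector(f"L1-{plan.tu_vectors[j]}")
            p, _ = simulate_one_pot(ReactionMix(vec, parts16[j - 1].plasmids(), BSA_I))
            l1_products.append(p.molecule)
        acceptor = toolkit.vector(step.vector)
        backbone = next(
            f for f in digest(acceptor, AAR_I)
            if any(ft.kind == "resistance" for ft in f.features)
        )
        cassettes = [
            next(f for f in digest(m, AAR_I) if not any(ft.kind == "resistance" for ft in f.features))
            for m in l1_products
        ]
        linker = next(
            f for f in digest(toolkit.auxiliary(step.linker), AAR_I)
            if not any(ft.kind == "resistance" for ft in f.features)
        )
        expected = sum(len(f.core) - 4 for f in [backbone] + cassettes + [linker])
        product = simulate_plan(plan, toolkit, parts16[:4])
        assert len(product.molecule.sequence) == expected

    def test_cargo_count_mismatch(self, toolkit, parts16):
        with pytest.raises(ValueError):
            simulate_plan(plan_assembly(4), toolkit, parts16[:3])

    def test_failing_step_identified(self, toolkit, parts16):
        plan = plan_assembly(2)
        broken = type(plan)(
            plan.n_tus,
            [type(plan.steps[0])(**{**plan.steps[0].__dict__, "linker": "4A"})],
            plan.rounds,
            dict(plan.tu_vectors),
        )
        with pytest.raises(PlanExecutionError) as err:
            simulate_plan(broken, toolkit, parts16[:2])
        assert err.value.step_id == "s1"
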