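# mobius-assembly

In silico implementation of the Mobius Assembly Golden Gate standard:
simulation of Type IIS digestion–ligation reactions, hierarchical planning of
multi-transcriptional-unit (TU) builds across the framework's two levels,
onboarding-primer design, and analytic domestication-burden statistics — all
exercised on a deterministic synthetic 16-vector toolkit that reproduces the
standard's site architecture (mUAV; Level 1 and Level 2 Acceptor Vectors A, B,
Γ, Δ; seven Auxiliary Plasmids) without any external sequence downloads.

## Package layout

| module | contents |
| --- | --- |
| `seq_core` | `DnaMolecule`, `TypeIISEnzyme` (built-in AarI `CACCTGC(4/8)` and BsaI `GGTCTC(1/5)`), site finding on both strands of linear/circular molecules, digestion into `StickyFragment`s with top-strand 4-mer overhang tokens, FASTA/GenBank I/O |
| `standard` | the routing standard as data: 9 `VectorSpec` + 7 `LinkerSpec` entries, part-type overhangs, chain validation, YAML export/import of the whole standard |
| `planner` | `capacity` (1, 4, 16, 64, …), `plan_assembly(n)` — greedy left-packed chunking with End-to-End (4A/4B/4Γ/4Δ) and Middle-to-End (M1–M3) linker selection, `extend_plan`, bench-sheet output |
| `assembly_sim` | `simulate_one_pot` — overhang-matching cycle enumeration over both fragment orientations, validity = zero residual reaction-enzyme sites, diagnostics (`no_closed_cycle`, `overhang_clash`, …); `cassette_of`; `simulate_plan` |
| `domestication` | forbidden-site scanning, closed-form burden model (58.3% / 37.5% reductions), synonymous-codon domestication with deterministic tie-breaks |
| `onboarding` | primer tails (clamp + AarI + spacer + CTCT/TGAG fusion + standard overhang + annealing region), in silico PCR, Level 0 part verification |
| `fixtures` | deterministic synthetic toolkit and dummy promoter/CDS/terminator parts, onboarded through the real primer→PCR→mUAV pipeline |
| `cli` | the `mobius` command |

## CLI

```bash
mobius toolkit --seed 1 --out toolkit/      # 16 GenBank vectors + manifest
mobius scan parts.fasta --strict            # TSV site report, exit 1 on hits
mobius domesticate cds.fasta                # synonymous edit proposals
mobius primers cargo.fasta --role promoter  # onboarding primer tails
mobius plan 7 --out plan/                   # YAML plan + bench sheet
mobius simulate --n 16 --seed 1 --out sim/  # end-to-end build on fixtures
mobius burden                               # 58.3 (vs three 6-bp cutters)
mobius burden --reference 6,6               # 37.5
```

## Notes

- Coordinates are 0-based half-open on the top strand; circular arithmetic is
  modulo length. Sticky ends are recorded as the top-strand 4-mer spanning
  the cut, so ends ligate iff their tokens match.
- The simulator is an idealized end-point model: no ligase kinetics, no
  overhang-fidelity scoring, products capped at 12 fragments with one copy
  per physical fragment.
- Fixtures make no claim of sequence identity to any deposited vectors; they
  reproduce the site architecture only (markers and resistances are labelled
  stubs).
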