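# symdock

Sequence-independent rigid-body docking of protein building blocks into
symmetric architectures: cyclic rings, dihedral assemblies, coaxial stacks,
tetrahedral/octahedral/icosahedral cages, and planar lattices. The package
is aimed at protein-design workflows in which validated monomers or cyclic
oligomers are combined into larger self-assembling materials and the
resulting interfaces are handed to downstream sequence design.

## What it does

Given one to three building blocks (PDB files, pre-aligned per the input
conventions) and an architecture keyword such as `C3`, `D4`, `O43`, or
`I532`, symdock searches the symmetry-constrained rigid-body degrees of
freedom for arrangements that form well-packed, clash-free interfaces. Two
ideas make this fast and sequence-free:

* **Residue-pair-transform (RPX) scoring.** The interaction of two residues
  is summarized by the 6D rigid transform between their backbone (N, CA, C)
  frames. Transforms are binned into a six-dimensional body-centered-cubic
  lattice — three translation dimensions, three rotation dimensions over the
  24 cells of a bitruncated 24-cell partition of quaternion space — and
  looked up in a precomputed *hscore* table of per-bin scores. The interface
  score is, by default,

      score = a * RPX + b * ncontact

  with `RPX` the sum of per-pair bin scores, `ncontact` the number of CA–CA
  pairs within 8 A, and a = 1, b = 0.001. Variants (`mean`, `median`, `exp`,
  `lin`) and an interface-size-targeting function (`sasa_priority`, a
  log-normal contact-count prior whose mode sits at the target buried area)
  are selectable with `--function`.

* **Hierarchical beam search.** An enumerative 6D search is hopeless — a
  typical 10,000,000-sample top level refined 16-fold per dimension is
  10,000,000 x 16^6 = 167 trillion configurations. Instead the search
  evaluates the whole space at coarse resolution (10 A / 30 deg), keeps the
  `--beam_size` best non-clashing configurations (default 100,000), subdivides
  each kept cell in half per dimension, and repeats to the finest level.
  Multi-resolution hscore tables store upper bounds at coarse levels, and
  clash/contact tolerances are loosened with the cell size, so regions are
  only discarded when no refinement of them can win.

Results are ranked, de-duplicated by an unaligned-RMSD redundancy filter,
optionally filtered (interface secondary-structure count, estimated buried
area, YAML-configurable), and written both as transform archives
(`.txz`/`.pickle`) and as symmetric-assembly PDB models.

Real motif tables distilled from the PDB are not bundled; the
`symdock.fixtures` module generates synthetic tables with the same schema
(anchored on ideal helix-pair packing) so the whole pipeline runs
self-contained, and `--hscore_files` accepts any table in the documented
format.

## Worked example

Dock a generated C4 ring and C3 ring into a two-component octahedral cage:

    symdock fixtures generate --seed 7 --outdir fx
    symdock --inputs1 fx/c4_asu.pdb --inputs2 fx/c3_asu.pdb \
            --architecture O43 --hscore_files fx/hscore_synth.txz \
            --cart_bounds 10 50 --n_levels 3 --beam_size 200 \
            --dump_pdbs --nout_top 2 --output_prefix o43

This prints the top-ranked docks:

    model 0: score 74.388 ncontact 1622 rpx 72.766
    model 1: score 71.223 ncontact 1210 rpx 70.013

Each line is one ranked configuration: `score` is the stnd score
a·RPX + b·ncontact, `rpx` the summed pair-motif score over every interface
of the assembly, and `ncontact` the number of contacting residue pairs
(summed over all symmetry-related interfaces). `o43_000.pdb`
contains the full 48-chain octahedral assembly (24 frames x 2 components);
`o43_result.txz` stores the transforms and metrics for every ranked dock
and reloads with `symdock.results.load_result`.

For library use, the same pipeline is four calls:

```python
from symdock import arch, fixtures, rpxscore, search, results

spec = arch.parse_architecture("D3")
trimer = fixtures.make_toy_oligomer(fixtures.make_ideal_helix(12), 3, 10.0)
table = fixtures.make_synthetic_hscore(fixtures.FixtureSpec(seed=0))
cfg = search.SearchConfig(n_levels=3, cart_bounds=(5, 25), beam_size=500)
sampler, layout = search.make_sampler(spec, cfg, [trimer])
stages = search.hier_search([trimer], spec, sampler, table,
                            rpxscore.ScoreParams(), cfg, layout)
res = results.result_from_search([trimer], spec, sampler, layout,
                                 stages[-1], cfg, rpxscore.ScoreParams())
```

## Input conventions

Monomers (ASYM, cyclic docking) should be centered at the origin
(`--recenter_input` does this). Oligomeric inputs for dihedral, stacking,
polyhedral, and wallpaper docking must contain only the asymmetric unit,
pre-aligned with the internal cyclic axis on z and the oligomer center of
mass at the origin. Multi-chain inputs concatenate into one chain with
recorded breaks; residues renumber from 1.

## Documentation

`docs/methods.md` describes the scoring model, the sampling hierarchy and
its admissibility margins, the filters, the synthetic-data generators and
what passing tests on them do and do not demonstrate, and the package's
numerical conventions and limitations.
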