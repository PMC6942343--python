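# traction

Non-parametric gene tree correction against a binary reference species tree.

Given an estimated gene tree `t` (possibly multifurcating after collapsing
low-support branches, possibly missing taxa) and a binary, singly-labeled
reference tree `T` whose leaf set contains the gene tree's taxa, the
corrected tree `T'` is binary on the full reference leaf set, restricted to
the gene taxa it refines `t`, and the Robinson–Foulds (RF) distance
`RF(T', T)` is provably minimal subject to those constraints. The pipeline
has two stages:

1. **Refinement** — insert every split of `T` (restricted to the shared
   taxa) that is compatible with `t`; this maximal compatible refinement is
   unique. Remaining polytomies are resolved first with previously collapsed
   edges of the uncollapsed input (when available), then by seeded random
   resolution. Any such resolution is co-optimal.
2. **Completion** — cut `T` along its backbone (edges on paths between
   shared taxa) and graft each hanging "superleaf" of missing taxa into the
   refined tree at an RF-minimizing position. The minimum achievable
   distance, `RF(T|_R, t) + 2m` with `m` the number of superleaves attached
   at splits absent from the gene tree, is asserted as a runtime optimality
   certificate on every call.

A multi-labeled (MUL) variant refines a gene family tree with repeated
species labels against the reference extended to matching copy counts, via
a consistent relabeling into indexed copies. Evaluation metrics (RF,
normalized RF, matching distance, quartet distance) and a seeded synthetic
instance generator are included.

## Layout

| module | contents |
| --- | --- |
| `traction.tree_core` | unrooted tree model, newick I/O, bipartition algebra, RF |
| `traction.rf_otr` | optimal refinement step |
| `traction.rf_otc` | backbone/superleaf analysis and certified completion |
| `traction.pipeline` | end-to-end correction + `traction` CLI |
| `traction.multree` | MUL-tree extension/differentiation/refinement |
| `traction.metrics` | matching and quartet distances, combined comparison |
| `traction.fixtures` | seeded synthetic instances (NNI/SPR perturbation, oracle supports, duplication scenarios) |

## CLI

```sh
# correct a gene tree: collapse support < 75, refine, complete
traction correct -g gene.nwk -s species.nwk -o corrected.nwk \
    --collapse 75 --seed 1 --report report.txt

# multi-labeled gene family tree
traction mt-correct -g family.nwk -s species.nwk -o corrected.nwk --seed 1

# distances between two trees (key=value lines)
traction compare --t1 a.nwk --t2 b.nwk

# write a synthetic instance
traction simulate --n 20 --error-nni 3 --prune 0.05 --seed 1 --outdir sim/
```

Trees are newick; branch support is read from numeric internal-node labels
(bootstrap dialect) and collapse uses a strict `<` comparison. Output
newick is deterministic (children ordered by smallest descendant label).

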