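"""End-to-end gene tree correction (collapse -> refine -> complete) and CLI.

The corrected tree T' is binary on the reference leaf set, restricted to the
gene taxa it refines the (collapsed) gene tree, and RF(T', reference) is the
minimum over all such refinements-and-completions.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import click

from . import fixtures, metrics, multree, rf_otc, rf_otr
from .tree_core import (
    LeafSetMismatchError,
    TreeError,
    UnrootedTree,
    collapse_low_support,
    parse_newick,
    rf_distance,
    restrict,
    write_newick,
)

__all__ = ["TractionConfig", "CorrectionReport", "traction", "correct",
           "run_cli", "main", "cli"]


@dataclass(frozen=True)
class TractionConfig:
    """Knobs for one correction run.

    ``collapse_threshold=None`` means the gene tree is used as-is (assumed
    pre-collapsed); the seed fully determines the output for fixed inputs.
    """

    collapse_threshold: Optional[float] = None
    seed: int = 0
    use_original_edges: bool = True
    mode: str = "single"  # "single" | "mul"


@dataclass(frozen=True)
class CorrectionReport:
    corrected: UnrootedTree
    rf_before: Optional[int]
    rf_after: int
    m: int
    lower_bound: int

    def report(self) -> str:
        lines = []
        if self.rf_before is not None:
            lines.append(f"rf_before={self.rf_before}")
        lines += [f"rf_after={self.rf_after}", f"m={self.m}",
                  f"lower_bound={self.lower_bound}"]
        return "\n".join(lines) + "\n"


def _validate(gene: UnrootedTree, species: UnrootedTree) -> None:
    if species.is_mul:
        raise TreeError("species tree must be singly-labeled")
    if not species.is_binary:
        raise TreeError("species tree must be binary")
    missing = gene.leaf_set - species.leaf_set
    if missing:
        raise LeafSetMismatchError(
            f"gene tree taxa absent from species tree: {sorted(missing)}")


def correct(gene: UnrootedTree, species: UnrootedTree,
            config: Optional[TractionConfig] = None) -> CorrectionReport:
    """Full correction with bookkeeping for the CLI report."""
    config = config or TractionConfig()
    if config.mode == "mul":
        res = multree.traction_mt_result(gene, species, seed=config.seed)
        pair = res.differentiated
        rf_before = rf_distance(pair.first, pair.second) \
            if pair.first.leaf_set == pair.second.leaf_set else None
        rf_after = rf_distance(res.refinement.t_star, pair.second)
        return CorrectionReport(corrected=res.output, rf_before=rf_before,
                                rf_after=rf_after, m=0, lower_bound=rf_after)
    if gene.is_mul:
        raise TreeError("gene tree is multi-labeled; use MUL mode")
    _validate(gene, species)
    original = None
    t = gene
    if config.collapse_threshold is not None:
        t = collapse_low_support(gene, config.collapse_threshold)
        if config.use_original_edges:
            original = gene
    R = t.leaf_set
    ref_r = species if R == species.leaf_set else restrict(species, R)
    rf_before = rf_distance(t, ref_r) if len(R) >= 4 else 0
    refined = rf_otr.refine(t, species, original=original, seed=config.seed)
    if R == species.leaf_set:
        out = refined.t_star
        rf_after = rf_distance(out, species)
        return CorrectionReport(corrected=out, rf_before=rf_before,
                                rf_after=rf_after, m=0, lower_bound=rf_after)
    comp = rf_otc.octal_complete(refined.t_star, species)
    return CorrectionReport(corrected=comp.completed, rf_before=rf_before,
                            rf_after=comp.achieved_rf, m=comp.m,
                            lower_bound=comp.lower_bound)


def traction(gene: UnrootedTree, species: UnrootedTree,
             config: Optional[TractionConfig] = None) -> UnrootedTree:
    """The corrected tree only; see :func:`correct` for the full report."""
    return correct(gene, species, config).corrected


# ----------------------------------------------------------------- CLI


def _read_tree(path: str, *, mul: bool = False) -> UnrootedTree:
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise TreeError(f"cannot read {path}: {exc}") from exc
    return parse_newick(text, mul=mul)


def _write_text(path: Optional[str], text: str) -> None:
    if path:
        Path(path).write_text(text)


@click.group()
def cli() -> None:
    """Gene tree correction against a binary reference species tree."""


@cli.command("correct")
@click.option("-g", "--gene-tree", "gene_path", required=True,
              type=click.Path(), help="Estimated gene tree (newick).")
@click.option("-s", "--species-tree", "species_path", required=True,
              type=click.Path(), help="Binary reference species tree (newick).")
@click.option("-o", "--output", "out_path", required=True, type=click.Path())
@click.option("--collapse", "threshold", type=float, default=None,
              help="Collapse internal edges with support strictly below this.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--no-original-edges", is_flag=True, default=False,
              help="Do not restore collapsed edges of the input gene tree.")
@click.option("--report", "report_path", type=click.Path(), default=None)
def cmd_correct(gene_path, species_path, out_path, threshold, seed,
                no_original_edges, report_path):
    """Refine and complete a singly-labeled gene tree."""
    gene = _read_tree(gene_path)
    species = _read_tree(species_path)
    cfg = TractionConfig(collapse_threshold=threshold, seed=seed,
                         use_original_edges=not no_original_edges)
    rep = correct(gene, species, cfg)
    Path(out_path).write_text(write_newick(rep.corrected) + "\n")
    _write_text(report_path, rep.report())


@cli.command("mt-correct")
@click.option("-g", "--gene-tree", "gene_path", required=True, type=click.Path())
@click.option("-s", "--species-tree", "species_path", required=True,
              type=click.Path())
@click.option("-o", "--output", "out_path", required=True, type=click.Path())
@click.option("--collapse", "threshold", type=float, default=None)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--indexed-output", "indexed_path", type=click.Path(),
              default=None, help="Also write the differentiated intermediate.")
def cmd_mt_correct(gene_path, species_path, out_path, threshold, seed,
                   indexed_path):
    """Refine a multi-labeled gene tree (repeated leaf labels allowed)."""
    gene = _read_tree(gene_path, mul=True)
    species = _read_tree(species_path)
    if threshold is not None:
        gene = collapse_low_support(gene, threshold)
    res = multree.traction_mt_result(gene, species, seed=seed)
    Path(out_path).write_text(write_newick(res.output) + "\n")
    _write_text(indexed_path,
                write_newick(res.refinement.t_star) + "\n")


@cli.command("compare")
@click.option("--t1", "path1", required=True, type=click.Path())
@click.option("--t2", "path2", required=True, type=click.Path())
@click.option("--metrics", "which", default="rf,matching,quartet",
              show_default=True)
@click.option("-o", "--output", "out_path", type=click.Path(), default=None)
def cmd_compare(path1, path2, which, out_path):
    """Distances between two newick trees, as key=value lines."""
    t1 = _read_tree(path1)
    t2 = _read_tree(path2)
    wanted = {w.strip() for w in which.split(",") if w.strip()}
    cmpres = metrics.compare(t1, t2)
    lines = [f"n={cmpres.n}"]
    if "rf" in wanted:
        lines.append(f"rf={cmpres.rf}")
        if cmpres.normalized_rf is not None:
            lines.append(f"normalized_rf={cmpres.normalized_rf:.6g}")
    if "matching" in wanted and cmpres.matching is not None:
        lines.append(f"matching={cmpres.matching}")
    if "quartet" in wanted and cmpres.quartet is not None:
        lines.append(f"quartet={cmpres.quartet}")
    text = "\n".join(lines) + "\n"
    if out_path:
        Path(out_path).write_text(text)
    else:
        click.echo(text, nl=False)


@cli.command("simulate")
@click.option("--n", type=int, default=20, show_default=True)
@click.option("--nni", type=int, default=0, show_default=True)
@click.option("--spr", type=int, default=0, show_default=True)
@click.option("--error-nni", type=int, default=0, show_default=True)
@click.option("--flip-prob", type=float, default=0.0, show_default=True)
@click.option("--prune", type=float, default=0.0, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--outdir", required=True, type=click.Path())
def cmd_simulate(n, nni, spr, error_nni, flip_prob, prune, seed, outdir):
    """Write a seeded synthetic correction instance to a directory."""
    inst = fixtures.make_instance(n=n, nni_moves=nni, spr_moves=spr,
                                  error_nni=error_nni, flip_prob=flip_prob,
                                  prune_fraction=prune, seed=seed)
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    (d / "species.nwk").write_text(write_newick(inst.species_tree) + "\n")
    (d / "true_gene.nwk").write_text(write_newick(inst.true_gene_tree) + "\n")
    (d / "est_gene.nwk").write_text(
        write_newick(inst.estimated_gene_tree) + "\n")
    manifest = "".join(f"{k}={v}\n" for k, v in sorted(
        inst.provenance.items()))
    (d / "manifest.txt").write_text(manifest)


def run_cli(argv=None) -> int:
    """Entry point returning an exit status instead of raising SystemExit."""
    try:
        cli.main(args=argv, prog_name="traction", standalone_mode=False)
    except click.ClickException as exc:
        exc.show(file=sys.stderr)
        return exc.exit_code or 1
    except click.exceptions.Abort:
        return 1
    except TreeError as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 2
    return 0


def main() -> None:  # console-script hook
    sys.exit(run_cli())
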