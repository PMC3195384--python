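"""End-to-end per-panel analysis: selection report, polymorphism table, tree.

The three report builders mirror the standard deliverables of an MHC exon-2
diversity study:

* a selection report with, for each panel and each stratum (PBR, non-PBR,
  All): the number of codons N, the mean pairwise K2P nucleotide divergence
  d, NG86 dN and dS with codon-bootstrap standard errors, the dN/dS ratio and
  the one-tailed P of the Z-test of positive selection;
* a polymorphism table with one row per codon position (PBR rows
  asterisk-prefixed), one column per panel, and a bottom row of panel sizes;
* a pooled Neighbor-Joining tree on Poisson-corrected amino-acid distances
  after complete deletion, with bootstrap supports, written as newick.

Rendering follows the field's table conventions: 3-decimal distances with the
SE in parentheses, 2-decimal ratios, 3-decimal P truncated to .000 / 1.000.
All outputs are byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_evolution as ce
from . import polymorphism as poly
from .errors import DrbSelectError
from .partition import CodonPartition, bundled_partition, load_partition, split_codons
from .phylo import bootstrap_supports, complete_deletion, write_newick
from .seq_io import AlleleSet, dedupe_identical, read_aligned_fasta, translate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one analysis run over one or more allele panels."""

    panels: list[tuple[str, str | Path]]
    mask: str | Path = "brown1993-22"
    replicates: int = 1000
    seed: int = 0
    output_dir: str | Path = "."
    precision: int = 3

    def __post_init__(self) -> None:
        if not self.panels:
            raise DrbSelectError("at least one panel is required")
        if self.replicates < 1:
            raise DrbSelectError("replicates must be >= 1")


def resolve_mask(mask: str | Path, total_codons: int = 78) -> CodonPartition:
    """A bundled mask name or a mask-file path."""
    if isinstance(mask, str) and not Path(mask).exists():
        return bundled_partition(mask, total_codons=total_codons)
    return load_partition(mask)


def load_panels(config: RunConfig) -> list[AlleleSet]:
    out = []
    for label, path in config.panels:
        alleles = dedupe_identical(read_aligned_fasta(path, label=label))
        out.append(alleles)
    return out


def _sub_seed(seed: int, panel_i: int, stratum_i: int, stat_i: int) -> int:
    # stable per-(panel, stratum, statistic) stream; keeps values < 2^31
    return (seed * 1_000_003 + panel_i * 9176 + stratum_i * 131 + stat_i) % (2**31)


def _fmt_est(est: ce.SubstitutionEstimate, precision: int) -> str:
    return f"{est.estimate:.{precision}f}({est.std_error:.{precision}f})"


def format_p(p: float) -> str:
    """Render a one-tailed P the way selection tables print it: 3 decimals,
    leading-dot style, truncated to '.000' below and '1.000' above."""
    if p >= 0.9995:
        return "1.000"
    text = f"{p:.3f}"
    return text[1:] if text.startswith("0.") else text


def analyze_stratum(
    alleles: AlleleSet, replicates: int, seed_triplet: tuple[int, int, int]
) -> dict:
    """All Table-style statistics for one sub-alignment."""
    dk2p = ce.bootstrap_se(alleles, "d_k2p", replicates, seed_triplet[0])
    dn = ce.bootstrap_se(alleles, "dN", replicates, seed_triplet[1])
    ds = ce.bootstrap_se(alleles, "dS", replicates, seed_triplet[2])
    test = ce.z_test_selection(dn, ds)
    return {"d": dk2p, "dn": dn, "ds": ds, "test": test}


def run_selection_report(config: RunConfig) -> pd.DataFrame:
    """Build the per-panel, per-stratum selection report and write
    ``selection_report.tsv`` under the output directory."""
    rows = []
    for panel_i, alleles in enumerate(load_panels(config)):
        try:
            partition = resolve_mask(config.mask, total_codons=alleles.length // 3)
            pbr, non = split_codons(alleles, partition)
            strata = [
                ("PBR", pbr, partition.n_pbr),
                ("Non-PBR", non, partition.n_non_pbr),
                ("All", alleles, partition.total_codons),
            ]
            for stratum_i, (name, sub, n_codons) in enumerate(strata):
                seeds = tuple(
                    _sub_seed(config.seed, panel_i, stratum_i, k) for k in range(3)
                )
                res = analyze_stratum(sub, config.replicates, seeds)
                test = res["test"]
                rows.append(
                    {
                        "Alleles": alleles.label,
                        "No_alleles": alleles.n,
                        "Positions": name,
                        "N": n_codons,
                        "d_K2p": _fmt_est(res["d"], config.precision),
                        "dN_SE": _fmt_est(res["dn"], config.precision),
                        "dS_SE": _fmt_est(res["ds"], config.precision),
                        "dN_dS": "undef" if test.ratio is None else f"{test.ratio:.2f}",
                        "P": format_p(test.p_value),
                    }
                )
        except DrbSelectError as exc:
            logger.error("panel %s failed: %s", alleles.label, exc)
            continue
    report = pd.DataFrame(rows)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "selection_report.tsv", sep="\t", index=False)
    return report


def run_polymorphism_report(config: RunConfig) -> pd.DataFrame:
    """Build the per-codon amino-acid repertoire table (one column per panel,
    asterisked PBR rows, bottom row of panel sizes) and write
    ``polymorphism_table.tsv``."""
    panels = load_panels(config)
    columns: dict[str, list[str]] = {}
    position_labels: list[str] | None = None
    for alleles in panels:
        partition = resolve_mask(config.mask, total_codons=alleles.length // 3)
        table = poly.residue_table(translate(alleles), partition)
        labels = [
            ("*" if flag else "") + str(pos)
            for pos, flag in zip(table.positions, table.is_pbr)
        ]
        if position_labels is None or len(labels) > len(position_labels):
            position_labels = labels
        columns[alleles.label] = table.rendered() + [f"n = {table.n_sequences}"]
    assert position_labels is not None
    index = position_labels + ["n"]
    n_rows = len(index)
    data = {
        label: cells[:-1] + [""] * (n_rows - len(cells)) + [cells[-1]]
        for label, cells in columns.items()
    }
    report = pd.DataFrame(data, index=index)
    report.index.name = "Codon_position"
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "polymorphism_table.tsv", sep="\t")
    return report


def run_tree(config: RunConfig) -> dict:
    """Pooled NJ tree with bootstrap supports; writes ``tree.nwk`` and a
    summary TSV.  Returns the summary dict (total branch length, retained
    columns, leaf count, newick path)."""
    panels = load_panels(config)
    ids: list[str] = []
    seqs: list[str] = []
    for alleles in panels:
        prefix = f"{alleles.label}_" if len(panels) > 1 else ""
        for rid, seq in alleles:
            ids.append(prefix + rid)
            seqs.append(seq)
    pooled = dedupe_identical(AlleleSet(label="pooled", ids=ids, sequences=seqs))
    if pooled.n < 3:
        raise DrbSelectError("need >= 3 distinct pooled sequences for a tree")
    residues = translate(pooled)
    filtered, kept = complete_deletion(residues)
    tree = bootstrap_supports(
        list(pooled.ids), filtered, replicates=config.replicates, seed=config.seed
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    newick_path = out / "tree.nwk"
    write_newick(tree, newick_path)
    summary = {
        "n_leaves": pooled.n,
        "retained_columns": len(kept),
        "total_branch_length": tree.total_length,
        "newick": str(newick_path),
    }
    with open(out / "tree_summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in summary.items():
            value = f"{v:.8f}" if isinstance(v, float) else v
            fh.write(f"{k}\t{value}\n")
    return summary


def run_all(config: RunConfig) -> dict:
    """Selection report + polymorphism table + tree in one pass."""
    return {
        "selection": run_selection_report(config),
        "polymorphism": run_polymorphism_report(config),
        "tree": run_tree(config),
    }
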