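#!/usr/bin/env python
"""Codon-partitioned selection analysis of the exon2 panel.

For each stratum (PBR, non-PBR, All) computes the mean pairwise K2P
nucleotide divergence, NG86 dN and dS with 1000-replicate codon-bootstrap
standard errors, the dN/dS ratio, and the one-tailed P of the Z-test of
positive selection.  Writes results/selection_report.tsv.

Expected signature: PBR dN/dS well above 1 with small P; non-PBR dN/dS
below 1 (the simulation's ω contrast recovered by the estimators).
"""

from pathlib import Path

from drbselect.pipeline import RunConfig, run_selection_report

ROOT = Path(__file__).resolve().parent.parent
PANEL = ROOT / "results" / "panels" / "exon2.fasta"


def main() -> None:
    if not PANEL.exists():
        raise SystemExit("run analysis/01_simulate_panels.py first")
    config = RunConfig(
        panels=[("exon2", str(PANEL))],
        mask="brown1993-22",
        replicates=1000,
        seed=20110127,
        output_dir=ROOT / "results",
    )
    report = run_selection_report(config)
    print(report.to_string(index=False))
    ratios = dict(zip(report["Positions"], report["dN_dS"]))
    print(
        f"\nPBR dN/dS = {ratios['PBR']} vs non-PBR {ratios['Non-PBR']}: "
        "elevated nonsynonymous substitution is confined to the "
        "peptide-binding codons, the positive-selection signature."
    )


if __name__ == "__main__":
    main()
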