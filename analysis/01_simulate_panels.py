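#!/usr/bin/env python
"""Write the study panels used by the downstream analysis scripts.

Produces, under results/panels/: the hand-checkable `tiny` panel (4 alleles x
6 codons), and the `exon2` panel — 22 simulated DRB exon-2-style
alleles x 78 codons evolved with diversifying selection (ω = 3) confined to
the 22 peptide-binding codons and weak purifying selection (ω = 0.5)
elsewhere.
"""

from pathlib import Path

from drbselect.synthetic_data import make_fixture_panel, write_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "panels"


def main() -> None:
    for preset in ("tiny", "exon2"):
        fasta, mask, manifest = write_fixture(preset, OUT)
        alleles, partition = make_fixture_panel(preset)
        print(
            f"{preset}: {alleles.n} alleles x {alleles.length // 3} codons "
            f"({partition.n_pbr} PBR) -> {fasta.name}, {mask.name}, {manifest.name}"
        )
    print(f"panels written under {OUT}")


if __name__ == "__main__":
    main()
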