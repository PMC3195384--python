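"""Simulation of allele families under PBR-restricted diversifying selection.

Alleles evolve independently from a common stop-free ancestral coding
sequence (a star phylogeny — the simplest genealogy that induces the
pairwise-distance structure the estimators consume).  Substitutions are
proposed uniformly over single-base changes and accepted with relative
probability 1 if synonymous and ω(stratum of the codon) if nonsynonymous;
proposals creating stop codons are always rejected.  ω > 1 at PBR codons with
ω ≤ 1 elsewhere emulates the balancing-selection signature of MHC exon-2
panels: elevated nonsynonymous divergence confined to peptide-contact sites.

``branch_length`` is the expected number of accepted substitutions per codon
on each ancestor-to-allele branch, so the expected pairwise divergence is
about 2·branch_length substitutions per codon.

The bundled presets match the scale of a typical single-species exon-2 panel:
22 alleles x 78 codons with a 22-codon PBR mask, branch length 0.2
substitutions/codon (pairwise nucleotide divergence of roughly 0.1/site, the
order observed in such panels).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codon_evolution import BASES, GENETIC_CODE
from .errors import DrbSelectError
from .partition import CodonPartition, bundled_partition, save_partition
from .seq_io import AlleleSet, write_aligned_fasta

_SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one star-phylogeny allele-family simulation."""

    n_alleles: int
    partition: CodonPartition
    omega_pbr: float
    omega_nonpbr: float
    branch_length: float
    seed: int
    n_codons: int = 78
    ancestral: str | None = None
    label: str = "simulated"

    def __post_init__(self) -> None:
        if self.n_alleles < 2:
            raise DrbSelectError("n_alleles must be >= 2")
        if self.omega_pbr <= 0 or self.omega_nonpbr <= 0:
            raise DrbSelectError("omega values must be positive")
        if self.branch_length < 0:
            raise DrbSelectError("branch_length must be >= 0")
        if self.partition.total_codons != self.n_codons:
            raise DrbSelectError(
                f"partition covers {self.partition.total_codons} codons, "
                f"config says {self.n_codons}"
            )
        if self.ancestral is not None:
            if len(self.ancestral) != 3 * self.n_codons:
                raise DrbSelectError("ancestral length != 3 x n_codons")
            for k in range(self.n_codons):
                if GENETIC_CODE.get(self.ancestral[3 * k : 3 * k + 3]) in ("*", None):
                    raise DrbSelectError("ancestral contains a stop/invalid codon")


def _random_ancestor(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))


def _evolve_branch(
    ancestor: list[str],
    omega: np.ndarray,
    n_substitutions: int,
    rng: np.random.Generator,
) -> list[str]:
    """Apply ``n_substitutions`` accepted substitutions to a codon list."""
    seq = list(ancestor)
    n_codons = len(seq)
    omega_max = max(1.0, float(omega.max()))
    accepted = 0
    while accepted < n_substitutions:
        k = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        codon = seq[k]
        new_base = BASES[int(rng.integers(4))]
        if new_base == codon[pos]:
            continue
        mutant = codon[:pos] + new_base + codon[pos + 1 :]
        if GENETIC_CODE[mutant] == "*":
            continue
        if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
            accept_p = 1.0 / omega_max
        else:
            accept_p = omega[k] / omega_max
        if rng.random() < accept_p:
            seq[k] = mutant
            accepted += 1
    return seq


def simulate_alleles(config: SimulationConfig) -> AlleleSet:
    """Simulate an allele panel under the star-phylogeny ω model.

    Deterministic for a fixed config (single seed; per-allele substitution
    counts are Poisson with mean branch_length·n_codons).
    """
    rng = np.random.default_rng(config.seed)
    if config.ancestral is not None:
        ancestor = [
            config.ancestral[3 * k : 3 * k + 3] for k in range(config.n_codons)
        ]
    else:
        anc = _random_ancestor(config.n_codons, rng)
        ancestor = [anc[3 * k : 3 * k + 3] for k in range(config.n_codons)]
    # per-codon omega vector (partition positions -> 0-based codon index)
    omega = np.full(config.n_codons, config.omega_nonpbr)
    for pos in config.partition.pbr_indices:
        omega[pos - config.partition.first_position] = config.omega_pbr

    ids, seqs = [], []
    for i in range(config.n_alleles):
        k = int(rng.poisson(config.branch_length * config.n_codons))
        allele = _evolve_branch(ancestor, omega, k, rng)
        ids.append(f"allele{i + 1:03d}")
        seqs.append("".join(allele))
    return AlleleSet(label=config.label, ids=ids, sequences=seqs)


# ---------------------------------------------------------------------------
# packaged fixture panels
# ---------------------------------------------------------------------------

#: Hand-checkable 4-allele x 6-codon panel.  Differences from sequence tiny1:
#: tiny2 TTT->TTC (synonymous), tiny3 TTT->TTA (Phe->Leu, nonsynonymous),
#: tiny4 AAA->AGA (Lys->Arg, nonsynonymous).
_TINY_SEQUENCES = {
    "tiny1": "TTTATGGCTAAACCCGGG",
    "tiny2": "TTCATGGCTAAACCCGGG",
    "tiny3": "TTAATGGCTAAACCCGGG",
    "tiny4": "TTTATGGCTAGACCCGGG",
}
_TINY_PARTITION = CodonPartition(total_codons=6, pbr_indices=(1, 4), name="tiny")


def make_fixture_panel(preset: str) -> tuple[AlleleSet, CodonPartition]:
    """Return a reproducible packaged fixture panel and its PBR mask.

    ``tiny``
        4 alleles x 6 codons with hand-classified differences (above).
    ``exon2``
        22 simulated alleles x 78 codons, 22-codon PBR mask, ω_pbr = 3,
        ω_nonpbr = 0.5, branch length 0.2 substitutions/codon, fixed seed.
    """
    if preset == "tiny":
        alleles = AlleleSet(
            label="tiny",
            ids=list(_TINY_SEQUENCES),
            sequences=list(_TINY_SEQUENCES.values()),
        )
        return alleles, _TINY_PARTITION
    if preset == "exon2":
        partition = bundled_partition("brown1993-22")
        config = SimulationConfig(
            n_alleles=22,
            partition=partition,
            omega_pbr=3.0,
            omega_nonpbr=0.5,
            branch_length=0.2,
            seed=20110127,
            label="exon2",
        )
        return simulate_alleles(config), partition
    raise DrbSelectError(f"unknown preset {preset!r}")


def write_fixture(
    preset: str, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write a fixture panel as FASTA + mask file + manifest TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alleles, partition = make_fixture_panel(preset)
    fasta = out_dir / f"{preset}.fasta"
    mask = out_dir / f"{preset}.mask"
    manifest = out_dir / f"{preset}.manifest.tsv"
    write_aligned_fasta(alleles, fasta)
    save_partition(partition, mask)
    with open(manifest, "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"preset\t{preset}\n")
        fh.write(f"n_alleles\t{alleles.n}\n")
        fh.write(f"n_codons\t{alleles.length // 3}\n")
        fh.write(f"pbr_codons\t{partition.n_pbr}\n")
    return fasta, mask, manifest
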