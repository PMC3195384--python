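"""Per-site variability accounting for allele panels.

Counts variable nucleotide/amino-acid sites, stratifies variability by the
PBR mask, tabulates the amino-acid repertoire observed at every codon
position, and summarises pairwise percent identity.  A column is *variable*
iff at least two distinct non-missing symbols occur in it; missing symbols
(gap, N at the nucleotide level; X at the amino-acid level) never create
variability and are excluded from residue sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoDataError
from .partition import CodonPartition
from .seq_io import AlleleSet

_MISSING_NT = {"-", "N"}
_MISSING_AA = {"-", "X"}


@dataclass(frozen=True)
class PolymorphismTable:
    """Per-codon-position amino-acid repertoires for one panel."""

    positions: tuple[int, ...]
    residue_sets: tuple[tuple[str, ...], ...]
    is_pbr: tuple[bool, ...]
    n_sequences: int

    def rendered(self) -> list[str]:
        """Alphabetical one-string-per-position rendering (e.g. 'FLY')."""
        return ["".join(rs) for rs in self.residue_sets]


@dataclass(frozen=True)
class IdentitySummary:
    """Pairwise percent identities with their observed range."""

    matrix: pd.DataFrame
    min_identity: float
    max_identity: float


def _columns(seqs: list[str]) -> list[str]:
    return ["".join(col) for col in zip(*seqs)]


def variable_sites(
    alignment: AlleleSet | list[str], level: str = "nucleotide"
) -> tuple[int, int, float]:
    """Count variable columns: ``(variable, total, fraction)``.

    ``level`` is ``nucleotide`` (pass an :class:`AlleleSet` or nucleotide
    strings) or ``amino_acid`` (pass translated strings).
    """
    if level not in ("nucleotide", "amino_acid"):
        raise ValueError(f"level must be 'nucleotide' or 'amino_acid', got {level!r}")
    seqs = alignment.sequences if isinstance(alignment, AlleleSet) else list(alignment)
    if len(seqs) < 2:
        raise NoDataError("need >= 2 sequences")
    missing = _MISSING_NT if level == "nucleotide" else _MISSING_AA
    total = len(seqs[0])
    variable = 0
    for col in _columns(seqs):
        observed = {ch for ch in col if ch not in missing}
        if len(observed) >= 2:
            variable += 1
    return variable, total, (variable / total if total else 0.0)


def partition_variability(
    residues: list[str], partition: CodonPartition
) -> tuple[int, int, int, int]:
    """Variable amino-acid sites per stratum:
    ``(pbr_variable, pbr_total, nonpbr_variable, nonpbr_total)``."""
    if len(residues[0]) != partition.total_codons:
        raise NoDataError(
            f"residue length {len(residues[0])} != {partition.total_codons} codons"
        )
    cols = _columns(residues)
    pbr = set(partition.pbr_indices)
    pbr_var = nonpbr_var = 0
    for pos, col in enumerate(cols, start=partition.first_position):
        observed = {ch for ch in col if ch not in _MISSING_AA}
        if len(observed) >= 2:
            if pos in pbr:
                pbr_var += 1
            else:
                nonpbr_var += 1
    return pbr_var, partition.n_pbr, nonpbr_var, partition.n_non_pbr


def residue_table(
    residues: list[str], partition: CodonPartition, n_sequences: int | None = None
) -> PolymorphismTable:
    """Observed amino acids per codon position, sorted alphabetically;
    missing residues (X/gap) are excluded from the sets."""
    if len(residues[0]) != partition.total_codons:
        raise NoDataError(
            f"residue length {len(residues[0])} != {partition.total_codons} codons"
        )
    pbr = set(partition.pbr_indices)
    positions, sets, flags = [], [], []
    for pos, col in enumerate(_columns(residues), start=partition.first_position):
        observed = sorted({ch for ch in col if ch not in _MISSING_AA})
        positions.append(pos)
        sets.append(tuple(observed))
        flags.append(pos in pbr)
    return PolymorphismTable(
        positions=tuple(positions),
        residue_sets=tuple(sets),
        is_pbr=tuple(flags),
        n_sequences=n_sequences if n_sequences is not None else len(residues),
    )


def identity_matrix(alleles: AlleleSet) -> IdentitySummary:
    """Pairwise percent identity (pairwise deletion of missing columns) and
    its (min, max) over all unordered pairs."""
    if alleles.n < 2:
        raise NoDataError("need >= 2 sequences")
    n = alleles.n
    values = np.full((n, n), 100.0)
    pair_values = []
    for i in range(n):
        for j in range(i + 1, n):
            match = compared = 0
            for x, y in zip(alleles.sequences[i], alleles.sequences[j]):
                if x in _MISSING_NT or y in _MISSING_NT:
                    continue
                compared += 1
                if x == y:
                    match += 1
            ident = 100.0 * match / compared if compared else np.nan
            values[i, j] = values[j, i] = ident
            pair_values.append(ident)
    matrix = pd.DataFrame(values, index=alleles.ids, columns=alleles.ids)
    return IdentitySummary(
        matrix=matrix,
        min_identity=float(np.nanmin(pair_values)),
        max_identity=float(np.nanmax(pair_values)),
    )
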