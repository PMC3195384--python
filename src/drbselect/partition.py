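"""Peptide-binding-region (PBR) codon partitions.

Every selection statistic in this package is stratified by whether a codon
encodes a peptide-contact residue of the MHC class II β1 domain.  Two bundled
masks are provided for the standard 78-codon exon-2 window and the caller must
pick one explicitly:

``table2-asterisks``
    The 20 positions conventionally starred in interspecies DRB polymorphism
    tables: 9, 11, 13, 28, 30, 32, 37, 38, 47, 56, 60, 61, 70, 71, 74, 78,
    81, 82, 85, 86.

``brown1993-22``
    A 22-position peptide-contact mask per the Brown et al. (1993) human DR1
    crystal structure: the 20 above plus the pocket-lining residues 65 and 68.

Codon positions follow the mature β1-domain residue numbering used in DRB
polymorphism tables: the standard 78-codon exon-2 window spans residues 9-86,
so a partition carries a ``first_position`` (9 for the bundled masks) and its
positions live in ``[first_position, first_position + total_codons - 1]``.
This numbering also accommodates shorter windows naturally (e.g. a 75-codon
panel spanning residues 9-83 simply loses the starred positions 85 and 86,
leaving a 20-codon PBR).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import MaskError, PartitionApplicationError
from .seq_io import AlleleSet

TABLE2_ASTERISKS_20 = (
    9, 11, 13, 28, 30, 32, 37, 38, 47, 56,
    60, 61, 70, 71, 74, 78, 81, 82, 85, 86,
)
BROWN1993_22 = tuple(sorted(TABLE2_ASTERISKS_20 + (65, 68)))

_BUNDLED = {
    "table2-asterisks": TABLE2_ASTERISKS_20,
    "brown1993-22": BROWN1993_22,
}


@dataclass(frozen=True)
class CodonPartition:
    """A PBR / non-PBR split of the codons of an aligned coding region.

    ``pbr_indices`` are 1-based codon positions in the numbering that starts
    at ``first_position`` (1 for ad-hoc masks, 9 for the bundled β1-domain
    masks); they must lie in ``[first_position, first_position + total_codons - 1]``.
    """

    total_codons: int
    pbr_indices: tuple[int, ...]
    name: str = ""
    first_position: int = 1

    def __post_init__(self) -> None:
        if self.total_codons < 1:
            raise MaskError(f"total_codons must be positive, got {self.total_codons}")
        if len(set(self.pbr_indices)) != len(self.pbr_indices):
            raise MaskError("duplicate PBR positions in mask")
        for pos in self.pbr_indices:
            if not self.first_position <= pos <= self.last_position:
                raise MaskError(
                    f"PBR position {pos} outside "
                    f"{self.first_position}..{self.last_position}"
                )
        object.__setattr__(self, "pbr_indices", tuple(sorted(self.pbr_indices)))

    @property
    def last_position(self) -> int:
        return self.first_position + self.total_codons - 1

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(self.first_position, self.last_position + 1))

    @property
    def non_pbr_indices(self) -> tuple[int, ...]:
        pbr = set(self.pbr_indices)
        return tuple(i for i in self.positions if i not in pbr)

    @property
    def n_pbr(self) -> int:
        return len(self.pbr_indices)

    @property
    def n_non_pbr(self) -> int:
        return self.total_codons - len(self.pbr_indices)

    def is_pbr(self, position: int) -> bool:
        return position in set(self.pbr_indices)


def bundled_partition(name: str, total_codons: int = 78) -> CodonPartition:
    """Return one of the bundled β1-domain PBR masks by name (numbering
    starts at residue 9; shorter windows drop the trailing positions)."""
    if name not in _BUNDLED:
        raise MaskError(
            f"unknown bundled mask {name!r}; available: {sorted(_BUNDLED)}"
        )
    last = 9 + total_codons - 1
    positions = tuple(p for p in _BUNDLED[name] if p <= last)
    return CodonPartition(
        total_codons=total_codons, pbr_indices=positions, name=name, first_position=9
    )


def load_partition(path: str | Path) -> CodonPartition:
    """Read a mask file: ``total=<n>``, optional ``first=<n>`` (default 1),
    then a comma-separated line of PBR codon positions (may be empty for an
    all-non-PBR mask)."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("total="):
        raise MaskError(f"{path}: first line must be 'total=<n>'")
    try:
        total = int(lines[0].split("=", 1)[1])
    except ValueError as exc:
        raise MaskError(f"{path}: cannot parse total codon count") from exc
    first = 1
    rest = lines[1:]
    if rest and rest[0].startswith("first="):
        try:
            first = int(rest[0].split("=", 1)[1])
        except ValueError as exc:
            raise MaskError(f"{path}: cannot parse first position") from exc
        rest = rest[1:]
    positions: tuple[int, ...] = ()
    if rest and rest[0]:
        try:
            positions = tuple(int(tok) for tok in rest[0].split(","))
        except ValueError as exc:
            raise MaskError(f"{path}: cannot parse PBR positions") from exc
    return CodonPartition(
        total_codons=total, pbr_indices=positions, name=path.stem, first_position=first
    )


def save_partition(partition: CodonPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"total={partition.total_codons}\n")
        fh.write(f"first={partition.first_position}\n")
        fh.write(",".join(str(p) for p in partition.pbr_indices) + "\n")


def _extract(seq: str, codon_positions: tuple[int, ...], first: int) -> str:
    return "".join(
        seq[3 * (p - first) : 3 * (p - first) + 3] for p in codon_positions
    )


def split_codons(
    alleles: AlleleSet, partition: CodonPartition
) -> tuple[AlleleSet, AlleleSet]:
    """Split a panel into its PBR and non-PBR codon sub-alignments.

    Codon order within each stratum follows the original alignment, so
    re-interleaving by the recorded indices reconstructs the input exactly.
    """
    if alleles.length != 3 * partition.total_codons:
        raise PartitionApplicationError(
            f"alignment length {alleles.length} != 3 x {partition.total_codons} codons"
        )
    first = partition.first_position
    pbr = AlleleSet(
        label=f"{alleles.label}|PBR",
        ids=list(alleles.ids),
        sequences=[
            _extract(s, partition.pbr_indices, first) for s in alleles.sequences
        ],
    )
    non = AlleleSet(
        label=f"{alleles.label}|non-PBR",
        ids=list(alleles.ids),
        sequences=[
            _extract(s, partition.non_pbr_indices, first) for s in alleles.sequences
        ],
    )
    return pbr, non


def partition_table_tsv(partition: CodonPartition, path: str | Path) -> None:
    """Export the partition as TSV (codon position, stratum)."""
    pbr = set(partition.pbr_indices)
    with open(path, "w") as fh:
        fh.write("codon_position\tstratum\n")
        for pos in partition.positions:
            fh.write(f"{pos}\t{'PBR' if pos in pbr else 'non-PBR'}\n")
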