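"""Reading, curation and translation of aligned DRB exon-2 allele panels.

An allele panel is a set of distinct, equal-length, in-frame nucleotide
sequences for one species or breed group (e.g. the 234-bp exon-2 windows the
source panels use, 78 codons).  Curation mirrors the conventional workflow:
trim every record to a common coding window, drop byte-identical duplicates,
translate with the standard genetic code.

GenBank flat files are accepted as a convenience input, but the canonical
interchange format is aligned FASTA; accession fetching over the network is
deliberately not provided.  Note one documented erratum in the source panels:
the buffalo accession "AF3854473" carries one digit too many for a GenBank
identifier and cannot be resolved without guessing.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlignmentError, FormatError

logger = logging.getLogger(__name__)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid for all 64 codons, stops as '*'
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
GENETIC_CODE.update({c: "*" for c in _STANDARD_TABLE.stop_codons})

_VALID_CHARS = set("ACGTN-")
#: IUPAC ambiguity codes collapsed to N on read (their handling is otherwise
#: undocumented in typical submissions)
_AMBIGUITY = set("RYSWKMBDHV")


@dataclass
class AlleleSet:
    """An ordered, equal-length, aligned collection of allele sequences.

    Invariants: all sequences share one length that is a multiple of 3
    (codon-aligned); ids are unique and index-aligned with sequences.
    A zero-length set is permitted as the degenerate output of an empty
    codon-partition stratum.
    """

    label: str
    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences must be index-aligned")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError(f"duplicate ids in panel {self.label!r}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(
                f"unequal sequence lengths in panel {self.label!r}: {sorted(lengths)}"
            )
        if self.sequences and len(self.sequences[0]) % 3 != 0:
            raise AlignmentError(
                f"alignment length {len(self.sequences[0])} is not a multiple of 3"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))


def _normalize(seq: str, record_id: str) -> str:
    out = []
    warned = False
    for ch in seq.upper().replace("U", "T"):
        if ch in _AMBIGUITY:
            if not warned:
                logger.warning(
                    "record %s: ambiguity codes mapped to N", record_id
                )
                warned = True
            ch = "N"
        elif ch not in _VALID_CHARS:
            raise FormatError(f"record {record_id}: invalid character {ch!r}")
        out.append(ch)
    return "".join(out)


def read_aligned_fasta(path: str | Path, label: str | None = None) -> AlleleSet:
    """Read an aligned FASTA file into an :class:`AlleleSet`.

    Record order is preserved; lowercase is uppercased, U becomes T, IUPAC
    ambiguity codes collapse to N with a logged warning.  Records of unequal
    length raise :class:`AlignmentError` naming the first offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    seqs = [_normalize(str(r.seq), r.id) for r in records]
    ref_len = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != ref_len:
            raise AlignmentError(
                f"record {rid} has length {len(s)}, expected {ref_len}"
            )
    return AlleleSet(label=label or path.stem, ids=ids, sequences=seqs)


def read_genbank(path: str | Path, label: str | None = None) -> AlleleSet:
    """Convenience reader for a GenBank flat file of pre-aligned records."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    ids = [r.id for r in records]
    seqs = [_normalize(str(r.seq), r.id) for r in records]
    ref_len = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != ref_len:
            raise AlignmentError(
                f"record {rid} has length {len(s)}, expected {ref_len}"
            )
    return AlleleSet(label=label or path.stem, ids=ids, sequences=seqs)


def write_aligned_fasta(alleles: AlleleSet, path: str | Path) -> None:
    """Write the panel as aligned FASTA, wrapped at 60 columns."""
    with open(path, "w") as fh:
        for rid, seq in alleles:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def trim_to_region(alleles: AlleleSet, start: int, length: int) -> AlleleSet:
    """Cut every sequence to the window [start, start+length) (1-based start).

    The window length must be a multiple of 3 so the result stays
    codon-aligned.
    """
    if start < 1:
        raise AlignmentError(f"start must be >= 1, got {start}")
    if length % 3 != 0:
        raise AlignmentError(f"window length {length} is not a multiple of 3")
    if start + length - 1 > alleles.length:
        raise AlignmentError(
            f"window [{start}, {start + length - 1}] exceeds alignment length "
            f"{alleles.length}"
        )
    lo = start - 1
    return AlleleSet(
        label=alleles.label,
        ids=list(alleles.ids),
        sequences=[s[lo : lo + length] for s in alleles.sequences],
    )


def dedupe_identical(alleles: AlleleSet) -> AlleleSet:
    """Drop byte-identical sequences, keeping the first occurrence in order.

    Comparison is on the normalized nucleotide string, not the translation.
    """
    seen: set[str] = set()
    ids, seqs = [], []
    for rid, seq in alleles:
        if seq in seen:
            logger.info("panel %s: dropped duplicate %s", alleles.label, rid)
            continue
        seen.add(seq)
        ids.append(rid)
        seqs.append(seq)
    return AlleleSet(label=alleles.label, ids=ids, sequences=seqs)


def translate_sequence(seq: str, frame_offset: int = 0) -> str:
    """Translate one nucleotide string with the standard code.

    Codons containing '-' or 'N' yield 'X'; stop codons yield '*'.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    aa = []
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aa.append(GENETIC_CODE.get(codon, "X"))
    return "".join(aa)


def translate(alleles: AlleleSet, frame_offset: int = 0) -> list[str]:
    """Translate every sequence in the panel; see :func:`translate_sequence`."""
    return [translate_sequence(s, frame_offset) for s in alleles.sequences]


def write_manifest(alleles: AlleleSet, path: str | Path) -> None:
    """Write a TSV manifest (id, label, length, md5) for provenance tracking."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\tlength\tmd5\n")
        for rid, seq in alleles:
            digest = hashlib.md5(seq.encode()).hexdigest()
            fh.write(f"{rid}\t{alleles.label}\t{len(seq)}\t{digest}\n")
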