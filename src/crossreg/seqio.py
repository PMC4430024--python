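"""Sequence records, FASTA input/output and base-composition statistics.

Conventions used throughout the package:

* DNA alphabet is ``{A, C, G, T, N}``. Lowercase input is uppercased and RNA
  ``U`` is silently mapped to ``T`` so that 3'UTR analysis (AUUUA pentamers)
  runs on a single internal alphabet.
* Coordinates are 0-based, half-open everywhere internally (BED-compatible);
  1-based coordinates appear only in human-facing reports.
* A promoter is the 1,000 bp strictly upstream of the transcription start
  site on the gene's strand, written 5'->3' on that strand; the TSS base
  itself is excluded. The package consumes already-extracted sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")
STRANDS = frozenset({"+", "-", "."})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the expected format or alphabet."""


@dataclass
class SequenceRecord:
    """A named DNA sequence (promoter, 3'UTR or other).

    ``seq`` is stored uppercase over ``{A,C,G,T,N}``; ``species`` and ``role``
    are optional labels used by the cross-species and UTR stages.
    """

    id: str
    seq: str
    description: str = ""
    species: Optional[str] = None
    role: Optional[str] = None  # "promoter" | "utr3" | "other"

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq, record_id=self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Shared base pairs with ``other`` (0 if on different sequences)."""
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def normalize_seq(seq: str, record_id: str = "<seq>") -> str:
    """Uppercase, map U->T, and validate against the package alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise FastaFormatError(
            f"record {record_id!r} contains invalid characters: "
            + ", ".join(sorted(bad))
        )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement over ``{A,C,G,T,N}`` (N maps to N)."""
    s = normalize_seq(seq)
    return s.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T); N is excluded entirely."""
    s = normalize_seq(seq)
    if not s:
        raise ValueError("empty sequence")
    unambiguous = len(s) - s.count("N")
    if unambiguous == 0:
        raise ValueError("sequence contains only N")
    return (s.count("G") + s.count("C")) / unambiguous


def at_content(seq: str) -> float:
    """Complement of :func:`gc_content` over unambiguous bases."""
    return 1.0 - gc_content(seq)


def read_fasta(
    path: str | Path,
    species: Optional[str] = None,
    role: Optional[str] = None,
) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-FASTA file.

    Lowercase and RNA spellings are normalized; an empty file yields an empty
    list. Record ids must be unique within the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=str(rec.seq),
                description=rec.description,
                species=species,
                role=role,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_bed6(
    rows: Sequence[tuple[str, int, int, str, float, str]],
    path: str | Path,
) -> None:
    """Write BED6 lines from ``(chrom, start, end, name, rel_score, strand)``.

    The BED score column is ``round(1000 * rel_score)`` clamped to [0, 1000].
    """
    with open(path, "w") as fh:
        for chrom, start, end, name, rel, strand in rows:
            score = int(min(1000, max(0, round(1000 * rel))))
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
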