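"""Cross-species conservation: alignment parsing, identity profiles,
conserved-region calling and phylogenetic footprinting of motif hits.

The filtering logic follows classical phylogenetic footprinting: a motif
prediction in the reference species is kept only when (a) it falls in an
alignment segment of elevated cross-species identity and (b) a prediction
for the same factor in the other species overlaps it in alignment columns.
Conservation is assessed pairwise against a designated reference species
(human in the intended application), not as a joint multi-species criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import AlignIO

from .motif import MotifHit
from .seqio import normalize_seq

DEFAULT_WINDOW = 21
DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MIN_LEN = 21
DEFAULT_MIN_COL_OVERLAP = 0.5

GAP = "-"


@dataclass
class Alignment:
    """Gapped alignment rows as ``(species_label, gapped_sequence)`` pairs."""

    rows: list[tuple[str, str]]
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        for label, s in self.rows:
            normalize_seq(s.replace(GAP, ""), record_id=label)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    def species(self) -> list[str]:
        return [label for label, _ in self.rows]

    def row(self, key: int | str) -> tuple[str, str]:
        if isinstance(key, int):
            return self.rows[key]
        for label, s in self.rows:
            if label == key:
                return label, s
        raise KeyError(key)

    def ungapped(self, key: int | str) -> str:
        return self.row(key)[1].replace(GAP, "")


@dataclass(frozen=True)
class ConservedHit:
    """A reference-species motif hit supported by an overlapping same-TF hit
    in another species inside a conserved alignment region."""

    tf_name: str
    hit_a: MotifHit
    hit_b: MotifHit
    species_a: str
    species_b: str
    aligned_col_span_a: tuple[int, int]
    aligned_col_span_b: tuple[int, int]
    col_overlap_fraction: float
    region: tuple[int, int]


def parse_alignment(path: str | Path, fmt: str = "clustal") -> Alignment:
    """Read a CLUSTAL (``clustal``) or aligned-FASTA (``fasta``) alignment."""
    if fmt not in {"clustal", "fasta"}:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    aln = AlignIO.read(str(path), fmt)
    if len(aln) == 0:
        raise ValueError(f"empty alignment in {path}")
    return Alignment(rows=[(rec.id, str(rec.seq).upper()) for rec in aln])


def seq_to_aln_map(gapped_row: str) -> np.ndarray:
    """Array mapping each ungapped sequence position to its alignment column."""
    return np.flatnonzero(np.frombuffer(gapped_row.encode(), np.uint8) != ord(GAP))


def identity_profile(
    alignment: Alignment,
    pair: tuple[int | str, int | str] = (0, 1),
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Per-column identity between two rows, smoothed by a centered moving
    average with truncated windows at the edges.

    A column scores 1 when both bases are equal and neither is a gap.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    _, a = alignment.row(pair[0])
    _, b = alignment.row(pair[1])
    ai = np.frombuffer(a.encode(), np.uint8)
    bi = np.frombuffer(b.encode(), np.uint8)
    col_id = ((ai == bi) & (ai != ord(GAP))).astype(float)
    n = len(col_id)
    half = window // 2
    cs = np.concatenate([[0.0], np.cumsum(col_id)])
    pos = np.arange(n)
    starts = np.maximum(0, pos - half)
    ends = np.minimum(n, pos + half + 1)
    return (cs[ends] - cs[starts]) / (ends - starts)


def call_conserved_regions(
    profile: np.ndarray,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[tuple[int, int]]:
    """Maximal runs of columns with smoothed identity >= ``min_identity``,
    kept when at least ``min_len`` columns long."""
    if not 0.0 <= min_identity <= 1.0:
        raise ValueError("min_identity must be in [0, 1]")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    above = np.asarray(profile) >= min_identity
    regions: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                regions.append((start, i))
            start = None
    if start is not None and len(above) - start >= min_len:
        regions.append((start, len(above)))
    return regions


def pairwise_identity(alignment: Alignment, pair: tuple[int | str, int | str] = (0, 1)) -> float:
    """Percent identity: 100 x matches / columns-where-not-both-gaps.

    Columns with exactly one gap count as mismatches; gap-vs-gap columns are
    excluded from the denominator.
    """
    _, a = alignment.row(pair[0])
    _, b = alignment.row(pair[1])
    ai = np.frombuffer(a.encode(), np.uint8)
    bi = np.frombuffer(b.encode(), np.uint8)
    both_gap = (ai == ord(GAP)) & (bi == ord(GAP))
    usable = (~both_gap).sum()
    if usable == 0:
        raise ValueError("no usable (non gap-gap) columns")
    matches = ((ai == bi) & (ai != ord(GAP))).sum()
    return 100.0 * matches / usable


def _hit_col_span(hit: MotifHit, aln_map: np.ndarray) -> tuple[int, int]:
    if hit.end > len(aln_map):
        raise ValueError(
            f"hit [{hit.start}, {hit.end}) outside ungapped row of length {len(aln_map)}"
        )
    return int(aln_map[hit.start]), int(aln_map[hit.end - 1]) + 1


def conserved_hits(
    hits_by_species: dict[str, Sequence[MotifHit]],
    alignment: Alignment,
    regions: Sequence[tuple[int, int]],
    min_col_overlap: float = DEFAULT_MIN_COL_OVERLAP,
    reference: Optional[str] = None,
) -> list[ConservedHit]:
    """Call conserved TFBS between the reference species and every other
    species present in both ``hits_by_species`` and the alignment.

    A reference hit is conserved iff its mapped column span intersects a
    conserved region and a same-TF hit in the other species overlaps at
    least ``min_col_overlap`` of the reference span (in alignment columns).
    One :class:`ConservedHit` is emitted per supporting pair.
    """
    species = alignment.species()
    if reference is None:
        reference = species[0]
    if reference not in species:
        raise KeyError(f"reference species {reference!r} not in alignment")
    maps = {sp: seq_to_aln_map(alignment.row(sp)[1]) for sp in species}
    out: list[ConservedHit] = []
    for hit_a in hits_by_species.get(reference, []):
        span_a = _hit_col_span(hit_a, maps[reference])
        containing = [
            r for r in regions if min(span_a[1], r[1]) - max(span_a[0], r[0]) > 0
        ]
        if not containing:
            continue
        len_a = span_a[1] - span_a[0]
        for sp in species:
            if sp == reference:
                continue
            for hit_b in hits_by_species.get(sp, []):
                if hit_b.tf_name != hit_a.tf_name:
                    continue
                span_b = _hit_col_span(hit_b, maps[sp])
                overlap = min(span_a[1], span_b[1]) - max(span_a[0], span_b[0])
                frac = overlap / len_a if overlap > 0 else 0.0
                if frac >= min_col_overlap:
                    out.append(
                        ConservedHit(
                            tf_name=hit_a.tf_name,
                            hit_a=hit_a,
                            hit_b=hit_b,
                            species_a=reference,
                            species_b=sp,
                            aligned_col_span_a=span_a,
                            aligned_col_span_b=span_b,
                            col_overlap_fraction=frac,
                            region=containing[0],
                        )
                    )
    return out


def align_pair(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    label_a: str = "a",
    label_b: str = "b",
) -> Alignment:
    """Global Needleman-Wunsch alignment with a linear gap penalty.

    Plumbing only — it lets the pipeline run end-to-end when no external
    alignment is supplied. Ties are broken deterministically: prefer the
    diagonal move, then the gap-in-``seq_b`` (up) move, then gap-in-``seq_a``.
    The alignment score is stored on the returned :class:`Alignment`.
    """
    a = normalize_seq(seq_a, "seq_a")
    b = normalize_seq(seq_b, "seq_b")
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0=diag 1=up 2=left
    score[1:, 0] = gap * np.arange(1, n + 1)
    score[0, 1:] = gap * np.arange(1, m + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    b_arr = np.frombuffer(b.encode(), np.uint8)
    prev = score[0]
    for i in range(1, n + 1):
        cur = score[i]
        sub = np.where(b_arr == ord(a[i - 1]), match, mismatch)
        diag = prev[:-1] + sub
        cur[0] = gap * i
        for j in range(1, m + 1):
            d = diag[j - 1]
            u = prev[j] + gap
            l = cur[j - 1] + gap
            # priority diag > up > left on ties
            best, p = d, 0
            if u > best:
                best, p = u, 1
            if l > best:
                best, p = l, 2
            cur[j] = best
            ptr[i, j] = p
        prev = cur
    # traceback
    ga: list[str] = []
    gb: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == 0:
            ga.append(a[i - 1])
            gb.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and (p == 1 or j == 0):
            ga.append(a[i - 1])
            gb.append(GAP)
            i -= 1
        else:
            ga.append(GAP)
            gb.append(b[j - 1])
            j -= 1
    return Alignment(
        rows=[(label_a, "".join(reversed(ga))), (label_b, "".join(reversed(gb)))],
        score=float(score[n, m]),
    )


def conserved_hits_to_rows(chits: Iterable[ConservedHit]) -> list[dict]:
    return [
        {
            "tf": c.tf_name,
            "species_ref": c.species_a,
            "species_other": c.species_b,
            "ref_seq": c.hit_a.seq_id,
            "ref_start": c.hit_a.start,
            "ref_end": c.hit_a.end,
            "other_seq": c.hit_b.seq_id,
            "other_start": c.hit_b.start,
            "other_end": c.hit_b.end,
            "col_overlap_fraction": c.col_overlap_fraction,
            "region_start": c.region[0],
            "region_end": c.region[1],
        }
        for c in chits
    ]
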