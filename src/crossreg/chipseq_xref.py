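"""Cross-reference predicted TFBS with ChIP-seq peak files.

Peaks are consumed as BED3, BED6 or ENCODE narrowPeak (BED6+4) text files
with 0-based half-open coordinates. Support is binary interval overlap: a
predicted hit is supported by a peak set when it shares at least ``min_bp``
bases with any peak. Peak signal strength is carried through but never
thresholded — "strong peak" statements in the literature are qualitative
and are not operationalized here.

By default hits and peaks are expected in the same (promoter-local)
coordinate system; a genomic lift helper is provided for hits on promoters
whose genomic interval is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .motif import MotifHit
from .seqio import GenomicInterval


class PeakFormatError(ValueError):
    """Raised for malformed peak files (message carries the line number)."""


class CoordinateSystemMismatch(UserWarning):
    """Warned when hit and peak sequence ids are completely disjoint."""


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    name: str = "."
    signal: float = 0.0
    summit_offset: Optional[int] = None
    cell_line: str = ""
    tf_name: str = ""


@dataclass(frozen=True)
class HitSupport:
    hit: MotifHit
    supported: bool
    n_peaks: int
    max_overlap_bp: int


@dataclass(frozen=True)
class SupportReport:
    """Per-hit support across cell lines plus per-promoter peak coverage.

    ``per_hit`` maps each hit to its per-cell-line supported flags and the
    support fraction (supported lines / lines assayed); ``per_promoter``
    gives, per sequence id, the fraction of cell lines with at least one
    peak overlapping the promoter interval.
    """

    cell_lines: tuple[str, ...]
    per_hit: tuple[tuple[MotifHit, dict[str, bool], float], ...]
    per_promoter: dict[str, float]


def read_peaks(
    path: str | Path,
    fmt: Optional[str] = None,
    cell_line: str = "",
    tf_name: str = "",
) -> list[Peak]:
    """Read BED3 / BED6 / narrowPeak. ``fmt`` in {"bed3","bed6","narrowPeak"}
    or None to infer from the column count (3, 6 or 10)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            ncol = len(fields)
            this_fmt = fmt or {3: "bed3", 6: "bed6", 10: "narrowPeak"}.get(ncol)
            if this_fmt is None:
                raise PeakFormatError(
                    f"{path}:{lineno}: cannot infer format from {ncol} columns"
                )
            expected = {"bed3": 3, "bed6": 6, "narrowPeak": 10}[this_fmt]
            if ncol < expected:
                raise PeakFormatError(
                    f"{path}:{lineno}: {this_fmt} needs {expected} columns, got {ncol}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PeakFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start or start < 0:
                raise PeakFormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name, signal, strand, summit = ".", 0.0, ".", None
            if this_fmt in ("bed6", "narrowPeak"):
                name = fields[3]
                strand = fields[5] if fields[5] in "+-." else "."
                try:
                    signal = float(fields[6]) if this_fmt == "narrowPeak" else float(fields[4])
                except ValueError as exc:
                    raise PeakFormatError(
                        f"{path}:{lineno}: non-numeric score/signal"
                    ) from exc
            if this_fmt == "narrowPeak":
                try:
                    summit_raw = int(fields[9])
                except ValueError as exc:
                    raise PeakFormatError(
                        f"{path}:{lineno}: non-integer summit offset"
                    ) from exc
                summit = None if summit_raw == -1 else summit_raw
                if summit is not None and not 0 <= summit < end - start:
                    raise PeakFormatError(
                        f"{path}:{lineno}: summit offset {summit} outside peak"
                    )
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    name=name,
                    signal=signal,
                    summit_offset=summit,
                    cell_line=cell_line,
                    tf_name=tf_name,
                )
            )
    return peaks


def lift_hits_to_genome(
    hits: Sequence[MotifHit],
    promoter_intervals: Mapping[str, GenomicInterval],
) -> list[MotifHit]:
    """Shift promoter-local hits into genomic coordinates given each
    promoter's genomic interval (plus-strand promoters only: local position
    0 maps to the genomic start)."""
    out = []
    for h in hits:
        prom = promoter_intervals[h.seq_id]
        out.append(
            MotifHit(
                seq_id=prom.seq_id,
                interval=GenomicInterval(
                    prom.seq_id, prom.start + h.start, prom.start + h.end, h.strand
                ),
                strand=h.strand,
                tf_name=h.tf_name,
                family=h.family,
                raw_score=h.raw_score,
                rel_score=h.rel_score,
                matched_seq=h.matched_seq,
            )
        )
    return out


def intersect_hits_peaks(
    hits: Sequence[MotifHit],
    peaks: Sequence[Peak],
    min_bp: int = 1,
) -> list[HitSupport]:
    """Annotate each hit with whether it overlaps any peak by >= ``min_bp``."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    hit_ids = {h.seq_id for h in hits}
    peak_ids = {p.interval.seq_id for p in peaks}
    if hits and peaks and not hit_ids & peak_ids:
        warnings.warn(
            "hit and peak sequence ids are disjoint - coordinate systems "
            "probably do not match",
            CoordinateSystemMismatch,
            stacklevel=2,
        )
    out = []
    for h in hits:
        overlaps = [h.interval.overlap_bp(p.interval) for p in peaks]
        qualifying = [o for o in overlaps if o >= min_bp]
        out.append(
            HitSupport(
                hit=h,
                supported=bool(qualifying),
                n_peaks=len(qualifying),
                max_overlap_bp=max(overlaps, default=0),
            )
        )
    return out


def support_summary(
    hits: Sequence[MotifHit],
    peak_sets_by_cell_line: Mapping[str, Sequence[Peak]],
    promoter_lengths: Optional[Mapping[str, int]] = None,
    min_bp: int = 1,
) -> SupportReport:
    """Per-hit support fraction across cell lines and per-promoter coverage.

    Every supplied peak set counts as an assayed line for every hit (filter
    the mapping by TF upstream if sets target different factors). Promoter
    coverage uses ``promoter_lengths`` when given, otherwise any peak on the
    promoter's sequence id counts as overlapping it.
    """
    if not peak_sets_by_cell_line:
        raise ValueError("at least one peak set is required")
    cell_lines = tuple(peak_sets_by_cell_line)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CoordinateSystemMismatch)
        flags_by_line = {
            cl: {id(h): s.supported for h, s in zip(hits, intersect_hits_peaks(hits, peaks, min_bp))}
            for cl, peaks in peak_sets_by_cell_line.items()
        }
    per_hit = []
    for h in hits:
        flags = {cl: flags_by_line[cl][id(h)] for cl in cell_lines}
        frac = sum(flags.values()) / len(cell_lines)
        per_hit.append((h, flags, frac))
    seq_ids = sorted({h.seq_id for h in hits})
    per_promoter: dict[str, float] = {}
    for sid in seq_ids:
        covered = 0
        for cl in cell_lines:
            peaks = peak_sets_by_cell_line[cl]
            if promoter_lengths and sid in promoter_lengths:
                prom = GenomicInterval(sid, 0, promoter_lengths[sid])
                hit_any = any(prom.overlap_bp(p.interval) >= min_bp for p in peaks)
            else:
                hit_any = any(p.interval.seq_id == sid for p in peaks)
            covered += hit_any
        per_promoter[sid] = covered / len(cell_lines)
    return SupportReport(
        cell_lines=cell_lines,
        per_hit=tuple(per_hit),
        per_promoter=per_promoter,
    )


def support_to_rows(report: SupportReport) -> list[dict]:
    rows = []
    for hit, flags, frac in report.per_hit:
        row = {
            "seq_id": hit.seq_id,
            "start": hit.start,
            "end": hit.end,
            "strand": hit.strand,
            "tf": hit.tf_name,
            "support_fraction": frac,
        }
        row.update({f"line_{cl}": int(v) for cl, v in flags.items()})
        rows.append(row)
    return rows
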