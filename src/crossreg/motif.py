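"""Position-matrix machinery: PFM -> PWM conversion, log-odds scanning and
IUPAC consensus matching.

A position frequency matrix (PFM) holds per-column base counts from known
binding sites. It is converted to a position weight matrix (PWM) of log2-odds

    weight[b, i] = log2( ((counts[b, i] + p * bg[b]) / (N_i + p)) / bg[b] )

where ``N_i`` is the column count sum, ``p`` the total pseudocount
(distributed proportionally to the background) and ``bg`` the background base
probabilities. A window score is the sum of the weights of its bases, and the
*relative score* rescales it to [0, 1] between the matrix's minimum and
maximum attainable scores — the thresholding convention of classical TFBS
scanners. Windows containing ``N`` are skipped: a log-odds model assigns no
principled score to an ambiguous base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import GenomicInterval, SequenceRecord, normalize_seq, reverse_complement, write_bed6

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_REL_THRESHOLD = 0.80

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Synthetic consensus patterns the bundled matrices are built from. IRF3,
# IRF7 and the canonical RELA site follow published consensus sequences for
# these factors; the rest are field-standard motifs (kB site variants, the
# AP-1 TRE, the SP1 GC-box).
SYNTHETIC_CONSENSI = {
    "IRF1": "GAAAGTGAAAG",
    "IRF2": "GAAANTGAAA",
    "IRF3": "GAAASSAAANY",
    "IRF7": "GAAWNYGAAANY",
    "NFKB1": "GGGGATYCCC",
    "NFKB2": "GGGGAMTCCC",
    "RELA": "AGGAAATTCCG",
    "RELB": "GGGAWTTCCC",
    "REL": "GGGRATTTCC",
    "JUN": "TGASTCA",
    "SP1": "GGGGCGGRRY",
}

DEFAULT_FAMILY_MAP = {
    "IRF1": "IRF", "IRF2": "IRF", "IRF3": "IRF", "IRF7": "IRF",
    "NFKB1": "NFKB", "NFKB2": "NFKB", "RELA": "NFKB", "RELB": "NFKB",
    "REL": "NFKB",
    "JUN": "cofactor", "SP1": "cofactor",
}


class PFMFormatError(ValueError):
    """Raised for malformed matrix files."""


@dataclass
class PFM:
    """Position frequency matrix: 4 x width non-negative counts (rows ACGT)."""

    tf_name: str
    counts: np.ndarray
    family: str = "other"
    matrix_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix (rows A,C,G,T)")
        if (self.counts < 0).any():
            raise ValueError(f"negative counts in PFM {self.tf_name!r}")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"zero-sum column in PFM {self.tf_name!r}")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass
class PWM:
    """Log2-odds scoring matrix with min/max attainable scores."""

    tf_name: str
    weights: np.ndarray
    family: str = "other"
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    score_min: float = field(init=False)
    score_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.score_min = float(self.weights.min(axis=0).sum())
        self.score_max = float(self.weights.max(axis=0).sum())

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def rel_score(self, raw: float) -> float:
        """Rescale a raw score to [0, 1].

        Degenerate cases: a zero score range maps to 1.0; with a
        pseudocount of 0 a zero count makes ``score_min`` -inf, and the
        relative score is then 1.0 for the maximal raw score and 0.0
        otherwise.
        """
        rng = self.score_max - self.score_min
        if rng == 0:
            return 1.0
        if not np.isfinite(rng):
            return 1.0 if raw == self.score_max else 0.0
        return (raw - self.score_min) / rng


@dataclass(frozen=True)
class MotifHit:
    """One predicted TFBS on a scanned sequence's own coordinates.

    Minus-strand hits are reported in plus-strand coordinates;
    ``matched_seq`` is the strand-oriented sequence that matched the motif.
    """

    seq_id: str
    interval: GenomicInterval
    strand: str
    tf_name: str
    family: str
    raw_score: float
    rel_score: float
    matched_seq: str

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def pfm_to_pwm(
    pfm: PFM,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> PWM:
    """Convert counts to log2-odds weights with a background-proportional
    pseudocount."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,):
        raise ValueError("background must have 4 entries")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    if (bg <= 0).any():
        raise ValueError("background entries must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = pfm.counts
    col_sums = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (col_sums + pseudocount)
    with np.errstate(divide="ignore"):
        weights = np.log2(probs / bg[:, None])
    return PWM(
        tf_name=pfm.tf_name,
        weights=weights,
        family=pfm.family,
        background=tuple(bg),
        pseudocount=pseudocount,
    )


def pwm_extrema(pwm: PWM) -> tuple[float, float]:
    """Column-wise (min-sum, max-sum) attainable scores."""
    return pwm.score_min, pwm.score_max


def _seq_to_indices(seq: str) -> np.ndarray:
    """Map bases to 0..3, N to -1."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def _window_scores(weights: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores and validity (no-N) flags for every window of the motif width."""
    w = weights.shape[1]
    n = len(idx) - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(w):
        col = idx[j : j + n]
        valid &= col >= 0
        scores += weights[np.clip(col, 0, 3), j]
    return scores, valid


def scan(
    pwm: PWM,
    record: SequenceRecord,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    strands: Iterable[str] = ("+", "-"),
) -> list[MotifHit]:
    """Score every window on the requested strands; keep windows whose
    relative score reaches ``rel_threshold``.

    Results are sorted by (start, strand). A record shorter than the motif
    yields an empty list.
    """
    if not 0.0 <= rel_threshold <= 1.0:
        raise ValueError("rel_threshold must be in [0, 1]")
    strands = set(strands)
    if not strands <= {"+", "-"}:
        raise ValueError("strands must be a subset of {+, -}")
    seq = record.seq
    L = len(seq)
    w = pwm.width
    hits: list[MotifHit] = []
    for strand in strands:
        oriented = seq if strand == "+" else reverse_complement(seq)
        scores, valid = _window_scores(pwm.weights, _seq_to_indices(oriented))
        for i in np.nonzero(valid)[0]:
            raw = float(scores[i])
            rel = pwm.rel_score(raw)
            if rel < rel_threshold:
                continue
            start = i if strand == "+" else L - i - w
            hits.append(
                MotifHit(
                    seq_id=record.id,
                    interval=GenomicInterval(record.id, int(start), int(start + w), strand),
                    strand=strand,
                    tf_name=pwm.tf_name,
                    family=pwm.family,
                    raw_score=raw,
                    rel_score=rel,
                    matched_seq=oriented[i : i + w],
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def match_consensus(
    iupac_pattern: str,
    record: SequenceRecord,
    strands: Iterable[str] = ("+", "-"),
) -> list[MotifHit]:
    """Exact IUPAC degenerate-pattern matching on both strands.

    Every window whose bases each fall in the IUPAC set of the corresponding
    pattern symbol is a hit; overlapping occurrences are all reported.
    Relative score is fixed at 1.0 and the raw score is the pattern width.
    """
    pattern = iupac_pattern.upper()
    bad = set(pattern) - set(IUPAC_SETS)
    if bad:
        raise ValueError("invalid IUPAC symbol(s): " + ", ".join(sorted(bad)))
    strands = set(strands)
    if not strands <= {"+", "-"}:
        raise ValueError("strands must be a subset of {+, -}")
    sets = [IUPAC_SETS[c] for c in pattern]
    w = len(pattern)
    seq = record.seq
    L = len(seq)
    hits: list[MotifHit] = []
    for strand in strands:
        oriented = seq if strand == "+" else reverse_complement(seq)
        for i in range(L - w + 1):
            window = oriented[i : i + w]
            if all(b in s for b, s in zip(window, sets)):
                start = i if strand == "+" else L - i - w
                hits.append(
                    MotifHit(
                        seq_id=record.id,
                        interval=GenomicInterval(record.id, start, start + w, strand),
                        strand=strand,
                        tf_name=pattern,
                        family="consensus",
                        raw_score=float(w),
                        rel_score=1.0,
                        matched_seq=window,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def consensus_to_pfm(
    tf_name: str,
    iupac_consensus: str,
    family: str = "other",
    n_sites: int = 20,
    matrix_id: str = "",
) -> PFM:
    """Build a synthetic count matrix from an IUPAC consensus.

    ``n_sites`` nominal observations per column are split between the allowed
    bases with a one-count noise floor on disallowed bases: a single-base
    column becomes 17/1/1/1, a two-base column 9/9/1/1, a three-base column
    6/6/6/2 and N 5/5/5/5 (for the default ``n_sites=20``). This mimics the
    sharpness of curated matrices while keeping the construction transparent.
    """
    cols = []
    for sym in iupac_consensus.upper():
        allowed = IUPAC_SETS[sym]
        k = len(allowed)
        col = np.empty(4)
        if k == 4:
            col[:] = n_sites / 4
        else:
            floor = 2 if k == 3 else 1
            n_floor = (4 - k) * floor
            col[:] = floor
            for b in allowed:
                col[BASE_INDEX[b]] = (n_sites - n_floor) / k
        cols.append(col)
    return PFM(
        tf_name=tf_name,
        counts=np.column_stack(cols),
        family=family,
        matrix_id=matrix_id,
    )


_HEADER_RE = re.compile(r"^>\s*(\S+)(?:\s+(\S+))?")


def load_pfm_file(
    path: str | Path,
    family_map: Optional[dict[str, str]] = None,
) -> list[PFM]:
    """Read a JASPAR-style plain-text matrix file.

    Each matrix is a ``>id name`` header followed by four labelled count rows
    (``A  [ 1 2 3 ]`` — brackets optional). Families are assigned from
    ``family_map`` (default: the package's IRF/NFKB/cofactor map), falling
    back to "other".
    """
    if family_map is None:
        family_map = DEFAULT_FAMILY_MAP
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    pfms: list[PFM] = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line or line.startswith("#"):
            i += 1
            continue
        m = _HEADER_RE.match(line)
        if not m:
            raise PFMFormatError(f"{path}: expected '>' header, got {line!r}")
        matrix_id = m.group(1)
        name = m.group(2) or matrix_id
        rows: dict[str, list[float]] = {}
        i += 1
        for base in BASES:
            if i >= len(lines):
                raise PFMFormatError(f"matrix {matrix_id!r}: missing row {base}")
            row = lines[i].replace("[", " ").replace("]", " ").split()
            if not row or row[0].upper() != base:
                raise PFMFormatError(
                    f"matrix {matrix_id!r}: expected row {base}, got {lines[i]!r}"
                )
            try:
                rows[base] = [float(x) for x in row[1:]]
            except ValueError as exc:
                raise PFMFormatError(
                    f"matrix {matrix_id!r}: non-numeric counts in row {base}"
                ) from exc
            i += 1
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1 or widths == {0}:
            raise PFMFormatError(
                f"matrix {matrix_id!r}: rows of unequal or zero length"
            )
        counts = np.array([rows[b] for b in BASES])
        try:
            pfms.append(
                PFM(
                    tf_name=name,
                    counts=counts,
                    family=family_map.get(name, "other"),
                    matrix_id=matrix_id,
                )
            )
        except ValueError as exc:
            raise PFMFormatError(f"matrix {matrix_id!r}: {exc}") from exc
    return pfms


def bundled_pfms() -> list[PFM]:
    """The package's bundled synthetic, consensus-derived matrices."""
    from importlib.resources import as_file, files

    resource = files("crossreg").joinpath("data/pfms_synthetic.jaspar")
    with as_file(resource) as p:
        return load_pfm_file(p)


def hits_to_rows(hits: Iterable[MotifHit]) -> list[dict]:
    return [
        {
            "seq_id": h.seq_id,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "tf": h.tf_name,
            "family": h.family,
            "raw_score": h.raw_score,
            "rel_score": h.rel_score,
            "matched_seq": h.matched_seq,
        }
        for h in hits
    ]


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        hits_to_rows(hits),
        columns=[
            "seq_id", "start", "end", "strand", "tf", "family",
            "raw_score", "rel_score", "matched_seq",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_hits_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    write_bed6(
        [(h.seq_id, h.start, h.end, h.tf_name, h.rel_score, h.strand) for h in hits],
        path,
    )
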