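"""AU-rich element (ARE) detection and classification on 3'UTR sequences.

AREs are mRNA-destabilization elements of the 3' untranslated region built
around the AUUUA pentamer (ATTTA on the DNA sense strand, which is the
internal alphabet here). The three-class scheme follows the standard
Chen-Shyu taxonomy:

* class II — clustered / overlapping pentamers;
* class I  — a single pentamer embedded in an AU-rich local context;
* class III — a U-rich (here AT-rich) stretch without the pentamer.

The pentamer search runs on the sense strand only: AREs are elements of the
mRNA, not of the DNA duplex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import GenomicInterval, SequenceRecord, at_content, normalize_seq

PENTAMER = "ATTTA"
AT_BASES = frozenset("AT")


@dataclass(frozen=True)
class AREParams:
    """Tunable ARE classification parameters.

    cluster_gap: max distance (bp) between consecutive pentamer starts for
        them to form one class II cluster (default 5, i.e. adjacent or
        overlapping pentamers).
    ctx_window: flank length (bp) on each side of a singleton pentamer whose
        AT fraction decides class I membership.
    ctx_at_min: minimum flank AT fraction for class I.
    classIII_min_len: minimum window length for a class III AT-rich stretch.
    classIII_at_min: minimum AT fraction of a class III window.
    """

    cluster_gap: int = 5
    ctx_window: int = 10
    ctx_at_min: float = 0.65
    classIII_min_len: int = 30
    classIII_at_min: float = 0.75

    def validate(self) -> None:
        if self.cluster_gap < 0 or self.ctx_window < 0 or self.classIII_min_len < 1:
            raise ValueError("lengths must be non-negative (min_len >= 1)")
        if not (0 <= self.ctx_at_min <= 1 and 0 <= self.classIII_at_min <= 1):
            raise ValueError("AT fractions must lie in [0, 1]")


DEFAULT_ARE_PARAMS = AREParams()


@dataclass(frozen=True)
class ARESite:
    """A classified AU-rich element on a UTR (half-open interval)."""

    interval: GenomicInterval
    are_class: str  # "I" | "II" | "III"
    n_pentamers: int
    context_at_fraction: float


@dataclass(frozen=True)
class UTRSummary:
    utr_id: str
    length: int
    at_content: float
    n_class_I: int
    n_class_II: int
    n_class_III: int


def find_pentamers(seq: str) -> list[int]:
    """Sorted start positions of all (possibly overlapping) ATTTA pentamers
    on the sense strand."""
    s = normalize_seq(seq)
    out = []
    i = s.find(PENTAMER)
    while i != -1:
        out.append(i)
        i = s.find(PENTAMER, i + 1)
    return out


def _at_fraction(s: str) -> float:
    if not s:
        return 0.0
    return sum(1 for b in s if b in AT_BASES) / len(s)


def classify_are(
    seq: str,
    params: AREParams = DEFAULT_ARE_PARAMS,
    seq_id: str = "utr",
) -> list[ARESite]:
    """Classify AREs on one UTR sequence.

    1. Pentamers whose consecutive starts differ by at most ``cluster_gap``
       are grouped; clusters of >= 2 become one class II site spanning the
       cluster.
    2. Singleton pentamers whose +/- ``ctx_window`` flanks reach
       ``ctx_at_min`` AT fraction become class I; other singletons stay
       unclassified.
    3. Maximal unions of pentamer-free windows of length
       ``classIII_min_len`` with AT fraction >= ``classIII_at_min`` become
       class III sites.

    The classes are mutually exclusive by construction.
    """
    params.validate()
    s = normalize_seq(seq, record_id=seq_id)
    starts = find_pentamers(s)
    sites: list[ARESite] = []

    # cluster pentamers
    clusters: list[list[int]] = []
    for p in starts:
        if clusters and p - clusters[-1][-1] <= params.cluster_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    for cluster in clusters:
        lo, hi = cluster[0], cluster[-1] + len(PENTAMER)
        if len(cluster) >= 2:
            sites.append(
                ARESite(
                    interval=GenomicInterval(seq_id, lo, hi),
                    are_class="II",
                    n_pentamers=len(cluster),
                    context_at_fraction=_at_fraction(s[lo:hi]),
                )
            )
        else:
            p = cluster[0]
            ctx = s[max(0, p - params.ctx_window) : p] + s[
                p + len(PENTAMER) : p + len(PENTAMER) + params.ctx_window
            ]
            frac = _at_fraction(ctx)
            if frac >= params.ctx_at_min:
                sites.append(
                    ARESite(
                        interval=GenomicInterval(seq_id, p, p + len(PENTAMER)),
                        are_class="I",
                        n_pentamers=1,
                        context_at_fraction=frac,
                    )
                )

    # class III: merge qualifying pentamer-free AT-rich windows
    w = params.classIII_min_len
    n = len(s)
    at = [1 if b in AT_BASES else 0 for b in s]
    cum = [0]
    for v in at:
        cum.append(cum[-1] + v)
    pent_in_window = [False] * max(0, n - w + 1)
    for p in starts:
        # windows [i, i+w) containing the whole pentamer [p, p+5)
        lo = max(0, p + len(PENTAMER) - w)
        for i in range(lo, min(p, n - w) + 1):
            pent_in_window[i] = True
    merged: list[tuple[int, int]] = []
    for i in range(0, max(0, n - w + 1)):
        if pent_in_window[i]:
            continue
        if (cum[i + w] - cum[i]) / w < params.classIII_at_min:
            continue
        if merged and i <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], i + w))
        else:
            merged.append((i, i + w))
    for lo, hi in merged:
        sites.append(
            ARESite(
                interval=GenomicInterval(seq_id, lo, hi),
                are_class="III",
                n_pentamers=0,
                context_at_fraction=_at_fraction(s[lo:hi]),
            )
        )
    sites.sort(key=lambda x: (x.interval.start, x.are_class))
    return sites


def utr_summary(
    record: SequenceRecord,
    params: AREParams = DEFAULT_ARE_PARAMS,
) -> UTRSummary:
    """Length, AT content and per-class ARE counts for one 3'UTR."""
    if not record.seq:
        raise ValueError(f"empty UTR sequence {record.id!r}")
    sites = classify_are(record.seq, params, seq_id=record.id)
    by_class = {"I": 0, "II": 0, "III": 0}
    for site in sites:
        by_class[site.are_class] += 1
    return UTRSummary(
        utr_id=record.id,
        length=len(record.seq),
        at_content=at_content(record.seq),
        n_class_I=by_class["I"],
        n_class_II=by_class["II"],
        n_class_III=by_class["III"],
    )


def summaries_to_rows(summaries: Iterable[UTRSummary]) -> list[dict]:
    return [
        {
            "utr_id": u.utr_id,
            "length_bp": u.length,
            "at_percent": round(100 * u.at_content, 2),
            "class_I": u.n_class_I,
            "class_II": u.n_class_II,
            "class_III": u.n_class_III,
        }
        for u in summaries
    ]
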