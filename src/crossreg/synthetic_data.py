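"""Synthetic benchmark generators with machine-readable ground truth.

Every stage of the pipeline gets an input generator whose truth is known by
construction: promoter-like sequences with planted PFM instances,
orthologous promoter families with conserved blocks of controlled identity,
3'UTR-like sequences with planted class I/II/III AREs, and peak files
covering a controlled fraction of true sites.

The ortholog model uses substitutions only (no indels by default), so the
identity alignment is the true alignment and conservation calls can be
scored against exact truth. An optional single-base indel mode exists for
exercising gapped coordinate maps, at the price of a more intricate truth
alignment.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .are_utr import PENTAMER
from .chipseq_xref import Peak
from .conservation import Alignment
from .motif import BASES, BASE_INDEX, PFM
from .seqio import GenomicInterval, SequenceRecord, reverse_complement

UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PlantedSite:
    seq_id: str
    interval: GenomicInterval
    strand: str
    tf_name: str
    sampled_sequence: str  # in motif orientation


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generators (BED-style 0-based half-open
    coordinates throughout)."""

    planted_sites: list[PlantedSite] = field(default_factory=list)
    conserved_blocks: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    are_sites: list[tuple[str, tuple[int, int], str]] = field(default_factory=list)
    peak_coverage_fraction: Optional[float] = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_sites": [
                {
                    "seq_id": s.seq_id,
                    "start": s.interval.start,
                    "end": s.interval.end,
                    "strand": s.strand,
                    "tf": s.tf_name,
                    "sequence": s.sampled_sequence,
                }
                for s in self.planted_sites
            ],
            "conserved_blocks": [
                {"species": sp, "start": b[0], "end": b[1]}
                for sp, b in self.conserved_blocks
            ],
            "are_sites": [
                {"utr_id": u, "start": iv[0], "end": iv[1], "class": cls}
                for u, iv, cls in self.are_sites
            ],
            "peak_coverage_fraction": self.peak_coverage_fraction,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def delta_pfm(consensus: str, tf_name: str = "SYN", family: str = "synthetic",
              count: float = 20.0) -> PFM:
    """A delta-like (maximum-information) PFM: all counts on the consensus
    base of each column."""
    counts = np.zeros((4, len(consensus)))
    for i, b in enumerate(consensus.upper()):
        counts[BASE_INDEX[b], i] = count
    return PFM(tf_name=tf_name, counts=counts, family=family)


def random_consensus(rng: np.random.Generator, width: int) -> str:
    return "".join(rng.choice(list(BASES), size=width))


def sample_motif_instance(pfm: PFM, seed: int | np.random.Generator = 0) -> str:
    """Draw one site from the PFM: per-column sampling proportional to
    counts."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = pfm.counts / pfm.counts.sum(axis=0)
    return "".join(
        rng.choice(list(BASES), p=cols[:, i]) for i in range(pfm.width)
    )


def _random_background(rng: np.random.Generator, length: int,
                       composition: Sequence[float]) -> list[str]:
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 4 probabilities summing to 1")
    return list(rng.choice(list(BASES), size=length, p=comp))


def plant_motifs(
    length: int,
    pfm: PFM,
    n_sites: int,
    composition: Sequence[float] = UNIFORM,
    seed: int = 0,
    seq_id: str = "synth_promoter",
    max_tries: int = 10_000,
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Background sequence with ``n_sites`` non-overlapping sampled motif
    instances placed uniformly at random on random strands."""
    w = pfm.width
    if n_sites * w > length:
        raise ValueError("sites cannot fit in the sequence")
    rng = np.random.default_rng(seed)
    bases = _random_background(rng, length, composition)
    placed: list[tuple[int, int]] = []
    truth = SyntheticTruth()
    for _ in range(n_sites):
        for attempt in range(max_tries):
            start = int(rng.integers(0, length - w + 1))
            if all(start + w <= s or start >= e for s, e in placed):
                break
        else:
            raise RuntimeError("could not pack sites without overlap")
        placed.append((start, start + w))
        strand = str(rng.choice(["+", "-"]))
        instance = sample_motif_instance(pfm, rng)
        inserted = instance if strand == "+" else reverse_complement(instance)
        bases[start : start + w] = list(inserted)
        truth.planted_sites.append(
            PlantedSite(
                seq_id=seq_id,
                interval=GenomicInterval(seq_id, start, start + w, strand),
                strand=strand,
                tf_name=pfm.tf_name,
                sampled_sequence=instance,
            )
        )
    truth.planted_sites.sort(key=lambda s: s.interval.start)
    record = SequenceRecord(id=seq_id, seq="".join(bases), role="promoter")
    return record, truth


def generate_ortholog_family(
    length: int,
    species_divergences: Mapping[str, float],
    conserved_blocks: Sequence[tuple[int, int]],
    pfm_plants: Sequence[tuple[PFM, int]] = (),
    composition: Sequence[float] = UNIFORM,
    seed: int = 0,
    block_divergence_factor: float = 0.1,
    indel_rate: float = 0.0,
    gene: str = "synth_gene",
) -> tuple[dict[str, SequenceRecord], Alignment, SyntheticTruth]:
    """Orthologous promoter family from a common ancestor.

    Each species copy mutates the ancestor per site with probability equal
    to its divergence outside the conserved blocks and ``divergence *
    block_divergence_factor`` inside them (substitutions only, uniform over
    the three other bases), so the true alignment is the identity alignment.
    Planted motif instances are written identically into all species at the
    requested (within-block) positions. With ``indel_rate`` > 0, species
    additionally acquire single-base insertions/deletions outside blocks,
    and the returned truth alignment is gapped accordingly.
    """
    if not species_divergences:
        raise ValueError("at least one species required")
    for lo, hi in conserved_blocks:
        if not (0 <= lo < hi <= length):
            raise ValueError(f"block [{lo}, {hi}) outside [0, {length})")
    rng = np.random.default_rng(seed)
    ancestor = _random_background(rng, length, composition)

    in_block = np.zeros(length, dtype=bool)
    for lo, hi in conserved_blocks:
        in_block[lo:hi] = True

    # plant instances into the ancestor (and, identically, every species)
    planted: list[tuple[int, int, str, str, str]] = []  # start,end,strand,tf,inst
    for pfm, start in pfm_plants:
        end = start + pfm.width
        if not in_block[start:end].all():
            raise ValueError(
                f"plant [{start}, {end}) not inside a conserved block"
            )
        if any(s < end and start < e for s, e, *_ in planted):
            raise ValueError(f"plant [{start}, {end}) overlaps another plant")
        strand = str(rng.choice(["+", "-"]))
        instance = sample_motif_instance(pfm, rng)
        inserted = instance if strand == "+" else reverse_complement(instance)
        ancestor[start:end] = list(inserted)
        planted.append((start, end, strand, pfm.tf_name, instance))
    plant_mask = np.zeros(length, dtype=bool)
    for s, e, *_ in planted:
        plant_mask[s:e] = True

    truth = SyntheticTruth()
    records: dict[str, SequenceRecord] = {}
    cells: dict[str, list[str]] = {}          # per ancestor position: base or ""
    inserts: dict[str, dict[int, str]] = {}   # insertions after ancestor position

    other = {b: [x for x in BASES if x != b] for b in BASES}
    for sp, div in species_divergences.items():
        if not 0.0 <= div <= 1.0:
            raise ValueError(f"divergence for {sp!r} must be in [0, 1]")
        p_site = np.where(in_block, div * block_divergence_factor, div)
        p_site = np.where(plant_mask, 0.0, p_site)  # plants stay intact
        mutate = rng.random(length) < p_site
        row = list(ancestor)
        for i in np.nonzero(mutate)[0]:
            row[i] = other[row[i]][rng.integers(0, 3)]
        ins: dict[int, str] = {}
        if indel_rate > 0:
            editable = ~(in_block | plant_mask)
            dele = (rng.random(length) < indel_rate / 2) & editable
            for i in np.nonzero(dele)[0]:
                row[i] = ""
            insert_at = (rng.random(length) < indel_rate / 2) & editable
            for i in np.nonzero(insert_at)[0]:
                ins[int(i)] = str(rng.choice(list(BASES)))
        cells[sp] = row
        inserts[sp] = ins
        seq_id = f"{gene}_{sp}"
        parts = []
        # prefix[i] = species-local coordinate of ancestor position i
        prefix = [0] * (length + 1)
        for i, base in enumerate(row):
            parts.append(base)
            if i in ins:
                parts.append(ins[i])
            prefix[i + 1] = prefix[i] + len(base) + len(ins.get(i, ""))
        records[sp] = SequenceRecord(
            id=seq_id, seq="".join(parts), species=sp, role="promoter"
        )
        for lo, hi in conserved_blocks:
            truth.conserved_blocks.append((sp, (prefix[lo], prefix[hi])))
        for s, e, strand, tf, inst in planted:
            truth.planted_sites.append(
                PlantedSite(
                    seq_id=seq_id,
                    interval=GenomicInterval(seq_id, prefix[s], prefix[e], strand),
                    strand=strand,
                    tf_name=tf,
                    sampled_sequence=inst,
                )
            )

    # build the truth alignment
    species = list(species_divergences)
    gapped = {sp: [] for sp in species}
    for i in range(length):
        for sp in species:
            gapped[sp].append(cells[sp][i] or "-")
        for owner in species:
            if i in inserts[owner]:
                for sp in species:
                    gapped[sp].append(inserts[owner][i] if sp == owner else "-")
    alignment = Alignment(rows=[(sp, "".join(gapped[sp])) for sp in species])
    return records, alignment, truth


# --- synthetic 3'UTR construction ------------------------------------------

# Fixed feature blocks. Flanks of the class I block are pure A/T 10-mers
# chosen so that no junction creates a second ATTTA pentamer; the class III
# block is an AT run with all pentamers destroyed by construction.
_CLASS_I_FLANK_5 = "ATATTAATAT"
_CLASS_I_FLANK_3 = "TAATATTAAT"
_CLASS_I_BLOCK = _CLASS_I_FLANK_5 + PENTAMER + _CLASS_I_FLANK_3
_CLASS_II_BLOCK = "ATTTATTTA"
_CLASS_III_BLOCK = "AATT" * 9  # 36 nt, AT fraction 1.0, no ATTTA substring

_MIN_GAP = 30  # >= classIII_min_len so no window bridges two features


def _spacer(rng: np.random.Generator, n: int, at_fraction: float) -> str:
    """GC-dominated spacer with isolated A/T bases steered toward a target
    AT fraction.

    Constraints that make spacers inert for ARE analysis: the two bases at
    each end are G/C, and no two A/T bases are adjacent, so a spacer can
    never contain an ATTTA pentamer nor an AT-rich class III window.
    """
    at_fraction = min(max(at_fraction, 0.0), 0.5)
    out: list[str] = []
    placed = 0
    for i in range(n):
        allowed = 2 <= i < n - 2 and (not out or out[-1] not in "AT")
        if allowed and placed < at_fraction * (i + 1):
            out.append(str(rng.choice(["A", "T"])))
            placed += 1
        else:
            out.append(str(rng.choice(["G", "C"])))
    return "".join(out)


def generate_synthetic_utr(
    n_classI: int,
    n_classII: int,
    n_classIII: int,
    at_target: float = 0.5,
    length: int = 2000,
    seed: int = 0,
    utr_id: str = "synth_utr",
) -> tuple[SequenceRecord, SyntheticTruth]:
    """A 3'UTR-like sequence carrying exactly the requested ARE features.

    Class II features are overlapping pentamer pairs (ATTTATTTA); class I a
    single pentamer inside 10-nt pure-AT flanks; class III 36-nt AT runs
    with no pentamer. Features are separated by GC-dominated spacers of at
    least 30 nt whose sparse isolated A/T content steers the sequence
    toward ``at_target``.
    """
    rng = np.random.default_rng(seed)
    features = (
        [("I", _CLASS_I_BLOCK)] * n_classI
        + [("II", _CLASS_II_BLOCK)] * n_classII
        + [("III", _CLASS_III_BLOCK)] * n_classIII
    )
    order = rng.permutation(len(features))
    features = [features[i] for i in order]
    block_len = sum(len(b) for _, b in features)
    n_gaps = len(features) + 1
    spacer_total = length - block_len
    if features and spacer_total < _MIN_GAP * n_gaps:
        raise ValueError(
            f"cannot fit {len(features)} features plus {_MIN_GAP}-nt spacers "
            f"in {length} nt"
        )
    block_at = sum(sum(1 for b in blk if b in "AT") for _, blk in features)
    spacer_at_target = (
        (at_target * length - block_at) / spacer_total if spacer_total else 0.0
    )
    base = spacer_total // n_gaps
    rem = spacer_total % n_gaps
    gap_lens = [base + (1 if i < rem else 0) for i in range(n_gaps)]

    parts: list[str] = []
    truth = SyntheticTruth()
    pos = 0
    for (cls, blk), gap in zip(features, gap_lens):
        sp = _spacer(rng, gap, spacer_at_target)
        parts.append(sp)
        pos += len(sp)
        parts.append(blk)
        truth.are_sites.append((utr_id, (pos, pos + len(blk)), cls))
        pos += len(blk)
    parts.append(_spacer(rng, gap_lens[-1], spacer_at_target))
    record = SequenceRecord(id=utr_id, seq="".join(parts), role="utr3")
    assert len(record.seq) == length
    return record, truth


def generate_peak_file(
    truth: SyntheticTruth,
    coverage_fraction: float,
    seq_lengths: Mapping[str, int],
    jitter_bp: int = 0,
    n_decoys: int = 0,
    seed: int = 0,
    cell_line: str = "synthetic",
    max_tries: int = 10_000,
) -> list[Peak]:
    """Peaks covering each planted true site independently with probability
    ``coverage_fraction``, plus ``n_decoys`` decoy peaks away from true
    sites. Peak widths are uniform in [150, 300]; centers sit on the site
    center +/- ``jitter_bp``."""
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    peaks: list[Peak] = []
    covered = 0
    for site in truth.planted_sites:
        if rng.random() >= coverage_fraction:
            continue
        covered += 1
        L = seq_lengths[site.seq_id]
        width = int(rng.integers(150, 301))
        center = (site.interval.start + site.interval.end) // 2
        if jitter_bp:
            center += int(rng.integers(-jitter_bp, jitter_bp + 1))
        start = max(0, min(L - 1, center - width // 2))
        end = min(L, start + width)
        peaks.append(
            Peak(
                interval=GenomicInterval(site.seq_id, start, end),
                name=f"peak_{len(peaks) + 1}",
                signal=float(rng.uniform(5, 50)),
                summit_offset=(end - start) // 2,
                cell_line=cell_line,
                tf_name=site.tf_name,
            )
        )
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for site in truth.planted_sites:
        by_seq.setdefault(site.seq_id, []).append(
            (site.interval.start, site.interval.end)
        )
    seq_ids = sorted(seq_lengths)
    for k in range(n_decoys):
        for _ in range(max_tries):
            sid = seq_ids[int(rng.integers(0, len(seq_ids)))]
            L = seq_lengths[sid]
            width = int(rng.integers(150, min(301, L + 1)))
            start = int(rng.integers(0, max(1, L - width + 1)))
            end = start + width
            if all(e <= start or end <= s for s, e in by_seq.get(sid, [])):
                break
        else:
            raise RuntimeError("could not place decoy peaks away from true sites")
        peaks.append(
            Peak(
                interval=GenomicInterval(sid, start, end),
                name=f"decoy_{k + 1}",
                signal=float(rng.uniform(5, 50)),
                summit_offset=(end - start) // 2,
                cell_line=cell_line,
                tf_name="decoy",
            )
        )
    if truth.peak_coverage_fraction is None:
        truth.peak_coverage_fraction = coverage_fraction
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks in ENCODE narrowPeak (BED6+4) format."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}"
                f"\t{p.signal:.3f}\t-1\t-1\t{summit}\n"
            )
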