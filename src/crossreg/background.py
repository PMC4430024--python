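"""Random-sequence background model for motif-count specificity.

The specificity control asks whether a factor's binding sites are enriched
in the promoter dataset relative to chance: scan a set of random sequences
(by default 100 sequences of 1 kb, mirroring the promoter length) with the
same matrix and threshold, and compare mean hit counts. The empirical
p-value uses the add-one permutation-style estimator

    p = (1 + #{random sequences with count >= mean_data}) / (n_rand + 1)

which can never return zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .motif import DEFAULT_REL_THRESHOLD, PWM, match_consensus, scan
from .seqio import SequenceRecord

BASES = "ACGT"
UNIFORM = (0.25, 0.25, 0.25, 0.25)

Motif = Union[PWM, str]  # a PWM, or an IUPAC consensus pattern


@dataclass(frozen=True)
class BackgroundComparison:
    """Mean hit counts on real vs random sequences.

    ``specificity_ratio`` is ``mean_data / mean_rand`` (None when no random
    hits occurred); ``dataset_specific`` flags mean_data > mean_rand with
    empirical p <= 0.05 — reported, never enforced.
    """

    tf_name: str
    mean_data: float
    mean_rand: float
    specificity_ratio: Optional[float]
    empirical_p: float
    n_rand: int
    seed: int
    dataset_specific: bool


def random_sequences(
    n: int,
    length: int = 1000,
    composition: Sequence[float] = UNIFORM,
    seed: int = 0,
) -> list[SequenceRecord]:
    """``n`` i.i.d. random DNA sequences; reproducible for a fixed seed.

    Ids are ``rand_0001`` ... and the records carry role "other".
    """
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
        raise ValueError("composition must be 4 non-negative probabilities summing to 1")
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n):
        bases = rng.choice(list(BASES), size=length, p=comp)
        records.append(
            SequenceRecord(id=f"rand_{k + 1:04d}", seq="".join(bases), role="other")
        )
    return records


def _count_hits(motif: Motif, record: SequenceRecord, rel_threshold: float) -> int:
    if isinstance(motif, str):
        return len(match_consensus(motif, record, strands=("+", "-")))
    return len(scan(motif, record, rel_threshold=rel_threshold, strands=("+", "-")))


def hit_counts(
    motif: Motif,
    records: Sequence[SequenceRecord],
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
) -> np.ndarray:
    """Per-record hit counts (both strands)."""
    if len(records) == 0:
        raise ValueError("empty record list")
    return np.array([_count_hits(motif, r, rel_threshold) for r in records])


def mean_hit_count(
    motif: Motif,
    records: Sequence[SequenceRecord],
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
) -> float:
    """Arithmetic mean of per-record hit counts (both strands)."""
    return float(hit_counts(motif, records, rel_threshold).mean())


def expected_consensus_mean(length: int, width: int) -> float:
    """Closed-form expected count of an exact (non-degenerate) ``width``-mer
    on a uniform random sequence of ``length`` bp, both strands:
    ``2 * (length - width + 1) * 4**(-width)``."""
    return 2.0 * (length - width + 1) * 4.0 ** (-width)


def specificity_comparison(
    motif: Motif,
    data_records: Sequence[SequenceRecord],
    n_rand: int = 100,
    length: int = 1000,
    composition: Sequence[float] = UNIFORM,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    seed: int = 0,
    tf_name: Optional[str] = None,
) -> BackgroundComparison:
    """Compare mean hit counts on the dataset against a fresh random set."""
    data_counts = hit_counts(motif, data_records, rel_threshold)
    rand = random_sequences(n_rand, length=length, composition=composition, seed=seed)
    rand_counts = hit_counts(motif, rand, rel_threshold)
    mean_data = float(data_counts.mean())
    mean_rand = float(rand_counts.mean())
    p = (1 + int((rand_counts >= mean_data).sum())) / (n_rand + 1)
    ratio = mean_data / mean_rand if mean_rand > 0 else None
    if tf_name is None:
        tf_name = motif if isinstance(motif, str) else motif.tf_name
    return BackgroundComparison(
        tf_name=tf_name,
        mean_data=mean_data,
        mean_rand=mean_rand,
        specificity_ratio=ratio,
        empirical_p=p,
        n_rand=n_rand,
        seed=seed,
        dataset_specific=(mean_data > mean_rand and p <= 0.05),
    )


def comparisons_to_rows(comparisons: Sequence[BackgroundComparison]) -> list[dict]:
    return [
        {
            "tf": c.tf_name,
            "mean_data": c.mean_data,
            "mean_rand": c.mean_rand,
            "specificity_ratio": c.specificity_ratio,
            "empirical_p": c.empirical_p,
            "n_rand": c.n_rand,
            "seed": c.seed,
            "dataset_specific": c.dataset_specific,
        }
        for c in comparisons
    ]
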