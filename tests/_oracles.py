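"""Independent oracles used by the test suite: pure-Python brute-force
implementations that share no scoring code with the package."""

import math

# ---------------------------------------------------------------------------
# independent brute-force oracle: direct formula evaluation, no shared code
# with crossreg.motif beyond the count matrices themselves
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_scan(counts, seq, pseudocount, background, threshold):
    """Enumerate all windows on both strands and score them by the log-odds
    formula evaluated per cell with math.log2."""
    bases = "ACGT"
    w = len(counts[0])
    weights = []
    for bi in range(4):
        row = []
        for j in range(w):
            col_sum = sum(counts[k][j] for k in range(4))
            p = (counts[bi][j] + pseudocount * background[bi]) / (col_sum + pseudocount)
            row.append(math.log2(p / background[bi]) if p > 0 else -math.inf)
        weights.append(row)
    smin = sum(min(weights[b][j] for b in range(4)) for j in range(w))
    smax = sum(max(weights[b][j] for b in range(4)) for j in range(w))
    hits = []
    L = len(seq)
    for strand in "+-":
        oriented = seq if strand == "+" else _rc(seq)
        for i in range(L - w + 1):
            window = oriented[i : i + w]
            if "N" in window:
                continue
            raw = sum(weights[bases.index(b)][j] for j, b in enumerate(window))
            if smax == smin:
                rel = 1.0
            elif math.isinf(smin):
                rel = 1.0 if raw == smax else 0.0
            else:
                rel = (raw - smin) / (smax - smin)
            if rel >= threshold:
                start = i if strand == "+" else L - i - w
                hits.append((start, start + w, strand, raw, rel))
    hits.sort(key=lambda h: (h[0], h[2]))
    return hits
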