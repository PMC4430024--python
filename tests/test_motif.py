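import math

import numpy as np
import pytest

from crossreg import motif, seqio
from crossreg.synthetic_data import delta_pfm

from _oracles import brute_force_scan

# ---------------------------------------------------------------------------
# pfm_to_pwm
# ---------------------------------------------------------------------------

def test_uniform_column_gives_zero_weights():
    pfm = motif.PFM("u", np.ones((4, 1)))
    pwm = motif.pfm_to_pwm(pfm, pseudocount=0.0)
    assert np.allclose(pwm.weights, 0.0)


def test_delta_column_weight_is_two_bits():
    pfm = motif.PFM("d", np.array([[10.0], [0.0], [0.0], [0.0]]))
    pwm = motif.pfm_to_pwm(pfm, pseudocount=0.0)
    assert pwm.weights[0, 0] == pytest.approx(2.0)


def test_pseudocount_weight_hand_computed():
    # column (A:3, C:1, G:0, T:0), pseudocount 0.8, uniform background:
    # weight_G = log2(((0 + 0.8*0.25) / (4 + 0.8)) / 0.25)
    pfm = motif.PFM("x", np.array([[3.0], [1.0], [0.0], [0.0]]))
    pwm = motif.pfm_to_pwm(pfm, pseudocount=0.8)
    assert pwm.weights[2, 0] == pytest.approx(math.log2((0.2 / 4.8) / 0.25))
    assert pwm.weights[2, 0] == pytest.approx(-2.585, abs=1e-3)


def test_pfm_validation():
    with pytest.raises(ValueError, match="zero-sum"):
        motif.PFM("z", np.zeros((4, 2)))
    with pytest.raises(ValueError):
        motif.pfm_to_pwm(motif.PFM("u", np.ones((4, 1))), background=(0.5, 0.5, 0.0, 0.0))


def test_pwm_extrema():
    pwm = motif.pfm_to_pwm(delta_pfm("ACGT"), pseudocount=0.0)
    assert motif.pwm_extrema(pwm)[1] == pytest.approx(8.0)
    degenerate = motif.PWM("flat", np.zeros((4, 3)))
    assert motif.pwm_extrema(degenerate) == (0.0, 0.0)
    assert degenerate.rel_score(0.0) == 1.0


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def test_scan_delta_both_strands():
    pwm = motif.pfm_to_pwm(delta_pfm("ACGT"), pseudocount=0.0)
    rec = seqio.SequenceRecord("s", "ACGTACGT")
    hits = motif.scan(pwm, rec, rel_threshold=1.0)
    assert [(h.start, h.end, h.strand) for h in hits] == [
        (0, 4, "+"), (0, 4, "-"), (4, 8, "+"), (4, 8, "-"),
    ]
    assert all(h.matched_seq == "ACGT" for h in hits)


def test_scan_threshold_floor_counts_every_window():
    pwm = motif.pfm_to_pwm(delta_pfm("ACG"))
    rec = seqio.SequenceRecord("s", "TTTTTTTTTT")
    hits = motif.scan(pwm, rec, rel_threshold=0.0, strands=("+",))
    assert len(hits) == len(rec.seq) - pwm.width + 1


def test_scan_short_sequence_is_empty():
    pwm = motif.pfm_to_pwm(delta_pfm("ACGT"))
    assert motif.scan(pwm, seqio.SequenceRecord("s", "AAA")) == []


def test_scan_skips_windows_with_n():
    pwm = motif.pfm_to_pwm(delta_pfm("ACGT"), pseudocount=0.0)
    rec = seqio.SequenceRecord("s", "ACGTNACGT")
    hits = motif.scan(pwm, rec, rel_threshold=0.0, strands=("+",))
    starts = {h.start for h in hits}
    assert starts == {0, 5}  # windows touching the N are skipped


def test_scan_strand_symmetry(rng):
    from crossreg.seqio import reverse_complement

    for _ in range(20):
        w = int(rng.integers(2, 6))
        counts = rng.integers(0, 10, size=(4, w)).astype(float) + 0.5
        pwm = motif.pfm_to_pwm(motif.PFM("r", counts))
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(w, 25))))
        fwd = motif.scan(pwm, seqio.SequenceRecord("x", reverse_complement(seq)),
                         rel_threshold=0.0, strands=("+",))
        rev = motif.scan(pwm, seqio.SequenceRecord("x", seq),
                         rel_threshold=0.0, strands=("-",))
        L = len(seq)
        mirrored = sorted((L - h.end, L - h.start, round(h.raw_score, 9)) for h in fwd)
        got = sorted((h.start, h.end, round(h.raw_score, 9)) for h in rev)
        assert mirrored == got


def test_scan_agrees_with_bruteforce_oracle(rng):
    for _ in range(50):
        w = int(rng.integers(1, 7))
        counts = rng.integers(0, 12, size=(4, w)).astype(float)
        counts[rng.integers(0, 4), :] += 1  # positive column sums
        seq = "".join(
            rng.choice(list("ACGTN"), size=int(rng.integers(1, 31)), p=[0.23] * 4 + [0.08])
        )
        threshold = float(rng.uniform(0, 1))
        pwm = motif.pfm_to_pwm(motif.PFM("r", counts))
        got = [
            (h.start, h.end, h.strand, round(h.raw_score, 9), round(h.rel_score, 9))
            for h in motif.scan(pwm, seqio.SequenceRecord("x", seq), threshold)
        ]
        expected = [
            (s, e, st, round(raw, 9), round(rel, 9))
            for s, e, st, raw, rel in brute_force_scan(
                counts.tolist(), seq, 0.8, [0.25] * 4, threshold
            )
        ]
        assert got == expected


def test_scan_reported_rel_scores_respect_threshold(bundled):
    pwm = motif.pfm_to_pwm(bundled["JUN"])
    rec = seqio.SequenceRecord("s", "TGACTCA" * 20)
    hits = motif.scan(pwm, rec, rel_threshold=0.8)
    assert hits and all(h.rel_score >= 0.8 for h in hits)


# ---------------------------------------------------------------------------
# consensus matching
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pattern,seq,n_plus",
    [
        ("AGGAAATTCCG", "AGGAAATTCCG", 1),  # canonical kB site, self-match
        ("RGGRNNHHYYB", "AGGAAATTCCG", 1),  # generalized NF-kB consensus
        ("GAAASSAAANY", "GAAACCAAATC", 1),
        ("GAAASSAAANY", "GAAATTAAATC", 0),  # T not in S
    ],
)
def test_match_consensus_iupac(pattern, seq, n_plus):
    rec = seqio.SequenceRecord("s", seq)
    hits = motif.match_consensus(pattern, rec, strands=("+",))
    assert len(hits) == n_plus
    if hits:
        assert (hits[0].start, hits[0].end) == (0, len(pattern))
        assert hits[0].rel_score == 1.0


def test_match_consensus_invalid_symbol():
    with pytest.raises(ValueError, match="IUPAC"):
        motif.match_consensus("ACGX", seqio.SequenceRecord("s", "ACGT"))


def test_nondegenerate_consensus_equals_substring_search(rng):
    from crossreg.seqio import reverse_complement

    seq = "".join(rng.choice(list("ACGT"), size=300))
    pattern = "GAAATT"
    rec = seqio.SequenceRecord("s", seq)
    hits = motif.match_consensus(pattern, rec)
    expected = set()
    for i in range(len(seq) - len(pattern) + 1):
        if seq[i : i + len(pattern)] == pattern:
            expected.add((i, "+"))
        if seq[i : i + len(pattern)] == reverse_complement(pattern):
            expected.add((i, "-"))
    assert {(h.start, h.strand) for h in hits} == expected


# ---------------------------------------------------------------------------
# matrix file I/O
# ---------------------------------------------------------------------------

def test_bundled_pfms_load_with_families(bundled):
    assert set(bundled) == {
        "IRF1", "IRF2", "IRF3", "IRF7", "NFKB1", "NFKB2", "RELA", "RELB",
        "REL", "JUN", "SP1",
    }
    assert bundled["IRF3"].family == "IRF"
    assert bundled["REL"].family == "NFKB"
    assert bundled["SP1"].family == "cofactor"
    assert bundled["RELA"].width == 11


def test_load_pfm_file_order_and_width(tmp_path):
    path = tmp_path / "m.txt"
    path.write_text(
        ">M1 TFA\nA [ 1 2 ]\nC [ 3 4 ]\nG [ 5 6 ]\nT [ 7 8 ]\n"
        ">M2 TFB\nA 1\nC 1\nG 1\nT 1\n"
    )
    pfms = motif.load_pfm_file(path)
    assert [p.tf_name for p in pfms] == ["TFA", "TFB"]
    assert pfms[0].width == 2 and pfms[1].width == 1
    assert pfms[0].counts[3, 1] == 8


@pytest.mark.parametrize(
    "body,match",
    [
        (">M1 T\nA 1 1\nC 1 1\nG 1 1\nT 1\n", "M1"),  # unequal rows
        (">M1 T\nA 1\nC x\nG 1\nT 1\n", "M1"),  # non-numeric
        (">M1 T\nA 1\nG 1\nC 1\nT 1\n", "expected row"),  # wrong order
    ],
)
def test_load_pfm_file_errors_name_the_matrix(tmp_path, body, match):
    path = tmp_path / "bad.txt"
    path.write_text(body)
    with pytest.raises(motif.PFMFormatError, match=match):
        motif.load_pfm_file(path)


def test_hits_tsv_and_bed_export(tmp_path, bundled):
    import pandas as pd

    pwm = motif.pfm_to_pwm(bundled["RELA"])
    rec = seqio.SequenceRecord("p", "CCCC" + "AGGAAATTCCG" + "CCCC")
    hits = motif.scan(pwm, rec, rel_threshold=0.9)
    motif.write_hits_tsv(hits, tmp_path / "h.tsv")
    motif.write_hits_bed(hits, tmp_path / "h.bed")
    df = pd.read_csv(tmp_path / "h.tsv", sep="\t")
    assert list(df.start) == [h.start for h in hits]
    bed = (tmp_path / "h.bed").read_text().splitlines()
    assert len(bed) == len(hits) and bed[0].split("\t")[0] == "p"
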